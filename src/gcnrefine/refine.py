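"""Eigengene-seeded k-means refinement of a hierarchical partition.

Hierarchical clustering commits each gene to a dendrogram branch once and
never revisits the decision.  This module runs a k-means loop on top of the
hierarchical partition: k is the number of detected modules, the centroids
are the module eigengenes, and the distance between a gene and a centroid
is the correlation-based co-expression distance (signed:
``(1 - cor) / 2``; unsigned: ``1 - |cor|``).  Each iteration recomputes
eigengenes from the current partition and reassigns every gene to its
nearest eigengene, so genes prematurely committed by the dendrogram can
migrate to the module whose summary profile actually fits them.

In signed mode minimizing the distance is the same as maximizing module
membership (kME), so at convergence no gene is misplaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, ParameterError, ValidationError
from .io import UNASSIGNED, ExpressionMatrix, Partition
from .modules import (
    EigengeneSet,
    count_misplaced,
    module_eigengenes,
    module_membership,
)
from .network import SIGNED, _NETWORK_TYPES


@dataclass(frozen=True)
class RefinementConfig:
    """Settings for the k-means refinement loop.

    ``max_iterations`` bounds the loop (the stopping rule also fires when
    no gene moves or when the misplaced count reaches
    ``target_misplaced``); ``include_unassigned_as_module`` decides whether
    the unassigned pool contributes its own centroid or its genes are
    simply captured by the nearest real module in the first iteration.
    Centroids are always recomputed from scratch each iteration.
    """

    max_iterations: int = 20
    target_misplaced: int = 0
    network_type: str = SIGNED
    include_unassigned_as_module: bool = False

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.target_misplaced < 0:
            raise ParameterError("target_misplaced must be >= 0")
        if self.network_type not in _NETWORK_TYPES:
            raise ParameterError(f"unknown network type: {self.network_type!r}")


@dataclass
class IterationRecord:
    iteration: int
    moved_genes: int
    within_cluster_distance: float
    mean_mm_movers: float  # NaN when nothing moved
    mean_mm_all: float
    eigengene_drift: dict[int, float]
    dropped_modules: tuple[int, ...] = ()


@dataclass
class RefinementTrace:
    records: list[IterationRecord] = field(default_factory=list)
    termination: str = ""

    @property
    def moved(self) -> list[int]:
        return [r.moved_genes for r in self.records]

    @property
    def within(self) -> list[float]:
        return [r.within_cluster_distance for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def coexpression_distance(
    gene_profile: np.ndarray,
    eigengene: np.ndarray,
    network_type: str = SIGNED,
) -> float:
    """Distance between a gene and an eigengene from their correlation.

    signed: ``(1 - cor) / 2`` (0 at cor 1, 1 at cor -1); unsigned:
    ``1 - |cor|`` (0 at either extreme).
    """
    if network_type not in _NETWORK_TYPES:
        raise ParameterError(f"unknown network type: {network_type!r}")
    g = np.asarray(gene_profile, dtype=float)
    e = np.asarray(eigengene, dtype=float)
    if g.shape != e.shape:
        raise ValidationError("gene and eigengene lengths differ")
    if g.std() == 0 or e.std() == 0:
        raise DegenerateDataError("constant vector has no correlation distance")
    cor = float(np.corrcoef(g, e)[0, 1])
    if network_type == SIGNED:
        return (1.0 - cor) / 2.0
    return 1.0 - abs(cor)


def _distance_matrix(mm_values: np.ndarray, network_type: str) -> np.ndarray:
    if network_type == SIGNED:
        return (1.0 - mm_values) / 2.0
    return 1.0 - np.abs(mm_values)


def reassign_step(
    expr: ExpressionMatrix,
    eigengenes: EigengeneSet,
    current: Partition,
    network_type: str = SIGNED,
) -> tuple[Partition, list[str]]:
    """One k-means assignment step: each gene to its nearest eigengene.

    Exact distance ties keep the gene's current module when it is among
    the tied candidates, otherwise the lowest tied label wins; this makes
    repeated reassignment a true fixed-point iteration.
    """
    labels = eigengenes.labels
    if not labels:
        raise ValidationError("empty eigengene set")
    mm = module_membership(expr, eigengenes)
    dist = _distance_matrix(mm.values, network_type)
    labels_arr = np.asarray(labels)
    new = current.labels.copy()
    moved: list[str] = []
    dmin = dist.min(axis=1)
    for g, gene in enumerate(expr.gene_ids):
        tied = labels_arr[dist[g] == dmin[g]]
        cur = int(current.labels[g])
        target = cur if cur in tied else int(tied.min())
        if target != cur:
            new[g] = target
            moved.append(gene)
    return current.with_labels(new), moved


def within_cluster_distance(
    expr: ExpressionMatrix,
    partition: Partition,
    eigengenes: EigengeneSet,
) -> float:
    """W(P): summed squared distance of standardized genes to centroids.

    Both the gene profiles and the eigengenes are standardized with the
    n-1 denominator, so per gene ``||g - c||^2 = 2 (n-1) (1 - cor(g, c))``
    and minimizing W is equivalent to the signed co-expression assignment.
    Unassigned genes contribute nothing.
    """
    n = expr.n_samples
    x = expr.values - expr.values.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateDataError("constant gene in within-cluster distance")
    x = x / sd
    total = 0.0
    for label in partition.module_labels:
        if label not in eigengenes.vectors:
            raise ValidationError(f"module {label} lacks an eigengene")
        c = eigengenes.vectors[label]
        idx = partition.members(label)
        diff = x[:, idx] - c[:, None]
        total += float(np.sum(diff**2))
    return total


def eigengene_drift(
    prev: EigengeneSet, curr: EigengeneSet
) -> dict[int, float]:
    """Euclidean distance between successive sign-aligned eigengenes.

    Labels present in only one set are reported as NaN (dropped modules).
    """
    shared = sorted(set(prev.vectors) & set(curr.vectors))
    if not shared:
        raise ValidationError("no shared module labels between eigengene sets")
    out: dict[int, float] = {}
    for label in set(prev.vectors) | set(curr.vectors):
        if label not in shared:
            out[label] = float("nan")
            continue
        a = prev.vectors[label]
        b = curr.vectors[label]
        if float(a @ b) < 0:  # re-apply the sign convention pairwise
            b = -b
        out[label] = float(np.linalg.norm(a - b))
    return out


def _effective_seed(partition: Partition, config: RefinementConfig) -> Partition:
    """Fold the unassigned label into a real module when configured."""
    if not config.include_unassigned_as_module:
        return partition
    if partition.n_unassigned() == 0:
        return partition
    new_label = max(partition.module_labels, default=0) + 1
    labels = partition.labels.copy()
    labels[labels == UNASSIGNED] = new_label
    return partition.with_labels(labels)


def refine(
    expr: ExpressionMatrix,
    seed_partition: Partition,
    config: RefinementConfig | None = None,
) -> tuple[Partition, RefinementTrace]:
    """Run the eigengene k-means loop from a hierarchical seed partition.

    Each iteration: recompute module eigengenes from the current partition,
    reassign every gene to its nearest eigengene, and record diagnostics
    (moved-gene count, W(P), mean kME of movers w.r.t. the seed eigengenes,
    mean own-module kME, per-module eigengene drift).  A module emptied by
    reassignment is dropped (k shrinks) and noted in the trace; dropping
    below k = 2 raises.  Stops when no gene moves, when the misplaced count
    reaches ``target_misplaced``, or at ``max_iterations``.
    """
    config = config or RefinementConfig()
    if tuple(seed_partition.genes) != expr.gene_ids:
        raise ValidationError("seed partition genes do not match expression")
    current = _effective_seed(seed_partition, config)
    if current.n_modules < 2:
        raise ValidationError(
            f"refinement needs k >= 2 modules, got {current.n_modules}"
        )
    seed_eigengenes = module_eigengenes(expr, current)
    seed_mm = module_membership(expr, seed_eigengenes)
    seed_col = {l: j for j, l in enumerate(seed_mm.labels)}
    seed_labels = current.labels.copy()

    trace = RefinementTrace()
    prev_eigengenes: EigengeneSet | None = None
    for it in range(1, config.max_iterations + 1):
        try:
            eigengenes = module_eigengenes(expr, current)
        except DegenerateDataError as exc:
            raise DegenerateDataError(
                f"iteration {it}: {exc}"
            ) from exc
        new_partition, moved = reassign_step(
            expr, eigengenes, current, config.network_type
        )
        # empty-module policy: drop and continue with smaller k
        alive = set(new_partition.module_labels)
        dropped = tuple(l for l in eigengenes.labels if l not in alive)
        if dropped and new_partition.n_modules < 2:
            raise ValidationError(
                f"iteration {it}: modules {dropped} emptied, leaving k < 2"
            )
        w = within_cluster_distance(
            expr,
            new_partition,
            EigengeneSet(
                {l: v for l, v in eigengenes.vectors.items() if l in alive},
                {l: v for l, v in eigengenes.variance_explained.items() if l in alive},
                eigengenes.sample_ids,
            ),
        )
        moved_idx = [expr.gene_index()[g] for g in moved]
        if moved_idx:
            mm_movers = float(
                np.mean(
                    [
                        seed_mm.values[g, seed_col[int(seed_labels[g])]]
                        for g in moved_idx
                        if int(seed_labels[g]) in seed_col
                    ]
                    or [np.nan]
                )
            )
        else:
            mm_movers = float("nan")
        cur_eg = module_eigengenes(expr, new_partition)
        cur_mm = module_membership(expr, cur_eg)
        cur_col = {l: j for j, l in enumerate(cur_mm.labels)}
        own = [
            cur_mm.values[g, cur_col[int(l)]]
            for g, l in enumerate(new_partition.labels)
            if int(l) in cur_col
        ]
        mm_all = float(np.mean(own)) if own else float("nan")
        drift = (
            eigengene_drift(prev_eigengenes, eigengenes)
            if prev_eigengenes is not None
            else {}
        )
        trace.records.append(
            IterationRecord(
                iteration=it,
                moved_genes=len(moved),
                within_cluster_distance=w,
                mean_mm_movers=mm_movers,
                mean_mm_all=mm_all,
                eigengene_drift=drift,
                dropped_modules=dropped,
            )
        )
        prev_eigengenes = eigengenes
        current = new_partition
        if len(moved) == 0:
            trace.termination = "converged"
            break
        # With the default target of 0 in signed mode, zero misplaced genes
        # is exactly the fixed point: the next iteration records 0 moves and
        # stops as "converged".  A positive target short-circuits earlier.
        if config.target_misplaced > 0:
            misplaced, _ = count_misplaced(cur_mm, current)
            if misplaced <= config.target_misplaced:
                trace.termination = "target_misplaced"
                break
    else:
        trace.termination = "max_iterations"
    return current, trace
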