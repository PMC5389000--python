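"""Quantitative evaluation of network partitions.

Three families of statistics:

* agreement between two partitions of the same genes — pair-counting Rand
  and Jaccard indices plus a one-to-one module-matching accuracy computed
  by maximum-weight bipartite matching;
* gene-set over-representation — one-sided Fisher exact tests per
  (module, set) pair with Benjamini-Hochberg adjustment, aggregated per
  module as ``s_GO = sum of -log10(p)`` over significant terms and per
  partition as ``S_GO``, with the information content ``IC = -log P(term)``
  guarding against generic annotations;
* a size-preserving random-reassignment null — movers between a seed and a
  refined partition are re-scattered at random subject to the refined
  module sizes, giving a baseline for how much of an enrichment gain mere
  size shuffling explains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import false_discovery_control, hypergeom

from .errors import DegenerateDataError, ParameterError, ValidationError
from .io import UNASSIGNED, ExpressionMatrix, GeneSetCollection, Partition
from .modules import module_eigengenes, module_membership

_INDICES = ("rand", "jaccard", "matching")


def contingency_table(p: Partition, q: Partition) -> np.ndarray:
    """Counts n_ij = |p_i intersect q_j| over the shared gene universe."""
    if p.genes != q.genes:
        raise ValidationError("partitions cover different gene universes")
    pl = np.unique(p.labels)
    ql = np.unique(q.labels)
    pi = {l: i for i, l in enumerate(pl)}
    qi = {l: i for i, l in enumerate(ql)}
    table = np.zeros((pl.size, ql.size), dtype=int)
    for a, b in zip(p.labels, q.labels):
        table[pi[int(a)], qi[int(b)]] += 1
    return table


def partition_similarity(p: Partition, q: Partition, index: str = "rand") -> float:
    """Label-permutation-invariant agreement between two partitions.

    ``rand`` and ``jaccard`` count gene pairs (co-clustered in both / one /
    neither); ``matching`` is the fraction of genes captured by an optimal
    one-to-one matching of modules between the partitions.  The unassigned
    label is treated as a regular cluster.
    """
    if index not in _INDICES:
        raise ParameterError(f"unknown similarity index: {index!r}")
    table = contingency_table(p, q)
    n = table.sum()
    if index == "matching":
        rows, cols = linear_sum_assignment(table, maximize=True)
        return float(table[rows, cols].sum() / n)
    # pair counting from the contingency table
    def pairs(x: np.ndarray) -> float:
        return float(np.sum(x * (x - 1) / 2))

    t = pairs(table)  # co-clustered in both
    pr = pairs(table.sum(axis=1))
    qr = pairs(table.sum(axis=0))
    total = n * (n - 1) / 2
    a = t
    b = pr - t  # co-clustered in P only
    c = qr - t  # in Q only
    d = total - pr - qr + t
    if index == "rand":
        return float((a + d) / total) if total else 1.0
    denom = a + b + c
    return float(a / denom) if denom else 1.0


@dataclass(frozen=True)
class EnrichmentResult:
    """One module x gene-set over-representation test."""

    module: int
    set_name: str
    overlap: int
    module_size: int
    set_size: int
    universe_size: int
    p_value: float
    adjusted_p: float
    odds_ratio: float


def _fisher_one_sided(
    overlap: int, module_size: int, set_size: int, universe_size: int
) -> float:
    # P(X >= overlap) for X ~ Hypergeom(universe, set, module)
    return float(
        hypergeom.sf(overlap - 1, universe_size, set_size, module_size)
    )


def _odds_ratio(
    overlap: int, module_size: int, set_size: int, universe_size: int
) -> float:
    a = overlap
    b = module_size - overlap
    c = set_size - overlap
    d = universe_size - module_size - set_size + overlap
    if min(a, b, c, d) == 0:  # Haldane correction
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def fisher_enrichment(
    module_genes: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
) -> tuple[float, float, int]:
    """One-sided Fisher exact test for over-representation.

    Returns ``(p_value, odds_ratio, overlap)``; the p-value is the exact
    hypergeometric upper tail.  Adjustment across a batch is applied by
    :func:`enrichment_table`.
    """
    universe = set(universe)
    module = set(module_genes) & universe
    gset = set(gene_set) & universe
    if not module:
        raise ValidationError("module is empty after intersecting the universe")
    if not gset:
        raise ValidationError("gene set is empty after intersecting the universe")
    overlap = len(module & gset)
    p = _fisher_one_sided(overlap, len(module), len(gset), len(universe))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    orr = _odds_ratio(overlap, len(module), len(gset), len(universe))
    return p, orr, overlap


def enrichment_table(
    partition: Partition,
    collection: GeneSetCollection,
    universe: Sequence[str] | None = None,
    include_unassigned: bool = False,
) -> list[EnrichmentResult]:
    """All (module, gene set) Fisher tests with BH adjustment across the batch."""
    universe = list(partition.genes) if universe is None else list(universe)
    uset = set(universe)
    gene_arr = np.asarray(partition.genes)
    labels = partition.module_labels
    if include_unassigned and partition.n_unassigned() > 0:
        labels = [UNASSIGNED] + labels
    raw: list[EnrichmentResult] = []
    for label in labels:
        module = set(gene_arr[partition.labels == label]) & uset
        if not module:
            continue
        for name in collection.names():
            gset = collection.members(name) & uset
            if not gset:
                continue
            p, orr, overlap = fisher_enrichment(module, gset, uset)
            raw.append(
                EnrichmentResult(
                    module=int(label),
                    set_name=name,
                    overlap=overlap,
                    module_size=len(module),
                    set_size=len(gset),
                    universe_size=len(uset),
                    p_value=p,
                    adjusted_p=float("nan"),
                    odds_ratio=orr,
                )
            )
    if not raw:
        return []
    adj = false_discovery_control([r.p_value for r in raw], method="bh")
    return [
        EnrichmentResult(
            r.module,
            r.set_name,
            r.overlap,
            r.module_size,
            r.set_size,
            r.universe_size,
            r.p_value,
            float(min(a, 1.0)),
            r.odds_ratio,
        )
        for r, a in zip(raw, adj)
    ]


@dataclass(frozen=True)
class SGoReport:
    """Per-module and partition-level enrichment aggregation."""

    per_module: dict[int, float]
    total: float
    alpha: float
    n_significant: int


def s_go(
    results: Sequence[EnrichmentResult],
    alpha: float = 0.05,
    use_adjusted_in_sum: bool = False,
    gate_on: str = "adjusted",
) -> SGoReport:
    """Aggregate enrichment p-values: s_GO per module, S_GO for the partition.

    A result is significant when its gated p-value (adjusted by default,
    raw with ``gate_on='raw'``) is below ``alpha``; significant results
    contribute ``-log10(p)`` (raw p by default) to their module's s_GO, and
    S_GO is the sum over modules.
    """
    if gate_on not in ("adjusted", "raw"):
        raise ParameterError(f"gate_on must be 'adjusted' or 'raw', got {gate_on!r}")
    per: dict[int, float] = {}
    n_sig = 0
    for r in results:
        per.setdefault(r.module, 0.0)
        gate = r.adjusted_p if gate_on == "adjusted" else r.p_value
        if gate < alpha:
            p = r.adjusted_p if use_adjusted_in_sum else r.p_value
            per[r.module] += -math.log10(p)
            n_sig += 1
    return SGoReport(per, float(sum(per.values())), alpha, n_sig)


def relative_improvement(s_after: SGoReport, s_before: SGoReport) -> float:
    """S_GO(after) / S_GO(before) - 1."""
    if s_before.total <= 0:
        raise DegenerateDataError(
            "relative improvement undefined: baseline S_GO is 0"
        )
    return s_after.total / s_before.total - 1.0


def information_content(
    term: str,
    annotation_frequencies: Mapping[str, float],
    base: str = "e",
) -> float:
    """IC(t) = -log P(t), the negative log annotation probability of a term."""
    if term not in annotation_frequencies:
        raise ValidationError(f"term {term!r} has no annotation frequency")
    p = float(annotation_frequencies[term])
    if not 0.0 < p <= 1.0:
        raise ValidationError(f"annotation probability of {term!r} must be in (0, 1]")
    if base == "e":
        return -math.log(p)
    if base == "10":
        return -math.log10(p)
    if base == "2":
        return -math.log2(p)
    raise ParameterError(f"unknown log base: {base!r}")


def random_reassignment_null(
    seed_partition: Partition,
    refined_partition: Partition,
    rng_seed: int,
) -> Partition:
    """Size-preserving random placement of the genes the refinement moved.

    Genes whose label differs between the seed and the refined partition
    are pooled and redistributed uniformly at random so that every module's
    final size equals its refined size; genes the refinement left in place
    stay put.  Deterministic given ``rng_seed``.
    """
    if seed_partition.genes != refined_partition.genes:
        raise ValidationError("partitions cover different gene universes")
    movers = np.flatnonzero(seed_partition.labels != refined_partition.labels)
    if movers.size == 0:
        return refined_partition
    labels = seed_partition.labels.copy()
    # capacity per label = refined size minus genes already fixed there
    fixed = labels.copy()
    fixed_mask = np.ones(len(labels), dtype=bool)
    fixed_mask[movers] = False
    refined_sizes: dict[int, int] = {}
    for l in np.unique(refined_partition.labels):
        refined_sizes[int(l)] = int(np.sum(refined_partition.labels == l))
    capacity: dict[int, int] = {}
    for l, size in refined_sizes.items():
        stay = int(np.sum(fixed[fixed_mask] == l))
        cap = size - stay
        if cap < 0:
            raise ValidationError(
                f"module {l}: refined size {size} below its unchanged-gene count"
            )
        capacity[l] = cap
    if sum(capacity.values()) != movers.size:
        raise ValidationError("mover pool cannot satisfy refined module sizes")
    slots = np.concatenate(
        [np.full(c, l, dtype=int) for l, c in sorted(capacity.items())]
    )
    rng = np.random.default_rng(rng_seed)
    rng.shuffle(slots)
    labels[movers] = slots
    return seed_partition.with_labels(labels)


@dataclass(frozen=True)
class MoverStats:
    """kME of moved genes at departure (seed) and arrival (refined)."""

    n_movers: int
    departure_mean: float
    departure_sd: float
    arrival_mean: float
    arrival_sd: float

    @property
    def empty(self) -> bool:
        return self.n_movers == 0


def mover_mm_stats(
    expr: ExpressionMatrix,
    seed_partition: Partition,
    refined_partition: Partition,
) -> MoverStats:
    """kME statistics of the genes the refinement moved.

    Departure kME is measured at the seed module against the seed
    partition's eigengenes; arrival kME at the destination module against
    the refined partition's eigengenes.  Genes departing the unassigned
    pool have no seed eigengene and are excluded from the departure side.
    Returns an empty-stats sentinel (NaNs) when nothing moved.
    """
    if seed_partition.genes != refined_partition.genes:
        raise ValidationError("partitions cover different gene universes")
    movers = np.flatnonzero(seed_partition.labels != refined_partition.labels)
    if movers.size == 0:
        return MoverStats(0, *([float("nan")] * 4))
    seed_eg = module_eigengenes(expr, seed_partition)
    seed_mm = module_membership(expr, seed_eg)
    seed_col = {l: j for j, l in enumerate(seed_mm.labels)}
    ref_eg = module_eigengenes(expr, refined_partition)
    ref_mm = module_membership(expr, ref_eg)
    ref_col = {l: j for j, l in enumerate(ref_mm.labels)}
    departures = [
        seed_mm.values[g, seed_col[int(seed_partition.labels[g])]]
        for g in movers
        if int(seed_partition.labels[g]) in seed_col
    ]
    arrivals = [
        ref_mm.values[g, ref_col[int(refined_partition.labels[g])]]
        for g in movers
        if int(refined_partition.labels[g]) in ref_col
    ]

    def _mean_sd(x: list[float]) -> tuple[float, float]:
        if not x:
            return float("nan"), float("nan")
        arr = np.asarray(x)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    dm, dsd = _mean_sd(departures)
    am, asd = _mean_sd(arrivals)
    return MoverStats(int(movers.size), dm, dsd, am, asd)
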