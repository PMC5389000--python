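"""Module detection and eigengene machinery.

Modules are detected by average-linkage hierarchical clustering on the
``1 - TOM`` distance followed by a dendrogram cut; each module is summarised
by its eigengene, the first principal component of the standardized member
expression, sign-aligned so the mean correlation with member genes is
non-negative.  Module membership (kME) is the correlation of each gene with
each eigengene, and a gene is "misplaced" when some other module's
eigengene fits it strictly better than its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DegenerateDataError, ParameterError, ValidationError
from .io import UNASSIGNED, ExpressionMatrix, Partition
from .network import TOMatrix


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over the gene order of the input TOM."""

    linkage_matrix: np.ndarray  # scipy (m-1) x 4 format
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        z = np.asarray(self.linkage_matrix, dtype=float)
        object.__setattr__(self, "linkage_matrix", z)
        m = len(self.gene_ids)
        if z.shape != (m - 1, 4):
            raise ValidationError("linkage must have exactly m-1 merges")
        heights = z[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValidationError("merge heights must be non-decreasing")


@dataclass(frozen=True)
class EigengeneSet:
    """Per-module eigengene profiles (zero mean, unit variance, n-1 ddof).

    ``sign_ambiguous`` records modules whose mean member correlation was
    exactly zero, where the sign convention cannot bite and the PCA
    solver's sign is kept.
    """

    vectors: dict[int, np.ndarray]
    variance_explained: dict[int, float]
    sample_ids: tuple[str, ...]
    sign_ambiguous: frozenset[int] = field(default_factory=frozenset)

    @property
    def labels(self) -> list[int]:
        return sorted(self.vectors)

    def matrix(self, labels: list[int] | None = None) -> np.ndarray:
        """Eigengenes stacked as an n_samples x k matrix."""
        labels = self.labels if labels is None else labels
        return np.column_stack([self.vectors[l] for l in labels])


@dataclass(frozen=True)
class ModuleMembershipMatrix:
    """Gene x module correlation matrix (kME)."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    labels: tuple[int, ...]

    def column(self, label: int) -> np.ndarray:
        return self.values[:, self.labels.index(label)]


def _standardize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance columns using the n-1 denominator."""
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateDataError("constant profile cannot be standardized")
    return x / sd


def _cut_static(z: np.ndarray, cut_height: float) -> np.ndarray:
    return fcluster(z, t=cut_height, criterion="distance")


def _tree_children(z: np.ndarray, m: int) -> dict[int, tuple[int, int, float]]:
    return {
        m + i: (int(z[i, 0]), int(z[i, 1]), float(z[i, 2]))
        for i in range(z.shape[0])
    }


def _cut_tree_dynamic(
    z: np.ndarray, m: int, cut_height: float, min_size: int, split_gap: float
) -> np.ndarray:
    """Height-threshold branch decomposition with recursive gap splitting.

    Branches are first separated at ``cut_height``.  A merge is then split
    recursively when it is a clear bifurcation — both child subtrees
    "hang", i.e. sit at least ``split_gap`` below the merge height — or
    when one child hangs with at least ``min_size`` leaves while the other
    continues a plateau of near-equal merge heights (e.g. three equidistant
    clusters joined by two same-height merges).  Tight clusters, whose
    stray children are single leaves joining just below the cluster top,
    stay whole.  The minimum-size filter then applies to the resulting
    branches; leaves in no qualifying branch stay unassigned.
    """
    children = _tree_children(z, m)

    def node_height(node: int) -> float:
        return 0.0 if node < m else children[node][2]

    def leaves(node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            nd = stack.pop()
            if nd < m:
                out.append(nd)
            else:
                left, right, _ = children[nd]
                stack.extend((left, right))
        return out

    def n_leaves(node: int) -> int:
        return 1 if node < m else int(z[node - m, 3])

    def hangs(node: int, h: float) -> bool:
        return h - node_height(node) >= split_gap

    def decompose(node: int) -> list[list[int]]:
        if node < m:
            return [[node]]
        left, right, h = children[node]
        bifurcation = hangs(left, h) and hangs(right, h)
        plateau_branch = any(
            hangs(ch, h) and n_leaves(ch) >= min_size for ch in (left, right)
        )
        if bifurcation or plateau_branch:
            return decompose(left) + decompose(right)
        return [leaves(node)]

    parent = {}
    for nd, (a, b, _) in children.items():
        parent[a] = nd
        parent[b] = nd

    # maximal subtrees whose root merge height is <= cut_height
    flat = _cut_static(z, cut_height)
    labels = np.zeros(m, dtype=int)
    next_label = 1
    for comp in np.unique(flat):
        idx = np.flatnonzero(flat == comp)
        if idx.size < min_size:
            continue
        # root node of this component in the merge tree
        member = set(idx.tolist())
        root = int(idx[0])
        while root in parent and set(leaves(parent[root])) <= member:
            root = parent[root]
        for clus in decompose(root):
            if len(clus) >= min_size:
                labels[clus] = next_label
                next_label += 1
    return labels


def hierarchical_partition(
    tom: TOMatrix,
    min_module_size: int = 30,
    cut_method: str = "tree",
    cut_height: float = 0.99,
    split_gap: float = 0.05,
) -> tuple[Dendrogram, Partition]:
    """Average-linkage clustering on 1 - TOM plus a dendrogram cut.

    ``cut_method='tree'`` performs the height-threshold branch
    decomposition with recursive gap-based splitting; ``'static'`` is a
    plain flat cut at ``cut_height``.  Branches smaller than
    ``min_module_size`` are left unassigned.  Modules are renumbered 1..k
    by decreasing size.
    """
    m = len(tom.gene_ids)
    if min_module_size < 2:
        raise ParameterError("min_module_size must be >= 2")
    if min_module_size > m:
        raise ParameterError(
            f"min_module_size {min_module_size} exceeds gene count {m}"
        )
    if cut_method not in ("tree", "static"):
        raise ParameterError(f"unknown cut method: {cut_method!r}")
    dist = tom.distance()
    z = linkage(squareform(dist, checks=False), method="average")
    z[:, 2] = np.maximum.accumulate(z[:, 2])  # guard tiny non-monotone noise
    dendro = Dendrogram(z, tom.gene_ids)
    if cut_method == "static":
        flat = _cut_static(z, cut_height)
        labels = np.zeros(m, dtype=int)
        nxt = 1
        for comp in np.unique(flat):
            idx = np.flatnonzero(flat == comp)
            if idx.size >= min_module_size:
                labels[idx] = nxt
                nxt += 1
    else:
        labels = _cut_tree_dynamic(z, m, cut_height, min_module_size, split_gap)
    part = Partition(tom.gene_ids, labels).relabel_by_size()
    return dendro, part


def module_eigengenes(
    expr: ExpressionMatrix, partition: Partition
) -> EigengeneSet:
    """First principal component summary of every non-unassigned module.

    Member genes are standardized (correlation PCA), the first PC score
    vector across samples is standardized in turn, and its sign is flipped
    so the mean correlation with member genes is >= 0.
    """
    if tuple(partition.genes) != expr.gene_ids:
        raise ValidationError("partition genes do not match expression genes")
    vectors: dict[int, np.ndarray] = {}
    varex: dict[int, float] = {}
    ambiguous: set[int] = set()
    for label in partition.module_labels:
        idx = partition.members(label)
        block = expr.values[:, idx]
        try:
            x = _standardize(block)
        except DegenerateDataError:
            raise DegenerateDataError(
                f"module {label} contains a constant gene; eigengene undefined"
            ) from None
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        score = u[:, 0]
        sd = score.std(ddof=1)
        if sd == 0:
            raise DegenerateDataError(f"module {label} has a degenerate eigengene")
        eg = (score - score.mean()) / sd
        mean_cor = float(np.mean((x.T @ eg) / (len(eg) - 1)))
        if mean_cor < 0:
            eg = -eg
        elif mean_cor == 0:
            ambiguous.add(label)
        vectors[label] = eg
        varex[label] = float(s[0] ** 2 / np.sum(s**2))
    return EigengeneSet(vectors, varex, expr.sample_ids, frozenset(ambiguous))


def module_membership(
    expr: ExpressionMatrix, eigengenes: EigengeneSet
) -> ModuleMembershipMatrix:
    """kME: Pearson correlation of every gene with every module eigengene."""
    if expr.sample_ids != eigengenes.sample_ids:
        raise ValidationError("expression and eigengene samples do not match")
    from .network import check_variance

    check_variance(expr)
    labels = eigengenes.labels
    x = expr.values - expr.values.mean(axis=0)
    x /= np.linalg.norm(x, axis=0)
    e = eigengenes.matrix(labels)
    e = e - e.mean(axis=0)
    e /= np.linalg.norm(e, axis=0)
    mm = np.clip(x.T @ e, -1.0, 1.0)
    return ModuleMembershipMatrix(mm, expr.gene_ids, tuple(labels))


def count_misplaced(
    mm: ModuleMembershipMatrix, partition: Partition
) -> tuple[int, list[str]]:
    """Genes whose kME is strictly higher in some other module.

    Unassigned genes are never counted; exact ties do not misplace.
    """
    col = {l: j for j, l in enumerate(mm.labels)}
    missing = [l for l in partition.module_labels if l not in col]
    if missing:
        raise ValidationError(f"partition modules lack kME columns: {missing}")
    misplaced: list[str] = []
    for g, gene, label in zip(range(len(mm.gene_ids)), mm.gene_ids, partition.labels):
        if label == UNASSIGNED:
            continue
        own = mm.values[g, col[int(label)]]
        if np.any(mm.values[g] > own):
            misplaced.append(gene)
    return len(misplaced), misplaced


def assign_unclustered(
    expr: ExpressionMatrix,
    partition: Partition,
    eigengenes: EigengeneSet,
) -> Partition:
    """Give every unassigned gene to its argmax-kME module.

    Assigned genes are untouched; kME ties go to the lowest module label.
    """
    if not eigengenes.labels:
        raise ValidationError("no modules to assign unclustered genes to")
    un = np.flatnonzero(partition.labels == UNASSIGNED)
    if un.size == 0:
        return partition
    mm = module_membership(expr, eigengenes)
    labels_arr = np.asarray(eigengenes.labels)
    new = partition.labels.copy()
    for g in un:
        row = mm.values[g]
        best = row.max()
        tied = labels_arr[row == best]
        new[g] = int(tied.min())
    return partition.with_labels(new)
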