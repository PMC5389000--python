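"""Domain containers and file formats.

The canonical in-memory orientation for expression data is samples x genes:
rows are samples, columns are genes.  Files default to genes-in-rows (the
common distribution format for expression matrices) and are transposed on
read.  Partitions are two-column TSV (gene, module); gene sets are GMT.

Missing values are rejected, never imputed: pipelines are expected to filter
to complete data before network construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

UNASSIGNED = 0
GREY = "grey"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A samples x genes numeric expression matrix with identifiers."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n, m = values.shape
        if n != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if m != len(self.gene_ids):
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {m} columns")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                "non-finite expression value at sample "
                f"{self.sample_ids[bad[0]]!r}, gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: j for j, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        cols = [idx[g] for g in genes]
        return ExpressionMatrix(self.values[:, cols], self.sample_ids, tuple(genes))


@dataclass(frozen=True)
class CovariateTable:
    """Per-sample covariates (categoricals pre-encoded as indicators)."""

    values: np.ndarray
    covariate_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "covariate_ids", tuple(map(str, self.covariate_ids)))
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        if values.ndim != 2 or values.shape != (
            len(self.sample_ids),
            len(self.covariate_ids),
        ):
            raise ValidationError("covariate table shape does not match its ids")
        _check_unique(self.covariate_ids, "covariate")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(values)):
            raise ValidationError("covariate table contains non-finite values")


class Partition:
    """A total assignment of genes to module labels.

    Labels are non-negative integers; label ``0`` is the distinguished
    unassigned ("grey") label.  Every gene of the paired expression matrix
    appears exactly once, and every non-unassigned module is non-empty by
    construction.
    """

    __slots__ = ("genes", "labels")

    def __init__(self, genes: Sequence[str], labels: Iterable[int]) -> None:
        self.genes: tuple[str, ...] = tuple(map(str, genes))
        self.labels: np.ndarray = np.asarray(list(labels), dtype=int)
        if self.labels.shape != (len(self.genes),):
            raise ValidationError("one label per gene required")
        if np.any(self.labels < 0):
            raise ValidationError("module labels must be non-negative")
        _check_unique(self.genes, "gene")

    @classmethod
    def from_dict(
        cls, assignment: Mapping[str, int], genes: Sequence[str] | None = None
    ) -> "Partition":
        genes = tuple(assignment) if genes is None else tuple(genes)
        missing = [g for g in genes if g not in assignment]
        if missing:
            raise ValidationError(f"genes missing from assignment: {missing[:5]}")
        extra = set(assignment) - set(genes)
        if extra:
            raise ValidationError(f"assignment covers unknown genes: {sorted(extra)[:5]}")
        return cls(genes, [assignment[g] for g in genes])

    def to_dict(self) -> dict[str, int]:
        return dict(zip(self.genes, self.labels.tolist()))

    @property
    def module_labels(self) -> list[int]:
        """Sorted non-unassigned labels present in the partition."""
        return sorted(int(l) for l in np.unique(self.labels) if l != UNASSIGNED)

    @property
    def n_modules(self) -> int:
        return len(self.module_labels)

    def members(self, label: int) -> np.ndarray:
        """Column indices (gene positions) of the given module."""
        return np.flatnonzero(self.labels == label)

    def module_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return {
            int(l): int(c) for l, c in zip(labels, counts) if l != UNASSIGNED
        }

    def n_unassigned(self) -> int:
        return int(np.sum(self.labels == UNASSIGNED))

    def with_labels(self, labels: np.ndarray) -> "Partition":
        return Partition(self.genes, labels)

    def relabel_by_size(self) -> "Partition":
        """Renumber modules 1..k by decreasing size (ties by old label)."""
        sizes = self.module_sizes()
        order = sorted(sizes, key=lambda l: (-sizes[l], l))
        mapping = {old: new for new, old in enumerate(order, start=1)}
        mapping[UNASSIGNED] = UNASSIGNED
        return Partition(self.genes, [mapping[int(l)] for l in self.labels])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Partition)
            and self.genes == other.genes
            and bool(np.array_equal(self.labels, other.labels))
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Partition({len(self.genes)} genes, {self.n_modules} modules, "
            f"{self.n_unassigned()} unassigned)"
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT): name -> (description, members)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    path: str | Path,
    orientation: str = "genes_in_rows",
    delimiter: str = "\t",
) -> ExpressionMatrix:
    """Read a delimited expression matrix into canonical samples x genes form.

    ``orientation`` names what the file's ROWS contain.  With
    ``genes_in_rows`` (default) the header row holds sample ids and the
    first column gene ids; ``samples_in_rows`` is the transpose.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ParameterError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty expression file: {path}") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"expression file has no data body: {path}")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    what_rows = "gene" if orientation == "genes_in_rows" else "sample"
    what_cols = "sample" if orientation == "genes_in_rows" else "gene"
    _check_unique(row_ids, what_rows)
    _check_unique(col_ids, what_cols)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        # locate the first offending cell for the error message
        for i, row in enumerate(df.to_numpy()):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric value {cell!r} at row {row_ids[i]!r}, "
                        f"column {col_ids[j]!r}"
                    ) from None
        raise
    if orientation == "genes_in_rows":
        return ExpressionMatrix(values.T, sample_ids=col_ids, gene_ids=row_ids)
    return ExpressionMatrix(values, sample_ids=row_ids, gene_ids=col_ids)


def write_expression(
    expr: ExpressionMatrix,
    path: str | Path,
    orientation: str = "genes_in_rows",
    delimiter: str = "\t",
) -> None:
    df = pd.DataFrame(
        expr.values.T, index=list(expr.gene_ids), columns=list(expr.sample_ids)
    )
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "genes_in_rows":
        raise ParameterError(f"unknown orientation: {orientation!r}")
    df.to_csv(path, sep=delimiter, index_label="id")


def _label_to_str(label: int, grey: bool) -> str:
    if label == UNASSIGNED and grey:
        return GREY
    return str(label)


def write_partition(
    partition: Partition, path: str | Path, grey: bool = False
) -> None:
    """Write a partition as two-column TSV (gene, module) with a header."""
    with open(path, "w") as fh:
        fh.write("gene\tmodule\n")
        for g, l in zip(partition.genes, partition.labels.tolist()):
            fh.write(f"{g}\t{_label_to_str(l, grey)}\n")


def read_partition(path: str | Path, genes: Sequence[str]) -> Partition:
    """Read a two-column partition TSV and validate coverage against genes."""
    genes = tuple(map(str, genes))
    universe = set(genes)
    assignment: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"empty partition file: {path}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            gene, module = parts
            if gene in assignment:
                raise FormatError(f"{path}: duplicate gene row for {gene!r}")
            if gene not in universe:
                raise FormatError(
                    f"{path}: gene {gene!r} not in the supplied gene list"
                )
            if module == GREY:
                label = UNASSIGNED
            else:
                try:
                    label = int(module)
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: bad module label {module!r}"
                    ) from None
            assignment[gene] = label
    missing = [g for g in genes if g not in assignment]
    if missing:
        raise FormatError(
            f"{path}: genes missing from partition file: {missing[:5]}"
        )
    return Partition(genes, [assignment[g] for g in genes])


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB members..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >= 3 fields"
                )
            name, desc, *members = parts
            if name in sets:
                raise FormatError(f"{path}: duplicate gene-set name {name!r}")
            dedup = frozenset(m for m in members if m)
            if not dedup:
                raise FormatError(f"{path}: line {lineno}: set {name!r} is empty")
            sets[name] = (desc, dedup)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_covariates(path: str | Path, delimiter: str = "\t") -> CovariateTable:
    """Read a samples x covariates table (first column sample ids)."""
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty covariate file: {path}") from None
    return CovariateTable(
        df.to_numpy(dtype=float),
        covariate_ids=tuple(map(str, df.columns)),
        sample_ids=tuple(map(str, df.index)),
    )


# ---------------------------------------------------------------------------
# residualization


def residualize(expr: ExpressionMatrix, cov: CovariateTable) -> ExpressionMatrix:
    """Replace expression by OLS residuals on [intercept | covariates].

    Per gene, ordinary least-squares of expression on the covariate design
    with an intercept; residuals are exactly orthogonal to every design
    column.  Raises on sample mismatch or a rank-deficient design, naming
    the collinear columns.
    """
    if cov.sample_ids != expr.sample_ids:
        raise ValidationError(
            "covariate samples do not match expression samples "
            f"({len(cov.sample_ids)} vs {expr.n_samples})"
        )
    n = expr.n_samples
    design = np.column_stack([np.ones(n), cov.values])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name columns that do not increase the incremental rank
        collinear = []
        r = 1  # intercept
        cur = design[:, :1]
        for j, name in enumerate(cov.covariate_ids):
            trial = np.column_stack([cur, design[:, j + 1]])
            tr = np.linalg.matrix_rank(trial)
            if tr == r:
                collinear.append(name)
            else:
                cur, r = trial, tr
        raise ValidationError(
            f"rank-deficient covariate design; collinear columns: {collinear}"
        )
    coef, *_ = np.linalg.lstsq(design, expr.values, rcond=None)
    resid = expr.values - design @ coef
    return ExpressionMatrix(resid, expr.sample_ids, expr.gene_ids)
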