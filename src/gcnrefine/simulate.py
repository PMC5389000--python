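"""Eigengene-seeded simulation of module-structured expression data.

The generator mirrors how module structure arises in co-expression data:
each module is anchored by a latent eigengene profile across samples, and a
member gene with target correlation ``r`` is drawn as

    g = r * eg + sqrt(1 - r^2) * noise

so its marginal variance is 1 and its expected correlation with the
eigengene is exactly ``r``.  Per-gene ``r`` is drawn uniformly from a
configurable range, a fraction of genes may be anti-correlated (flip the
sign of ``r``) for unsigned-network fixtures, and background genes are pure
noise carrying the unassigned label in the returned ground-truth partition.

Eigengenes may be supplied (e.g. taken from a real network) or sampled as
near-orthogonal standard-normal profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .io import UNASSIGNED, ExpressionMatrix, Partition


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated dataset.

    ``module_proportions`` are fractions of ``n_genes`` per module summing
    to at most 1; the remainder becomes background noise genes with the
    unassigned truth label.
    """

    n_samples: int = 150
    n_genes: int = 600
    module_proportions: tuple[float, ...] = (0.2, 0.18, 0.16, 0.14, 0.12, 0.1)
    within_module_cor_range: tuple[float, float] = (0.6, 0.95)
    background_noise_sd: float = 1.0
    negative_fraction: float = 0.0
    eigengenes: np.ndarray | None = None  # k x n_samples, generated if absent
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ParameterError("need at least 4 samples")
        k = len(self.module_proportions)
        if k < 2:
            raise ParameterError("need at least 2 modules")
        if any(p <= 0 for p in self.module_proportions):
            raise ParameterError("module proportions must be positive")
        if sum(self.module_proportions) > 1 + 1e-9:
            raise ParameterError("module proportions must sum to <= 1")
        lo, hi = self.within_module_cor_range
        if not (0 < lo <= hi < 1):
            raise ParameterError(
                "within_module_cor_range must satisfy 0 < min <= max < 1"
            )
        if not 0 <= self.negative_fraction <= 1:
            raise ParameterError("negative_fraction must be in [0, 1]")
        if self.eigengenes is not None:
            eg = np.asarray(self.eigengenes, dtype=float)
            if eg.shape != (k, self.n_samples):
                raise ParameterError(
                    f"eigengene matrix must be {k} x {self.n_samples}"
                )
            object.__setattr__(self, "eigengenes", eg)

    @property
    def k(self) -> int:
        return len(self.module_proportions)

    def module_sizes(self) -> list[int]:
        return [int(round(p * self.n_genes)) for p in self.module_proportions]


@dataclass(frozen=True)
class SimulatedDataset:
    expression: ExpressionMatrix
    truth: Partition
    spec: SimulationSpec


def _standardize_vec(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    return v / v.std(ddof=1)


def simulate_eigengenes(
    k: int, n_samples: int, rng_seed: int, max_abs_cor: float = 0.3
) -> np.ndarray:
    """Sample k near-orthogonal standardized eigengene profiles.

    Rejection sampling keeps every pairwise |cor| below ``max_abs_cor``;
    raises if 1,000 attempts cannot satisfy that (k too large for n).
    """
    if k < 2:
        raise ParameterError("need at least 2 eigengenes")
    if n_samples < 4:
        raise ParameterError("need at least 4 samples")
    rng = np.random.default_rng(rng_seed)
    rows: list[np.ndarray] = []
    attempts = 0
    while len(rows) < k:
        attempts += 1
        if attempts > 1000:
            raise ValidationError(
                f"could not sample {k} eigengenes with pairwise |cor| < "
                f"{max_abs_cor} in {n_samples} samples"
            )
        cand = _standardize_vec(rng.standard_normal(n_samples))
        if all(
            abs(float(cand @ r) / (n_samples - 1)) < max_abs_cor for r in rows
        ):
            rows.append(cand)
    return np.vstack(rows)


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Generate expression and the planted ground-truth partition."""
    rng = np.random.default_rng(spec.rng_seed)
    n, m, k = spec.n_samples, spec.n_genes, spec.k
    if spec.eigengenes is not None:
        eg = np.vstack([_standardize_vec(row) for row in spec.eigengenes])
    else:
        eg = simulate_eigengenes(k, n, int(rng.integers(2**31 - 1)))
    sizes = spec.module_sizes()
    if sum(sizes) > m:
        raise ParameterError("rounded module sizes exceed the gene count")
    n_background = m - sum(sizes)
    values = np.empty((n, m))
    labels = np.empty(m, dtype=int)
    gene_ids = [f"g{j + 1:04d}" for j in range(m)]
    col = 0
    for mod, size in enumerate(sizes, start=1):
        r = rng.uniform(*spec.within_module_cor_range, size=size)
        flip = rng.random(size) < spec.negative_fraction
        r = np.where(flip, -r, r)
        noise = rng.standard_normal((n, size))
        values[:, col : col + size] = r * eg[mod - 1][:, None] + np.sqrt(
            1.0 - r**2
        ) * noise
        labels[col : col + size] = mod
        col += size
    if n_background:
        values[:, col:] = spec.background_noise_sd * rng.standard_normal(
            (n, n_background)
        )
        labels[col:] = UNASSIGNED
    expr = ExpressionMatrix(values, tuple(f"s{i + 1}" for i in range(n)), gene_ids)
    return SimulatedDataset(expr, Partition(gene_ids, labels), spec)


def scramble_partition(
    truth: Partition, fraction: float, rng_seed: int
) -> Partition:
    """Move a fraction of non-unassigned genes to a wrong (random) module."""
    if not 0 < fraction < 1:
        raise ParameterError("fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    labels = truth.labels.copy()
    assigned = np.flatnonzero(labels != UNASSIGNED)
    n_move = max(1, int(round(fraction * assigned.size)))
    victims = rng.choice(assigned, size=n_move, replace=False)
    module_labels = truth.module_labels
    for g in victims:
        others = [l for l in module_labels if l != labels[g]]
        labels[g] = int(rng.choice(others))
    return truth.with_labels(labels)


_TOY_NAMES = ("two_block", "five_module_scrambled", "empty_module_trap")


def make_toy_fixture(name: str) -> tuple[SimulatedDataset, Partition]:
    """Canonical deterministic fixtures used throughout the test suite.

    two_block
        two 40-gene modules with near-perfect within-module correlation;
        the seed partition is the truth itself.
    five_module_scrambled
        five well-separated modules; 10% of the true labels are moved to
        wrong modules to seed the refinement.
    empty_module_trap
        two true modules, but the seed carves a third module out of genes
        belonging to the other two, so refinement empties and drops it.
    """
    if name not in _TOY_NAMES:
        raise ParameterError(f"unknown fixture name: {name!r}")
    if name == "two_block":
        spec = SimulationSpec(
            n_samples=60,
            n_genes=80,
            module_proportions=(0.5, 0.5),
            within_module_cor_range=(0.95, 0.99),
            rng_seed=11,
        )
        ds = simulate_dataset(spec)
        return ds, ds.truth
    if name == "five_module_scrambled":
        spec = SimulationSpec(
            n_samples=100,
            n_genes=250,
            module_proportions=(0.2,) * 5,
            within_module_cor_range=(0.8, 0.95),
            rng_seed=23,
        )
        ds = simulate_dataset(spec)
        seed = scramble_partition(ds.truth, 0.10, rng_seed=29)
        return ds, seed
    # empty_module_trap
    spec = SimulationSpec(
        n_samples=80,
        n_genes=80,
        module_proportions=(0.5, 0.5),
        within_module_cor_range=(0.85, 0.95),
        rng_seed=37,
    )
    ds = simulate_dataset(spec)
    labels = ds.truth.labels.copy()
    rng = np.random.default_rng(41)
    trap = np.concatenate(
        [
            rng.choice(np.flatnonzero(labels == 1), size=10, replace=False),
            rng.choice(np.flatnonzero(labels == 2), size=10, replace=False),
        ]
    )
    labels[trap] = 3
    return ds, ds.truth.with_labels(labels)

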