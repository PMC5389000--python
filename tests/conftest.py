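"""Shared fixtures: small deterministic expression datasets and partitions."""

from __future__ import annotations

import numpy as np
import pytest

from gcnrefine import (
    ExpressionMatrix,
    Partition,
    make_toy_fixture,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_block():
    return make_toy_fixture("two_block")


@pytest.fixture(scope="session")
def five_module_scrambled():
    return make_toy_fixture("five_module_scrambled")


@pytest.fixture(scope="session")
def empty_module_trap():
    return make_toy_fixture("empty_module_trap")


@pytest.fixture
def small_expr():
    """10 samples x 4 genes with two clean anti/correlated pairs."""
    rng = np.random.default_rng(7)
    base = rng.standard_normal(10)
    other = rng.standard_normal(10)
    values = np.column_stack(
        [base, base + 0.01 * rng.standard_normal(10), other, -other]
    )
    return ExpressionMatrix(
        values, [f"s{i}" for i in range(10)], ["gA", "gA2", "gB", "gBneg"]
    )


def random_partition(genes, k, rng, allow_unassigned=True):
    low = 0 if allow_unassigned else 1
    labels = rng.integers(low, k + 1, size=len(genes))
    return Partition(genes, labels)
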