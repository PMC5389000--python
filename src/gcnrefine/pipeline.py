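"""End-to-end convenience pipeline: expression -> network -> modules.

Chains soft-threshold selection, TOM construction, hierarchical module
detection and eigengene computation, returning every intermediate artifact.
The k-means refinement is a separate, explicit step (see
:func:`gcnrefine.refine.refine`) because it consumes any seed partition,
not only the hierarchical one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import ExpressionMatrix, Partition
from .modules import (
    Dendrogram,
    EigengeneSet,
    ModuleMembershipMatrix,
    hierarchical_partition,
    module_eigengenes,
    module_membership,
)
from .network import (
    SFTReport,
    SIGNED,
    TOMatrix,
    adjacency,
    correlation_matrix,
    pick_soft_threshold,
    topological_overlap,
)


@dataclass(frozen=True)
class BuildResult:
    sft: SFTReport
    tom: TOMatrix
    dendrogram: Dendrogram
    partition: Partition
    eigengenes: EigengeneSet
    membership: ModuleMembershipMatrix


def build_network_partition(
    expr: ExpressionMatrix,
    beta: int | None = None,
    network_type: str = SIGNED,
    cor_method: str = "pearson",
    min_module_size: int = 30,
    cut_method: str = "tree",
    cut_height: float = 0.99,
    r2_cut: float = 0.85,
) -> BuildResult:
    """Standard weighted-network construction with hierarchical modules.

    When ``beta`` is None the soft threshold is chosen by the scale-free
    topology criterion; a fixed beta skips the scan (the report then
    contains only that beta, marked as met).
    """
    if beta is None:
        sft = pick_soft_threshold(
            expr, network_type=network_type, r2_cut=r2_cut, method=cor_method
        )
        beta = sft.chosen_beta
    else:
        sft = SFTReport((int(beta),), (float("nan"),), (float("nan"),), int(beta), True)
    cor = correlation_matrix(expr, method=cor_method)
    adj = adjacency(cor, beta, network_type)
    tom = topological_overlap(adj)
    dendro, partition = hierarchical_partition(
        tom,
        min_module_size=min_module_size,
        cut_method=cut_method,
        cut_height=cut_height,
    )
    if partition.n_modules == 0:
        from .errors import DegenerateDataError

        raise DegenerateDataError(
            "no module of the requested minimum size was detected; lower "
            "min_module_size or raise cut_height"
        )
    eigengenes = module_eigengenes(expr, partition)
    membership = module_membership(expr, eigengenes)
    return BuildResult(sft, tom, dendro, partition, eigengenes, membership)
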