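"""Context-specific reference PPI construction.

Public PPI catalogues aggregate interactions from many assay types and cell
contexts, so they are noisy and hub-biased.  The reference network used for
corpus construction therefore keeps only physical interactions whose partners
(i) localise to the nucleus and (ii) are strongly co-expressed in the cell
line under study.

Co-expression follows the weighted co-expression recipe: the absolute Pearson
correlation between gene expression profiles is raised to a soft-threshold
power (5 for MCF7-like data, 6 for K562-like data in the motivating study) to
approximate a scale-free network, a topological overlap measure is computed
from the resulting weights, nodes whose topological connectivity falls below
the median are discarded, and the remaining weighted adjacency is binarised.
Physical PPI edges whose endpoints are not connected in the binarised
co-expression network are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PPIGraph

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionConfig",
    "soft_threshold_adjacency",
    "topological_overlap",
    "filter_low_connectivity",
    "build_reference",
]


@dataclass(frozen=True)
class CoexpressionConfig:
    """Parameters of the co-expression filter.

    soft_power
        Exponent applied to |Pearson correlation| (the soft threshold).
        Distinct from the HDP's per-CMN edge distributions.
    connectivity_quantile
        Nodes with topological connectivity below this quantile of all node
        connectivities are removed (0.5 = the median filter).
    adjacency_cutoff
        A gene pair counts as co-expressed iff its soft-threshold weight is
        >= this cutoff (binarisation of the weighted network).
    tom_connectivity
        If True (default) node connectivity for the quantile filter is the
        TOM row sum; if False, the raw soft-threshold adjacency row sum.
    """

    soft_power: float = 5.0
    connectivity_quantile: float = 0.5
    adjacency_cutoff: float = 0.5
    tom_connectivity: bool = True

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0 < self.connectivity_quantile < 1:
            raise ValueError("connectivity_quantile must be in (0, 1)")
        if not 0 < self.adjacency_cutoff < 1:
            raise ValueError("adjacency_cutoff must be in (0, 1)")


def soft_threshold_adjacency(
    expr: ExpressionMatrix, soft_power: float
) -> pd.DataFrame:
    """Soft-threshold co-expression weights w_ij = |cor(x_i, x_j)|^power.

    Requires >= 3 samples; genes with constant expression have undefined
    correlation and must be removed first (they raise, naming the gene).
    The diagonal is set to 0.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    values = expr.to_numpy(dtype=float)
    stds = values.std(axis=1)
    constant = expr.index[stds == 0.0]
    if len(constant):
        raise ValueError(
            f"constant-expression gene(s) present: {list(constant)[:5]}"
        )
    cor = np.corrcoef(values)
    w = np.abs(cor) ** float(soft_power)
    np.fill_diagonal(w, 0.0)
    w = np.clip(w, 0.0, 1.0)
    return pd.DataFrame(w, index=expr.index, columns=expr.index)


def topological_overlap(w: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Unsigned topological overlap of a weighted adjacency matrix.

    TOM_ij = (sum_u w_iu * w_uj + w_ij) / (min(k_i, k_j) + 1 - w_ij) for
    i != j with k_i the row sum of w; TOM_ii = 1.  Entries lie in [0, 1].
    """
    arr = w.to_numpy(dtype=float) if isinstance(w, pd.DataFrame) else np.asarray(w, float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diagonal(arr) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = arr.sum(axis=1)
    numerator = arr @ arr + arr
    denominator = np.minimum.outer(k, k) + 1.0 - arr
    tom = numerator / denominator
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(w, pd.DataFrame):
        return pd.DataFrame(tom, index=w.index, columns=w.columns)
    return tom


def filter_low_connectivity(
    tom: pd.DataFrame, connectivity_quantile: float = 0.5
) -> list:
    """Names of nodes whose connectivity reaches the given quantile.

    Connectivity is the TOM row sum excluding the diagonal.  Nodes strictly
    below the quantile (default: the median) are removed; ties at the
    threshold are retained.  A single node is always retained.
    """
    arr = tom.to_numpy(dtype=float)
    connectivity = arr.sum(axis=1) - np.diagonal(arr)
    threshold = float(np.quantile(connectivity, connectivity_quantile))
    keep = connectivity >= threshold
    return list(tom.index[keep])


def build_reference(
    ppi: PPIGraph,
    expr: ExpressionMatrix,
    nuclear: set[str],
    cfg: CoexpressionConfig | None = None,
) -> PPIGraph:
    """Build the context-specific reference PPI.

    Steps: restrict the physical PPI to nuclear proteins; compute
    soft-threshold co-expression on the genes shared by the expression matrix
    and the restricted PPI; apply TOM and the low-connectivity filter;
    binarise at ``adjacency_cutoff``; keep only physical edges whose pair is
    co-expressed; drop isolated nodes.

    Gene and protein namespaces are assumed identical (caller's
    responsibility).  Raises if the result is empty.
    """
    cfg = cfg or CoexpressionConfig()
    restricted = ppi.subgraph(n for n in ppi.nodes if n in nuclear).copy()
    genes = [g for g in expr.index if g in restricted.nodes]
    if len(genes) < 2:
        raise ValueError(
            "fewer than 2 genes shared by the expression matrix and the "
            "nuclear-restricted PPI; check namespaces and cutoffs"
        )
    sub_expr = expr.loc[genes]
    # drop constant genes up-front: their correlation is undefined
    variable = sub_expr.index[sub_expr.to_numpy(float).std(axis=1) > 0]
    sub_expr = sub_expr.loc[variable]
    w = soft_threshold_adjacency(sub_expr, cfg.soft_power)
    tom = topological_overlap(w)
    if cfg.tom_connectivity:
        retained = set(filter_low_connectivity(tom, cfg.connectivity_quantile))
    else:
        retained = set(filter_low_connectivity(w, cfg.connectivity_quantile))
    logger.info(
        "connectivity filter retained %d/%d genes", len(retained), w.shape[0]
    )

    out = nx.Graph()
    for a, b in restricted.edges():
        if a in retained and b in retained and w.at[a, b] >= cfg.adjacency_cutoff:
            out.add_edge(a, b)
    if out.number_of_edges() == 0:
        raise ValueError(
            "reference PPI is empty after filtering; consider a lower "
            "adjacency_cutoff or soft_power"
        )
    return out
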