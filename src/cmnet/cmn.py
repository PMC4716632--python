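"""Reportable CMNs: truncation, similarity, enrichment and diagnostics.

A fitted CMN is a distribution ``beta_k`` over the edge vocabulary.  For
reporting, each CMN is truncated to the top edges capturing a chosen fraction
of its cumulative distribution (40-50 % is a reasonable balance between
coverage and background-PPI bias).  CMNs are compared with the
Jensen-Shannon-based similarity sim(p, q) = 1 - JS(p, q) computed with
base-2 logarithms, so the similarity lies exactly in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Vocabulary
from .io import GenomicInterval, Interaction, PPIGraph

logger = logging.getLogger(__name__)

__all__ = [
    "CMN",
    "extract_cmn",
    "extract_all",
    "cmn_similarity",
    "similarity_matrix",
    "top_interactions",
    "assign_genes",
    "degree_bias",
]


@dataclass
class CMN:
    """One inferred chromatin maintainer network.

    selected_edges holds (pair, probability, cumulative) tuples sorted by
    probability descending; nodes is the union of selected edge endpoints.
    """

    index: int
    beta: np.ndarray
    selected_edges: list[tuple[frozenset, float, float]]
    nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if abs(float(self.beta.sum()) - 1.0) > 1e-9:
            raise ValueError("beta must sum to 1 within 1e-9")
        if not self.nodes:
            self.nodes = {n for pair, _, _ in self.selected_edges for n in pair}

    def subgraph(self) -> PPIGraph:
        graph = nx.Graph()
        for pair, _, _ in self.selected_edges:
            a, b = sorted(pair)
            graph.add_edge(a, b)
        return graph


def extract_cmn(beta_k: np.ndarray, vocabulary: Vocabulary, index: int,
                coverage: float = 0.5) -> CMN:
    """Truncate a CMN to the shortest top-edge prefix covering ``coverage``.

    Edges are ranked by probability descending, ties broken by token id
    ascending; the selected prefix is the shortest one whose cumulative
    probability reaches ``coverage``.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    beta_k = np.asarray(beta_k, dtype=float)
    order = sorted(range(beta_k.size), key=lambda t: (-beta_k[t], t))
    selected: list[tuple[frozenset, float, float]] = []
    cum = 0.0
    for tok in order:
        prob = float(beta_k[tok])
        if prob <= 0.0:
            break
        cum += prob
        selected.append((vocabulary.pair_of(tok), prob, cum))
        if cum >= coverage:
            break
    return CMN(index=index, beta=beta_k, selected_edges=selected)


def extract_all(beta: np.ndarray, vocabulary: Vocabulary,
                coverage: float = 0.5) -> list[CMN]:
    """Truncate every row of a (K x V) beta matrix."""
    return [
        extract_cmn(beta[k], vocabulary, index=k, coverage=coverage)
        for k in range(beta.shape[0])
    ]


def _kl_base2(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def cmn_similarity(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon similarity sim(p, q) = 1 - JS(p, q), base-2 logs.

    JS(p, q) = [D(p, m) + D(q, m)] / 2 with m = (p + q) / 2 and the
    convention 0 * log(0/x) = 0.  Symmetric, in [0, 1], sim(p, p) = 1.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share one vocabulary")
    for name, dist in (("p", p), ("q", q)):
        if abs(dist.sum() - 1.0) > 1e-6 or (dist < 0).any():
            raise ValueError(f"{name} is not a probability distribution")
    m = (p + q) / 2.0
    js = 0.5 * (_kl_base2(p, m) + _kl_base2(q, m))
    return float(np.clip(1.0 - js, 0.0, 1.0))


def similarity_matrix(betas: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Pairwise Jensen-Shannon similarity of full beta vectors; diagonal 1."""
    betas = np.asarray(betas, dtype=float)
    K = betas.shape[0]
    sim = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            sim[i, j] = sim[j, i] = cmn_similarity(betas[i], betas[j])
    return sim


def top_interactions(
    theta: pd.DataFrame, k: int, min_enrichment: float = 0.5
) -> list[str]:
    """Interaction ids with theta(k) strictly above ``min_enrichment``."""
    column = theta.iloc[:, k]
    return list(theta.index[column > min_enrichment])


def assign_genes(
    interactions: dict[str, Interaction] | list[Interaction],
    genes: list[tuple[GenomicInterval, str]],
    theta: pd.DataFrame,
    k: int,
    window: int = 2500,
    min_enrichment: float = 0.5,
) -> set[str]:
    """Genes near the anchors of interactions enriched for CMN ``k``.

    For each interaction with theta(k) > min_enrichment, both anchor centres
    +/- ``window`` bp are scanned; genes overlapping either window by >= 1 bp
    are returned (deduplicated union).
    """
    if not isinstance(interactions, dict):
        interactions = {it.id: it for it in interactions}
    hits: set[str] = set()
    for iid in top_interactions(theta, k, min_enrichment):
        interaction = interactions[iid]
        for anchor in (interaction.anchor_a, interaction.anchor_b):
            c = anchor.center
            win = GenomicInterval(anchor.chrom, max(0, c - window), c + window)
            for iv, name in genes:
                if iv.overlaps(win):
                    hits.add(name)
    return hits


def degree_bias(cmn: CMN, ref: PPIGraph, method: str = "pearson") -> float:
    """Correlation between node degrees inside the CMN and in the background.

    A high correlation means the truncated CMN simply mirrors the hub
    structure of the reference PPI rather than the ChIA-PET/ChIP-seq signal.
    Requires >= 3 CMN nodes and non-constant degrees on both sides.
    """
    sub = cmn.subgraph()
    nodes = sorted(sub.nodes)
    if len(nodes) < 3:
        raise ValueError("degree bias needs >= 3 CMN nodes")
    cmn_deg = np.array([sub.degree(n) for n in nodes], dtype=float)
    ref_deg = np.array([ref.degree(n) if n in ref else 0 for n in nodes], dtype=float)
    if cmn_deg.std() == 0 or ref_deg.std() == 0:
        raise ValueError("degree correlation undefined for constant degrees")
    if method == "pearson":
        return float(stats.pearsonr(cmn_deg, ref_deg)[0])
    if method == "spearman":
        return float(stats.spearmanr(cmn_deg, ref_deg)[0])
    raise ValueError(f"unknown method {method!r}")
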