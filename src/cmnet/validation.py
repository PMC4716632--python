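"""Significance machinery for inferred CMNs.

Four families of checks:

* an edge-overlap hypergeometric p-value between two networks, used inside a
  pipeline-level permutation test that rebuilds corpora from shuffled peaks
  and anchor pairings to detect CMNs explained by background-PPI hubs alone;
* an observed-proportion (OP) test of TF enrichment: the fraction of claimed
  interactions whose anchor windows truly contain a held-out ChIP-seq
  signal, with a resampling null over random interaction subsets;
* a generic hypergeometric set-overlap test (literature/annotation gene
  sets, proteomics ground-truth lists) with Benjamini-Hochberg correction;
* multi-class ROC recovery of planted CMN labels through a similarity-based
  mapping between planted and inferred CMNs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from . import cmn as cmn_mod
from . import corpus as corpus_mod
from . import hdp as hdp_mod
from .io import GenomicInterval, Interaction, PeakSet, PPIGraph

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "network_overlap_pvalue",
    "permutation_cmn_test",
    "tf_enrichment_test",
    "hypergeom_overlap",
    "bh_correct",
    "map_cmns",
    "multiclass_auc",
]


@dataclass
class PermutationResult:
    """Outcome of one permutation-based test."""

    observed: float
    null_values: list[float] = field(default_factory=list)
    pvalue: float = float("nan")
    corrected_pvalue: float | None = None
    significant: bool | None = None


def network_overlap_pvalue(edges_a: set[frozenset], edges_b: set[frozenset]) -> float:
    """Upper-tail hypergeometric p-value for the edge overlap of two networks.

    With M the number of nodes in the union of the two networks, the
    population is all E = M(M-1)/2 possible edges; the overlap count c is
    tested as P(X >= c) for X ~ Hypergeom(E, |edges_a|, |edges_b|).
    """
    if not edges_a or not edges_b:
        raise ValueError("both edge sets must be non-empty")
    nodes = {n for e in edges_a for n in e} | {n for e in edges_b for n in e}
    M = len(nodes)
    E = M * (M - 1) // 2
    c = len(edges_a & edges_b)
    return float(stats.hypergeom.sf(c - 1, E, len(edges_a), len(edges_b)))


def hypergeom_overlap(hits: set, annotated: set, universe: set) -> float:
    """Upper-tail hypergeometric overlap of ``hits`` with ``annotated``.

    Population |universe|, successes |annotated|, draws |hits|, observed
    c = |hits & annotated|; returns P(X >= c).
    """
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe or not annotated <= universe:
        raise ValueError("hits and annotated must be subsets of the universe")
    c = len(hits & annotated)
    return float(stats.hypergeom.sf(c - 1, len(universe), len(annotated), len(hits)))


def bh_correct(pvals: list[float] | np.ndarray) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return [float(p) for p in multipletests(arr, method="fdr_bh")[1]]


def _contains_signal(
    interaction: Interaction, signal: list[GenomicInterval], flank: int
) -> bool:
    for anchor in (interaction.anchor_a, interaction.anchor_b):
        window = corpus_mod.anchor_window(anchor, flank)
        for peak in signal:
            if peak.overlaps(window):
                return True
    return False


def tf_enrichment_test(
    claimed: set[str],
    signal: list[GenomicInterval],
    all_interactions: list[Interaction],
    flank: int = corpus_mod.DEFAULT_FLANK,
    n_perm: int = 500,
    seed: int = 0,
) -> PermutationResult:
    """Observed-proportion (OP) enrichment of a ChIP-seq signal.

    OP is the fraction of claimed interactions whose anchor windows contain
    the signal.  The null draws |claimed| interactions uniformly without
    replacement from the full interaction set; the p-value uses the
    (r + 1) / (n + 1) estimator, so it is never exactly 0.
    """
    if not claimed:
        raise ValueError("claimed interaction set is empty")
    by_id = {it.id: it for it in all_interactions}
    if not claimed <= set(by_id):
        raise ValueError("claimed ids must be a subset of all interactions")
    contains = {
        it.id: _contains_signal(it, signal, flank) for it in all_interactions
    }
    observed = sum(contains[i] for i in claimed) / len(claimed)
    rng = np.random.default_rng(seed)
    ids = list(by_id)
    null = []
    for _ in range(n_perm):
        draw = rng.choice(len(ids), size=len(claimed), replace=False)
        null.append(sum(contains[ids[i]] for i in draw) / len(claimed))
    exceed = sum(v >= observed for v in null)
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(observed=observed, null_values=null, pvalue=p)


def _shuffle_inputs(
    interactions: list[Interaction],
    peaks: PeakSet,
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
) -> tuple[list[Interaction], PeakSet]:
    """Random peak positions (length-preserving) + permuted anchor pairings."""
    new_peaks: PeakSet = {}
    for tf, ivs in peaks.items():
        moved = []
        for iv in ivs:
            limit = max(1, chrom_sizes[iv.chrom] - iv.length)
            start = int(rng.integers(0, limit))
            moved.append(GenomicInterval(iv.chrom, start, start + iv.length))
        new_peaks[tf] = moved
    b_perm = rng.permutation(len(interactions))
    shuffled = [
        Interaction(it.id, it.anchor_a, interactions[b_perm[j]].anchor_b)
        for j, it in enumerate(interactions)
    ]
    return shuffled, new_peaks


def permutation_cmn_test(
    interactions: list[Interaction],
    peaks: PeakSet,
    ref: PPIGraph,
    observed_cmns: list[cmn_mod.CMN],
    flank: int = corpus_mod.DEFAULT_FLANK,
    min_frac: float = 0.05,
    max_frac: float = 0.80,
    hdp_cfg: hdp_mod.HDPConfig | None = None,
    coverage: float = 0.5,
    n_perm: int = 1000,
    seed: int = 0,
    flag_alpha: float = 0.05,
    chrom_sizes: dict[str, int] | None = None,
) -> list[PermutationResult]:
    """Pipeline-level permutation test of each observed CMN.

    Per iteration, peak positions are re-drawn uniformly on their chromosome
    (lengths preserved) and anchor pairings are permuted; the corpus is
    rebuilt against the *same* reference PPI and the HDP re-fit (typically
    with reduced sweeps).  Each observed CMN is compared against every null
    CMN via the edge-overlap hypergeometric test on truncated edge sets; the
    per-iteration statistic is the minimum overlap p-value.  A CMN is
    flagged non-significant when the fraction of iterations in which some
    null CMN reconstructs it well (best overlap p < 0.05) exceeds
    ``flag_alpha`` - i.e. the background PPI alone reproduces it.  The
    per-CMN empirical p-values (fraction of good null reconstructions, with
    the +1 correction) are BH-corrected.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    hdp_cfg = hdp_cfg or hdp_mod.HDPConfig(sweeps=100)
    if chrom_sizes is None:
        chrom_sizes = {}
        for it in interactions:
            for iv in (it.anchor_a, it.anchor_b):
                chrom_sizes[iv.chrom] = max(chrom_sizes.get(iv.chrom, 0), iv.end)
        for ivs in peaks.values():
            for iv in ivs:
                chrom_sizes[iv.chrom] = max(chrom_sizes.get(iv.chrom, 0), iv.end)
    rng = np.random.default_rng(seed)
    observed_edge_sets = [
        {pair for pair, _, _ in c.selected_edges} for c in observed_cmns
    ]
    best_ps: list[list[float]] = [[] for _ in observed_cmns]
    degenerate = 0
    for it_idx in range(n_perm):
        shuffled, moved = _shuffle_inputs(interactions, peaks, rng, chrom_sizes)
        null_corpus = corpus_mod.build_corpus(shuffled, moved, ref, flank=flank)
        if len(null_corpus.bags) == 0:
            degenerate += 1
            continue
        try:
            null_corpus = corpus_mod.filter_outlier_edges(
                null_corpus, min_frac, max_frac
            )
        except ValueError:
            degenerate += 1
            continue
        null_cfg = hdp_mod.HDPConfig(
            eta=hdp_cfg.eta,
            gamma=hdp_cfg.gamma,
            alpha=hdp_cfg.alpha,
            sweeps=hdp_cfg.sweeps,
            burnin_sweeps=hdp_cfg.burnin_sweeps,
            burnin_resample_every=hdp_cfg.burnin_resample_every,
            seed=int(rng.integers(0, 2**31 - 1)),
            max_cmns=hdp_cfg.max_cmns,
        )
        state = hdp_mod.gibbs_fit(null_corpus, null_cfg)
        beta = hdp_mod.posterior_beta(state, null_cfg)
        null_cmns = cmn_mod.extract_all(beta, null_corpus.vocabulary, coverage)
        null_edge_sets = [
            {pair for pair, _, _ in c.selected_edges} for c in null_cmns
        ]
        for i, obs_edges in enumerate(observed_edge_sets):
            ps = [
                network_overlap_pvalue(obs_edges, null_edges)
                for null_edges in null_edge_sets
                if null_edges
            ]
            if ps:
                best_ps[i].append(min(ps))
    if degenerate:
        logger.warning("%d/%d null iterations were degenerate", degenerate, n_perm)
    results = []
    for i, cmn in enumerate(observed_cmns):
        ps = best_ps[i]
        n_good = sum(p < 0.05 for p in ps)
        frac_good = n_good / len(ps) if ps else float("nan")
        emp_p = (1 + n_good) / (len(ps) + 1) if ps else float("nan")
        results.append(
            PermutationResult(
                observed=float(len(cmn.selected_edges)),
                null_values=ps,
                pvalue=emp_p,
                significant=not (frac_good > flag_alpha) if ps else None,
            )
        )
    finite = [r.pvalue for r in results if np.isfinite(r.pvalue)]
    if finite:
        corrected = bh_correct(finite)
        it_corr = iter(corrected)
        for r in results:
            if np.isfinite(r.pvalue):
                r.corrected_pvalue = next(it_corr)
    return results


def map_cmns(
    original: np.ndarray | list[np.ndarray],
    inferred: np.ndarray | list[np.ndarray],
) -> dict[int, int]:
    """Similarity-based mapping f(k) = argmax_x sim(original_k, inferred_x).

    Ties are broken by the lowest inferred index (logged).
    """
    original = np.asarray(original, dtype=float)
    inferred = np.asarray(inferred, dtype=float)
    if original.size == 0 or inferred.size == 0:
        raise ValueError("both CMN lists must be non-empty")
    mapping: dict[int, int] = {}
    for k in range(original.shape[0]):
        sims = np.array(
            [cmn_mod.cmn_similarity(original[k], inferred[x]) for x in range(inferred.shape[0])]
        )
        best = int(np.argmax(sims))  # argmax returns the lowest index on ties
        if (sims == sims[best]).sum() > 1:
            logger.info("tie in map_cmns for original CMN %d; lowest index used", k)
        mapping[k] = best
    return mapping


def multiclass_auc(
    true_labels: np.ndarray | list[int],
    theta: np.ndarray,
    f: dict[int, int],
    hand_till: bool = False,
) -> float:
    """Macro one-vs-rest AUC of recovering planted CMN labels.

    Original labels are remapped through ``f`` onto inferred CMN indices;
    class c is scored by theta(., c).  Classes absent after mapping are
    excluded (logged); fewer than 2 remaining classes is an error.  The
    Hand-Till variant averages pairwise AUCs instead.
    """
    labels = np.array([f[int(l)] for l in true_labels])
    theta = np.asarray(theta, dtype=float)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes after mapping")
    if hand_till:
        aucs = []
        for i, ci in enumerate(classes):
            for cj in classes[i + 1 :]:
                mask = (labels == ci) | (labels == cj)
                score = theta[mask, ci]
                aucs.append(roc_auc_score(labels[mask] == ci, score))
        return float(np.mean(aucs))
    aucs = []
    for c in classes:
        if c >= theta.shape[1]:
            logger.info("class %d has no theta column; excluded", c)
            continue
        aucs.append(roc_auc_score(labels == c, theta[:, c]))
    if len(aucs) < 2:
        raise ValueError("need >= 2 scoreable classes")
    return float(np.mean(aucs))
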