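"""Synthetic data: planted-CMN corpora and full genomic fixtures.

Two generators make every pipeline stage testable without downloads:

* :func:`sample_corpus` draws edge bags from planted CMN distributions the
  way the model assumes data arise - per interaction, mixing proportions
  from a Dirichlet, a network size uniform on [10, 200] edges, then each
  edge token from the CMN picked by its indicator.  A ``dominant_only`` mode
  draws all edges from the highest-proportion CMN, giving each bag a sharp
  true label.
* :func:`make_genomic_fixture` emulates the raw inputs: random anchors on a
  synthetic chromosome, per-TF peaks placed near anchor centres with a
  configurable hit probability, a small-world (or planted-module) PPI,
  expression with planted correlated blocks, and a nuclear whitelist - all
  in the on-disk dialects the readers understand.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as io_mod
from .corpus import Corpus, EdgeBag, Vocabulary
from .io import GenomicInterval, Interaction, PeakSet, PPIGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SimTruth",
    "make_planted_cmns",
    "make_pair_vocabulary",
    "sample_corpus",
    "subsample_corpus",
    "GenomicFixture",
    "make_genomic_fixture",
]


@dataclass
class SimTruth:
    """Ground truth of a planted-CMN corpus."""

    planted_cmns: np.ndarray  # K x V
    proportions: np.ndarray  # N x K per-interaction mixing proportions
    labels: np.ndarray  # dominant CMN per interaction (0-based)
    seed: int
    params: dict = field(default_factory=dict)


def make_planted_cmns(
    K: int,
    vocab_size: int,
    concentration: float = 0.1,
    seed: int = 0,
    disjoint: bool = False,
) -> np.ndarray:
    """Draw K planted CMN edge distributions over a vocabulary.

    Each row is a symmetric Dirichlet(concentration) draw.  In ``disjoint``
    mode the vocabulary is split into K contiguous blocks and each CMN's
    support is confined to its own block - a sharp, fully checkable regime.
    """
    if K < 1 or vocab_size < K:
        raise ValueError("need K >= 1 and vocab_size >= K")
    rng = np.random.default_rng(seed)
    betas = np.zeros((K, vocab_size))
    if disjoint:
        bounds = np.linspace(0, vocab_size, K + 1).astype(int)
        for k in range(K):
            lo, hi = bounds[k], bounds[k + 1]
            block = rng.dirichlet(np.full(hi - lo, concentration))
            betas[k, lo:hi] = block
    else:
        for k in range(K):
            betas[k] = rng.dirichlet(np.full(vocab_size, concentration))
    return betas


def make_pair_vocabulary(vocab_size: int) -> Vocabulary:
    """A vocabulary of ``vocab_size`` synthetic protein pairs.

    Pairs are the first ``vocab_size`` combinations of names P000, P001, ...
    so tokens form edges of a graph over a shared protein set.
    """
    n_nodes = 2
    while math.comb(n_nodes, 2) < vocab_size:
        n_nodes += 1
    names = [f"P{i:03d}" for i in range(n_nodes)]
    pairs = [
        frozenset(pair)
        for pair in itertools.islice(itertools.combinations(names, 2), vocab_size)
    ]
    return Vocabulary.from_pairs(pairs)


def sample_corpus(
    n_interactions: int,
    planted: np.ndarray,
    size_range: tuple[int, int] = (10, 200),
    mixing_alpha: float = 1.0,
    seed: int = 0,
    dominant_only: bool = False,
    vocabulary: Vocabulary | None = None,
) -> tuple[Corpus, SimTruth]:
    """Sample a bag-of-edges corpus from planted CMN distributions.

    Per interaction: mixing proportions ~ Dirichlet(mixing_alpha) over the K
    planted CMNs; a network size uniform on ``size_range`` (inclusive); each
    edge slot draws an indicator from the proportions then an edge token
    from the corresponding CMN.  The dominant label is the argmax
    proportion; ``dominant_only`` samples every edge from that CMN.
    """
    if n_interactions < 1:
        raise ValueError("n_interactions must be >= 1")
    planted = np.asarray(planted, dtype=float)
    K, V = planted.shape
    vocabulary = vocabulary or make_pair_vocabulary(V)
    if len(vocabulary) != V:
        raise ValueError("vocabulary size must match planted distributions")
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    proportions = rng.dirichlet(np.full(K, mixing_alpha), size=n_interactions)
    labels = proportions.argmax(axis=1)
    bags = []
    for j in range(n_interactions):
        size = int(rng.integers(lo, hi + 1))
        if dominant_only:
            z = np.full(size, labels[j])
        else:
            z = rng.choice(K, size=size, p=proportions[j])
        counts: dict[int, int] = {}
        for k in z:
            tok = int(rng.choice(V, p=planted[k]))
            counts[tok] = counts.get(tok, 0) + 1
        bags.append(EdgeBag(f"I{j + 1}", counts))
    corpus = Corpus(
        vocabulary=vocabulary,
        bags=bags,
        provenance={
            "simulated": True,
            "K_true": K,
            "size_range": size_range,
            "mixing_alpha": mixing_alpha,
            "dominant_only": dominant_only,
            "seed": seed,
        },
    )
    truth = SimTruth(
        planted_cmns=planted,
        proportions=proportions,
        labels=labels,
        seed=seed,
        params=dict(corpus.provenance),
    )
    return corpus, truth


def subsample_corpus(corpus: Corpus, fraction: float, seed: int = 0) -> Corpus:
    """Uniform without-replacement subsample of ceil(fraction * n) bags.

    Emulates reduced library complexity; the vocabulary is unchanged.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(corpus.bags)
    keep = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(n, size=keep, replace=False).tolist())
    return Corpus(
        vocabulary=corpus.vocabulary,
        bags=[corpus.bags[i] for i in idx],
        provenance={**corpus.provenance, "subsample_fraction": fraction},
    )


@dataclass
class GenomicFixture:
    """In-memory bundle of every pipeline input."""

    interactions: list[Interaction]
    peaks: PeakSet
    ppi: PPIGraph
    expression: pd.DataFrame
    nuclear: set[str]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "interactions": out_dir / "interactions.bedpe",
            "peaks": out_dir / "peaks.bed",
            "ppi": out_dir / "ppi.tsv",
            "expression": out_dir / "expression.tsv",
            "nuclear": out_dir / "nuclear.txt",
        }
        io_mod.write_interactions(self.interactions, paths["interactions"])
        io_mod.write_peaks(self.peaks, paths["peaks"])
        io_mod.write_ppi(self.ppi, paths["ppi"])
        io_mod.write_expression(self.expression, paths["expression"])
        io_mod.write_name_list(self.nuclear, paths["nuclear"])
        return paths


def make_genomic_fixture(
    n_interactions: int = 60,
    n_tfs: int = 12,
    seed: int = 0,
    chrom: str = "chrS",
    chrom_length: int = 5_000_000,
    anchor_size: int = 400,
    hit_probability: float = 0.6,
    peak_max_offset: int = 800,
    peak_size: int = 200,
    ppi_model: str = "small-world",
    n_extra_proteins: int = 24,
    n_expression_samples: int = 12,
    n_coexpression_blocks: int = 3,
    nuclear_fraction: float = 1.0,
) -> GenomicFixture:
    """Generate a full synthetic input bundle.

    Anchors are placed uniformly on one synthetic chromosome; each TF drops a
    peak within ``peak_max_offset`` bp of an anchor centre with probability
    ``hit_probability``.  The PPI covers the TFs plus extra proteins, drawn
    from a Watts-Strogatz small-world graph (``ppi_model='small-world'``) or
    a planted-module graph (``'planted-modules'``).  Expression profiles are
    drawn with ``n_coexpression_blocks`` planted correlated blocks so the
    reference-PPI filter has structure to find.
    """
    rng = np.random.default_rng(seed)
    tf_names = [f"TF{i:02d}" for i in range(n_tfs)]
    extra = [f"NP{i:02d}" for i in range(n_extra_proteins)]
    proteins = tf_names + extra

    interactions = []
    for j in range(n_interactions):
        starts = rng.integers(0, chrom_length - anchor_size, size=2)
        a = GenomicInterval(chrom, int(starts[0]), int(starts[0]) + anchor_size)
        b = GenomicInterval(chrom, int(starts[1]), int(starts[1]) + anchor_size)
        interactions.append(Interaction(f"I{j + 1}", a, b))

    peaks: PeakSet = {tf: [] for tf in tf_names}
    for it in interactions:
        for anchor in (it.anchor_a, it.anchor_b):
            c = anchor.center
            for tf in tf_names:
                if rng.random() < hit_probability:
                    offset = int(rng.integers(-peak_max_offset, peak_max_offset + 1))
                    start = max(0, c + offset - peak_size // 2)
                    peaks[tf].append(
                        GenomicInterval(chrom, start, start + peak_size)
                    )
    peaks = {tf: ivs for tf, ivs in peaks.items()}

    n = len(proteins)
    if ppi_model == "small-world":
        base = nx.connected_watts_strogatz_graph(
            n, k=4, p=0.3, seed=int(rng.integers(0, 2**31 - 1))
        )
    elif ppi_model == "planted-modules":
        sizes = [n // n_coexpression_blocks] * n_coexpression_blocks
        sizes[-1] += n - sum(sizes)
        base = nx.random_partition_graph(
            sizes, 0.7, 0.02, seed=int(rng.integers(0, 2**31 - 1))
        )
    else:
        raise ValueError(f"unknown ppi_model {ppi_model!r}")
    mapping = dict(zip(range(n), proteins))
    ppi = nx.relabel_nodes(base, mapping)

    # expression: planted correlated blocks + noise; blocks are contiguous so
    # they align with the lattice neighbourhoods of the small-world PPI
    block_of = {
        p: i * n_coexpression_blocks // n for i, p in enumerate(proteins)
    }
    signals = rng.normal(size=(n_coexpression_blocks, n_expression_samples))
    values = np.empty((n, n_expression_samples))
    for i, p in enumerate(proteins):
        noise = rng.normal(scale=0.25, size=n_expression_samples)
        values[i] = signals[block_of[p]] + noise
    expression = pd.DataFrame(
        values,
        index=proteins,
        columns=[f"S{i + 1}" for i in range(n_expression_samples)],
    )

    n_nuclear = max(1, int(round(nuclear_fraction * n)))
    nuclear = set(proteins[:n_nuclear])
    return GenomicFixture(interactions, peaks, ppi, expression, nuclear)
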