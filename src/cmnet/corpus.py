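"""Per-interaction local PPI networks and the bag-of-edges corpus.

Each ChIA-PET interaction is turned into a "document": the TFs bound near the
centre of each anchor are connected through the reference PPI by shortest
paths, and every reference edge receives a count equal to the number of
shortest paths (over all anchor-A/anchor-B TF pairs) that traverse it.  The
resulting multiset of edge tokens is the bag of edges handed to the HDP.

Corpus-level filtering then removes outlier edges: tokens present in more
than ``max_frac`` of the bags (hub/shortest-path artefacts and general
co-factors) or fewer than ``min_frac`` (rare or noisy contacts), with strict
inequalities on both sides.
"""

from __future__ import annotations

import hashlib
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io import GenomicInterval, Interaction, PeakSet, PPIGraph

logger = logging.getLogger(__name__)

__all__ = [
    "Vocabulary",
    "EdgeBag",
    "Corpus",
    "anchor_window",
    "assign_tfs",
    "shortest_path_edge_counts",
    "build_local_network",
    "build_corpus",
    "filter_outlier_edges",
    "write_corpus",
    "read_corpus",
    "corpus_checksum",
]

DEFAULT_FLANK = 1500  # bp around the anchor centre; a typical enhancer size


@dataclass
class Vocabulary:
    """Dense bijection between token ids and unordered protein-name pairs."""

    pairs: list[frozenset]
    index: dict[frozenset, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {p: i for i, p in enumerate(self.pairs)}
        if len(self.index) != len(self.pairs):
            raise ValueError("duplicate pairs in vocabulary")

    @classmethod
    def from_pairs(cls, pairs: Iterable[frozenset]) -> "Vocabulary":
        return cls(pairs=list(pairs))

    @classmethod
    def from_graph(cls, graph: PPIGraph) -> "Vocabulary":
        pairs = sorted(
            (frozenset((a, b)) for a, b in graph.edges()),
            key=lambda p: tuple(sorted(p)),
        )
        return cls(pairs=pairs)

    def id_of(self, pair: frozenset) -> int:
        return self.index[pair]

    def pair_of(self, token_id: int) -> frozenset:
        return self.pairs[token_id]

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: frozenset) -> bool:
        return pair in self.index


@dataclass
class EdgeBag:
    """One interaction's local network as a multiset of edge tokens."""

    interaction_id: str
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("bag counts must be >= 1")

    @property
    def size(self) -> int:
        return sum(self.counts.values())


@dataclass
class Corpus:
    """A collection of edge bags over a shared vocabulary."""

    vocabulary: Vocabulary
    bags: list[EdgeBag]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for bag in self.bags:
            if not bag.counts:
                raise ValueError(f"empty bag {bag.interaction_id!r}")
            for tok in bag.counts:
                if not 0 <= tok < len(self.vocabulary):
                    raise ValueError(
                        f"bag {bag.interaction_id!r} uses unknown token {tok}"
                    )

    def __len__(self) -> int:
        return len(self.bags)


def anchor_window(interval: GenomicInterval, flank: int) -> GenomicInterval:
    """Window of +/- ``flank`` bp around the anchor centre, clamped at 0.

    The centre is floor((start + end) / 2); the window is half-open
    ``[max(0, c - flank), c + flank)``.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    c = interval.center
    return GenomicInterval(interval.chrom, max(0, c - flank), c + flank)


def assign_tfs(
    interaction: Interaction, peaks: PeakSet, flank: int
) -> tuple[set[str], set[str]]:
    """TFs whose peaks overlap the centre window of each anchor (>= 1 bp)."""
    window_a = anchor_window(interaction.anchor_a, flank)
    window_b = anchor_window(interaction.anchor_b, flank)
    tfs_a, tfs_b = set(), set()
    for tf, intervals in peaks.items():
        for iv in intervals:
            if tf not in tfs_a and iv.overlaps(window_a):
                tfs_a.add(tf)
            if tf not in tfs_b and iv.overlaps(window_b):
                tfs_b.add(tf)
            if tf in tfs_a and tf in tfs_b:
                break
    return tfs_a, tfs_b


def _bfs_sigma(graph: PPIGraph, source) -> tuple[dict, dict]:
    """BFS distances and shortest-path counts (sigma) from ``source``."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def shortest_path_edge_counts(graph: PPIGraph, s, t) -> dict[frozenset, int]:
    """Per-edge count of s-t shortest paths traversing it.

    An edge (u, v) with d(s,u) + 1 + d(v,t) = d(s,t) is crossed by
    sigma_s(u) * sigma_t(v) shortest paths (sigma = number of shortest paths
    from the subscript endpoint).  Returns an empty map when s == t or when
    no path exists.
    """
    if s == t:
        return {}
    dist_s, sigma_s = _bfs_sigma(graph, s)
    if t not in dist_s:
        return {}
    dist_t, sigma_t = _bfs_sigma(graph, t)
    d = dist_s[t]
    counts: dict[frozenset, int] = {}
    for u, v in graph.edges():
        for a, b in ((u, v), (v, u)):
            if (
                a in dist_s
                and b in dist_t
                and dist_s[a] + 1 + dist_t[b] == d
            ):
                counts[frozenset((u, v))] = (
                    counts.get(frozenset((u, v)), 0) + sigma_s[a] * sigma_t[b]
                )
    return counts


def _single_path_edge_counts(graph: PPIGraph, s, t) -> dict[frozenset, int]:
    """One (deterministic) shortest path per pair: each of its edges counts 1."""
    if s == t:
        return {}
    try:
        path = nx.shortest_path(graph, s, t)
    except nx.NetworkXNoPath:
        return {}
    return {frozenset((a, b)): 1 for a, b in zip(path, path[1:])}


def build_local_network(
    tfs_a: set[str],
    tfs_b: set[str],
    ref: PPIGraph,
    single_path: bool = False,
) -> dict[frozenset, int]:
    """Edge counts of the local network connecting the two anchor TF sets.

    TFs absent from the reference graph are dropped.  Every unordered pair
    {s, t} with s in A and t in B (s != t) contributes the shortest-path
    traversal counts of its edges; a pair is counted once even when both
    memberships hold in both directions.  Pairs in different components
    contribute nothing.  An empty result signals that the interaction should
    be dropped upstream.
    """
    a = {tf for tf in tfs_a if tf in ref}
    b = {tf for tf in tfs_b if tf in ref}
    pairs = {frozenset((s, t)) for s in a for t in b if s != t}
    counter = _single_path_edge_counts if single_path else shortest_path_edge_counts
    counts: dict[frozenset, int] = {}
    for pair in sorted(pairs, key=lambda p: tuple(sorted(p))):
        s, t = sorted(pair)
        for edge, c in counter(ref, s, t).items():
            counts[edge] = counts.get(edge, 0) + c
    return counts


def build_corpus(
    interactions: Sequence[Interaction],
    peaks: PeakSet,
    ref: PPIGraph,
    flank: int = DEFAULT_FLANK,
    single_path: bool = False,
) -> Corpus:
    """Build the bag-of-edges corpus for a set of interactions.

    Interactions recruiting no connected TF pair (empty bag) are dropped and
    counted in ``provenance['n_dropped']``.
    """
    vocab = Vocabulary.from_graph(ref)
    bags: list[EdgeBag] = []
    dropped = 0
    for interaction in interactions:
        tfs_a, tfs_b = assign_tfs(interaction, peaks, flank)
        edge_counts = build_local_network(tfs_a, tfs_b, ref, single_path=single_path)
        if not edge_counts:
            dropped += 1
            continue
        counts = {vocab.id_of(edge): c for edge, c in edge_counts.items()}
        bags.append(EdgeBag(interaction.id, counts))
    if dropped:
        logger.info("dropped %d/%d interactions with empty bags", dropped, len(interactions))
    provenance = {
        "flank": flank,
        "single_path": single_path,
        "n_input_interactions": len(interactions),
        "n_dropped": dropped,
    }
    return Corpus(vocabulary=vocab, bags=bags, provenance=provenance)


def filter_outlier_edges(
    corpus: Corpus, min_frac: float = 0.05, max_frac: float = 0.80
) -> Corpus:
    """Remove tokens with document frequency > max_frac or < min_frac.

    Document frequency df(e) is the fraction of bags containing the token at
    least once; both inequalities are strict, so a token sitting exactly on a
    threshold is kept.  The vocabulary is re-indexed densely and bags that
    become empty are dropped (counted in provenance).
    """
    if not 0 <= min_frac < max_frac <= 1:
        raise ValueError("need 0 <= min_frac < max_frac <= 1")
    n_bags = len(corpus.bags)
    if n_bags == 0:
        raise ValueError("empty corpus")
    df: dict[int, int] = {}
    for bag in corpus.bags:
        for tok in bag.counts:
            df[tok] = df.get(tok, 0) + 1
    keep = set()
    for tok in range(len(corpus.vocabulary)):
        frac = df.get(tok, 0) / n_bags
        if not (frac > max_frac or frac < min_frac):
            keep.add(tok)
    # dense re-index preserving the original token order
    kept_sorted = sorted(keep)
    remap = {old: new for new, old in enumerate(kept_sorted)}
    new_vocab = Vocabulary.from_pairs(corpus.vocabulary.pair_of(t) for t in kept_sorted)
    new_bags: list[EdgeBag] = []
    dropped = 0
    for bag in corpus.bags:
        counts = {remap[t]: c for t, c in bag.counts.items() if t in remap}
        if counts:
            new_bags.append(EdgeBag(bag.interaction_id, counts))
        else:
            dropped += 1
    if not new_bags:
        raise ValueError("all bags empty after outlier filtering")
    if dropped:
        logger.info("outlier filtering dropped %d bags", dropped)
    n_removed = len(corpus.vocabulary) - len(new_vocab)
    logger.info(
        "outlier filtering removed %d/%d vocabulary edges",
        n_removed,
        len(corpus.vocabulary),
    )
    provenance = dict(corpus.provenance)
    provenance.update(
        {
            "min_frac": min_frac,
            "max_frac": max_frac,
            "n_tokens_removed": n_removed,
            "n_bags_dropped_by_filter": dropped,
        }
    )
    return Corpus(vocabulary=new_vocab, bags=new_bags, provenance=provenance)


def write_corpus(corpus: Corpus, vocab_path: str | Path, bags_path: str | Path) -> None:
    """Serialise as a vocabulary TSV and a (interaction, token, count) TSV."""
    with open(vocab_path, "w", encoding="utf-8") as handle:
        handle.write("token_id\tprotein_a\tprotein_b\n")
        for tok in range(len(corpus.vocabulary)):
            a, b = sorted(corpus.vocabulary.pair_of(tok))
            handle.write(f"{tok}\t{a}\t{b}\n")
    with open(bags_path, "w", encoding="utf-8") as handle:
        handle.write("interaction_id\ttoken_id\tcount\n")
        for bag in corpus.bags:
            for tok in sorted(bag.counts):
                handle.write(f"{bag.interaction_id}\t{tok}\t{bag.counts[tok]}\n")


def read_corpus(vocab_path: str | Path, bags_path: str | Path) -> Corpus:
    pairs: list[frozenset] = []
    with open(vocab_path, encoding="utf-8") as handle:
        next(handle)
        for line in handle:
            tok, a, b = line.rstrip("\n").split("\t")
            if int(tok) != len(pairs):
                raise ValueError("vocabulary token ids must be dense and ordered")
            pairs.append(frozenset((a, b)))
    vocab = Vocabulary.from_pairs(pairs)
    bags_by_id: dict[str, dict[int, int]] = {}
    order: list[str] = []
    with open(bags_path, encoding="utf-8") as handle:
        next(handle)
        for line in handle:
            iid, tok, count = line.rstrip("\n").split("\t")
            if iid not in bags_by_id:
                bags_by_id[iid] = {}
                order.append(iid)
            bags_by_id[iid][int(tok)] = int(count)
    bags = [EdgeBag(iid, bags_by_id[iid]) for iid in order]
    return Corpus(vocabulary=vocab, bags=bags)


def corpus_checksum(corpus: Corpus) -> str:
    """Deterministic SHA-256 over the canonical corpus serialisation."""
    digest = hashlib.sha256()
    for tok in range(len(corpus.vocabulary)):
        a, b = sorted(corpus.vocabulary.pair_of(tok))
        digest.update(f"{tok}\t{a}\t{b}\n".encode())
    for bag in corpus.bags:
        for tok in sorted(bag.counts):
            digest.update(f"{bag.interaction_id}\t{tok}\t{bag.counts[tok]}\n".encode())
    return digest.hexdigest()
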