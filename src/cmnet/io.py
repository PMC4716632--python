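"""Genomic/network primitives and readers/writers for every on-disk format.

Conventions used throughout the package:

* genomic coordinates are 0-based, half-open ``[start, end)``;
* strand is ignored;
* all text files are UTF-8, tab-separated, with ``#`` comment lines;
* protein-protein interaction (PPI) graphs are undirected simple graphs
  (:class:`networkx.Graph`) with protein names as nodes;
* expression matrices are :class:`pandas.DataFrame` objects with genes as
  rows and samples as columns.

Interactions are read from a BEDPE-style dialect: at least six tab-separated
columns ``chrom1 start1 end1 chrom2 start2 end2`` with an optional seventh
name column; further columns are ignored.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Interaction",
    "PeakSet",
    "PPIGraph",
    "ExpressionMatrix",
    "read_interactions",
    "write_interactions",
    "read_bed",
    "read_named_bed",
    "read_peaks",
    "read_peaks_bed",
    "write_peaks",
    "read_ppi",
    "write_ppi",
    "read_expression",
    "write_expression",
    "read_name_list",
    "write_name_list",
    "write_cmns",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(requires start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Interaction:
    """One ChIA-PET DNA-DNA interaction: a pair of anchor intervals.

    Anchors may lie on the same or different chromosomes.
    """

    id: str
    anchor_a: GenomicInterval
    anchor_b: GenomicInterval


# A PeakSet maps a TF name to its ChIP-seq peak intervals.
PeakSet = dict[str, list[GenomicInterval]]

# Undirected simple graph over protein names.
PPIGraph = nx.Graph

# Genes x samples numeric matrix.
ExpressionMatrix = pd.DataFrame


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _parse_coord(text: str, path: Path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: non-integer coordinate {text!r}"
        ) from None


def _interval_from_fields(
    chrom: str, start: str, end: str, path: Path, lineno: int
) -> GenomicInterval:
    s = _parse_coord(start, path, lineno)
    e = _parse_coord(end, path, lineno)
    try:
        return GenomicInterval(chrom, s, e)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from None


def read_interactions(path: str | Path) -> list[Interaction]:
    """Read ChIA-PET interactions from a BEDPE-style file.

    Each data line needs >= 6 columns; column 7, when present, supplies the
    interaction id, otherwise ``I<line-number>`` is used.  Ids must be unique.
    """
    path = Path(path)
    out: list[Interaction] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(
                f"{path}:{lineno}: expected >= 6 tab-separated columns, "
                f"got {len(fields)}"
            )
        a = _interval_from_fields(fields[0], fields[1], fields[2], path, lineno)
        b = _interval_from_fields(fields[3], fields[4], fields[5], path, lineno)
        iid = fields[6] if len(fields) >= 7 and fields[6] else f"I{lineno}"
        if iid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate interaction id {iid!r}")
        seen.add(iid)
        out.append(Interaction(iid, a, b))
    return out


def write_interactions(interactions: Sequence[Interaction], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for it in interactions:
            a, b = it.anchor_a, it.anchor_b
            handle.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t"
                f"{b.chrom}\t{b.start}\t{b.end}\t{it.id}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file as a list of intervals (columns beyond 3 ignored)."""
    path = Path(path)
    out = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
        out.append(_interval_from_fields(fields[0], fields[1], fields[2], path, lineno))
    return out


def read_named_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read a BED file whose 4th column carries a feature name (e.g. genes)."""
    path = Path(path)
    out = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected >= 4 columns (name in col 4)")
        iv = _interval_from_fields(fields[0], fields[1], fields[2], path, lineno)
        out.append((iv, fields[3]))
    return out


def read_peaks(
    paths: Mapping[str, str | Path] | Iterable[tuple[str, str | Path]],
) -> PeakSet:
    """Read per-TF BED3+ peak files keyed by TF name.

    ``paths`` may be a mapping or an iterable of ``(tf_name, path)`` pairs;
    duplicate TF names raise.  Overlapping peaks are preserved as-is.
    """
    items = list(paths.items()) if isinstance(paths, Mapping) else list(paths)
    peaks: PeakSet = {}
    for tf, p in items:
        if tf in peaks:
            raise ValueError(f"duplicate TF name {tf!r}")
        peaks[tf] = read_bed(p)
    return peaks


def read_peaks_bed(path: str | Path) -> PeakSet:
    """Read a single BED file with the TF name in column 4."""
    peaks: PeakSet = {}
    for iv, tf in read_named_bed(path):
        peaks.setdefault(tf, []).append(iv)
    return peaks


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as a single BED file with the TF name in column 4."""
    with open(path, "w", encoding="utf-8") as handle:
        for tf in sorted(peaks):
            for iv in peaks[tf]:
                handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{tf}\n")


def read_ppi(path: str | Path) -> PPIGraph:
    """Read a 2-column TSV of protein pairs into an undirected simple graph.

    Reversed duplicates collapse to one edge; self-loops are dropped with a
    logged warning; a single-column line is an error.
    """
    path = Path(path)
    graph = nx.Graph()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        a, b = fields[0], fields[1]
        if a == b:
            logger.warning("%s:%d: dropping self-loop %s-%s", path, lineno, a, b)
            continue
        graph.add_edge(a, b)
    return graph


def write_ppi(graph: PPIGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            handle.write(f"{a}\t{b}\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (header row of sample names, gene column 1)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene name(s): {sorted(set(dup))}")
    return frame.astype(float)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_csv(path, sep="\t")


def read_name_list(path: str | Path) -> set[str]:
    """Read a one-name-per-line list (deduplicated)."""
    names = set()
    for _, line in _data_lines(Path(path)):
        names.add(line.strip())
    return names


def write_name_list(names: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name in sorted(set(names)):
            handle.write(f"{name}\n")


def _edge_label(pair: frozenset) -> tuple[str, str]:
    a, b = sorted(pair)
    return a, b


def write_cmns(
    cmns,
    vocabulary,
    theta: pd.DataFrame,
    out_dir: str | Path,
    params: Mapping[str, object] | None = None,
    seed: int | None = None,
    corpus_checksum: str | None = None,
) -> list[Path]:
    """Write fitted results: one TSV per CMN, the theta matrix, and metadata.

    Each CMN file lists every vocabulary edge sorted by probability
    (descending), with its probability, running cumulative probability and a
    0/1 flag marking membership in the truncated (selected) edge set.  Theta
    rows are checked to sum to 1 within 1e-9.  The metadata file records all
    parameters and the seed so a run is reproducible; no timestamps are
    written, so re-running with the same seed yields byte-identical output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for cmn in cmns:
        path = out_dir / f"cmn_{cmn.index + 1:02d}.tsv"
        selected = {pair for pair, _, _ in cmn.selected_edges}
        order = sorted(range(len(cmn.beta)), key=lambda t: (-cmn.beta[t], t))
        cum = 0.0
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("protein_a\tprotein_b\tprobability\tcumulative\tselected\n")
            for tok in order:
                cum += float(cmn.beta[tok])
                a, b = _edge_label(vocabulary.pair_of(tok))
                flag = 1 if vocabulary.pair_of(tok) in selected else 0
                handle.write(f"{a}\t{b}\t{cmn.beta[tok]:.10g}\t{cum:.10g}\t{flag}\n")
        written.append(path)

    sums = theta.sum(axis=1)
    if (sums - 1.0).abs().max() > 1e-9:
        raise ValueError("theta rows must sum to 1 within 1e-9")
    theta_path = out_dir / "theta.tsv"
    theta.to_csv(theta_path, sep="\t", float_format="%.10g")
    written.append(theta_path)

    meta_path = out_dir / "run_metadata.txt"
    with open(meta_path, "w", encoding="utf-8") as handle:
        handle.write(f"n_cmns\t{len(list(cmns))}\n")
        handle.write(f"vocabulary_size\t{len(vocabulary)}\n")
        if seed is not None:
            handle.write(f"seed\t{seed}\n")
        if corpus_checksum is not None:
            handle.write(f"corpus_checksum\t{corpus_checksum}\n")
        for key in sorted(params or {}):
            handle.write(f"{key}\t{params[key]}\n")
    written.append(meta_path)
    return written


def file_checksum(path: str | Path) -> str:
    """SHA-256 checksum of a file, for provenance metadata."""
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()
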