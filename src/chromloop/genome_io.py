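"""Readers/writers for FASTA/BED/BEDPE/bedGraph and the interval algebra.

All coordinates follow the BED convention: 0-based, half-open. A chromatin
interaction is represented as an :class:`AnchorPair` — two same-chromosome
intervals ("anchors") with a midpoint-to-midpoint distance, an optional label
(positive / negative / unknown) and an optional probability score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "AnchorPair",
    "GenomeSequence",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_bedgraph",
    "write_bedgraph",
    "fetch_sequence",
    "reverse_complement",
    "merge_and_extend",
    "pair_distance",
]


class BedParseError(ValueError):
    """Malformed BED/BEDPE record (names the offending line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open chromosome span.

    ``annotations`` preserves any extra BED columns (name, score, the
    narrowPeak statistics, ...) verbatim.
    """

    chrom: str
    start: int
    end: int
    strand: str | None = None
    annotations: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with ``other`` (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def pair_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Midpoint-to-midpoint distance in bp between two same-chromosome spans."""
    if a.chrom != b.chrom:
        raise ValueError(f"pair_distance across chromosomes: {a.chrom} vs {b.chrom}")
    return abs(a.midpoint - b.midpoint)


@dataclass(frozen=True)
class AnchorPair:
    """Two same-chromosome anchors plus distance, label and optional score.

    Anchors are normalized so ``left.start <= right.start``. Inter-chromosomal
    pairs read from a BEDPE are retained but flagged (``interchromosomal``)
    and excluded by all downstream dataset construction.
    """

    left: GenomicInterval
    right: GenomicInterval
    label: str = "unknown"
    score: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative", "unknown"):
            raise ValueError(f"invalid label {self.label!r}")
        if not self.interchromosomal and self.left.start > self.right.start:
            left, right = self.left, self.right
            object.__setattr__(self, "left", right)
            object.__setattr__(self, "right", left)

    @property
    def interchromosomal(self) -> bool:
        return self.left.chrom != self.right.chrom

    @property
    def chrom(self) -> str:
        return self.left.chrom

    @property
    def distance(self) -> int:
        return pair_distance(self.left, self.right)

    def key(self) -> tuple:
        return self.left.key() + self.right.key()

    @property
    def id(self) -> str:
        """Canonical string key, e.g. ``chr1:100-600|chr1:50100-50600``."""
        return (
            f"{self.left.chrom}:{self.left.start}-{self.left.end}"
            f"|{self.right.chrom}:{self.right.start}-{self.right.end}"
        )

    def with_label(self, label: str) -> "AnchorPair":
        return replace(self, label=label)

    def with_score(self, score: float) -> "AnchorPair":
        return replace(self, score=score)


_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N is a fixed point)."""
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"unknown nucleotide(s) {sorted(bad)} in sequence")
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


class GenomeSequence:
    """Per-chromosome nucleotide strings with bounds-checked fetch.

    Sequences are stored uppercased with any character outside {A,C,G,T}
    mapped to N. Construct in memory from a dict or from a FASTA file
    (indexed via pyfaidx).
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for chrom, seq in sequences.items():
            s = seq.upper()
            s = "".join(c if c in _VALID else "N" for c in s) if set(s) - _VALID else s
            self._seqs[chrom] = s

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def fetch(self, iv: GenomicInterval) -> str:
        if iv.chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        seq = self._seqs[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} out of bounds "
                f"(chromosome length {len(seq)})"
            )
        return seq[iv.start : iv.end]


def fetch_sequence(genome: GenomeSequence, iv: GenomicInterval) -> str:
    """Uppercase sequence of ``iv``; non-ACGT characters are N."""
    return genome.fetch(iv)


# ---------------------------------------------------------------------------
# BED / BEDPE / bedGraph I/O


def _split_line(line: str, lineno: int, min_cols: int, what: str) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_cols:
        raise BedParseError(
            f"{what} line {lineno}: expected >= {min_cols} columns, got {len(fields)}"
        )
    return fields


def _parse_coord(value: str, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise BedParseError(f"{what} line {lineno}: non-integer coordinate {value!r}")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse a BED3+ / narrowPeak file, preserving extra columns and order."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_line(line, lineno, 3, "BED")
            start = _parse_coord(f[1], lineno, "BED")
            end = _parse_coord(f[2], lineno, "BED")
            if start >= end or start < 0:
                raise BedParseError(
                    f"BED line {lineno}: invalid interval {f[0]}:{start}-{end}"
                )
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else None
            out.append(
                GenomicInterval(f[0], start, end, strand, tuple(f[3:]))
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), *iv.annotations]
            fh.write("\t".join(cols) + "\n")


def read_bedpe(path: str | Path) -> list[AnchorPair]:
    """Parse a BEDPE loop file (>=6 columns; column 8, if present, is a score).

    Intra-chromosomal pairs are normalized to genomic order. Inter-chromosomal
    rows are retained (flagged via :attr:`AnchorPair.interchromosomal`).
    """
    out: list[AnchorPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _split_line(line, lineno, 6, "BEDPE")
            coords = [_parse_coord(x, lineno, "BEDPE") for x in (f[1], f[2], f[4], f[5])]
            s1, e1, s2, e2 = coords
            if s1 >= e1 or s2 >= e2 or min(s1, s2) < 0:
                raise BedParseError(f"BEDPE line {lineno}: invalid anchor coordinates")
            score = None
            if len(f) > 7 and f[7] not in (".", ""):
                try:
                    score = float(f[7])
                except ValueError:
                    raise BedParseError(f"BEDPE line {lineno}: bad score {f[7]!r}")
            out.append(
                AnchorPair(
                    GenomicInterval(f[0], s1, e1),
                    GenomicInterval(f[3], s2, e2),
                    score=score,
                )
            )
    return out


def write_bedpe(pairs: Iterable[AnchorPair], path: str | Path) -> None:
    """Write pairs as 8-column BEDPE (name '.', score or '.')."""
    with open(path, "w") as fh:
        for p in pairs:
            score = "." if p.score is None else f"{p.score:.6g}"
            fh.write(
                "\t".join(
                    [
                        p.left.chrom,
                        str(p.left.start),
                        str(p.left.end),
                        p.right.chrom,
                        str(p.right.start),
                        str(p.right.end),
                        p.sample_id or ".",
                        score,
                    ]
                )
                + "\n"
            )


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """Read a 4-column bedGraph into per-chromosome (start, end, value) arrays.

    Returns ``{chrom: array of shape (n, 3)}`` sorted by start. Overlapping
    segments within one chromosome are an error (signal would be ambiguous).
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _split_line(line, lineno, 4, "bedGraph")
            start = _parse_coord(f[1], lineno, "bedGraph")
            end = _parse_coord(f[2], lineno, "bedGraph")
            if start >= end:
                raise BedParseError(f"bedGraph line {lineno}: start >= end")
            per_chrom.setdefault(f[0], []).append((start, end, float(f[3])))
    out: dict[str, np.ndarray] = {}
    for chrom, rows in per_chrom.items():
        arr = np.array(sorted(rows), dtype=float)
        if np.any(arr[1:, 0] < arr[:-1, 1]):
            raise ValueError(f"bedGraph: overlapping segments on {chrom}")
        out[chrom] = arr
    return out


def write_bedgraph(track: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track:
            for start, end, value in track[chrom]:
                fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# Interval algebra


def merge_and_extend(
    intervals: Sequence[GenomicInterval],
    merge_distance: int,
    extension: int,
    chrom_lengths: Mapping[str, int],
) -> list[GenomicInterval]:
    """Merge nearby intervals and extend the merged spans.

    Per chromosome: sort by start; intervals whose gap (``next.start -
    current.end``) is <= ``merge_distance`` are unioned transitively; each
    merged span is then extended by ``extension`` bp on both sides and clamped
    to ``[0, chromosome length)``. Output is sorted by (chrom, start).
    """
    if merge_distance < 0 or extension < 0:
        raise ValueError("merge_distance and extension must be >= 0")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        merged: list[list[int]] = []
        for iv in ivs:
            if merged and iv.start - merged[-1][1] <= merge_distance:
                merged[-1][1] = max(merged[-1][1], iv.end)
            else:
                merged.append([iv.start, iv.end])
        clen = chrom_lengths[chrom]
        for start, end in merged:
            out.append(
                GenomicInterval(
                    chrom, max(0, start - extension), min(clen, end + extension)
                )
            )
    return out


class IntervalIndex:
    """Per-chromosome overlap queries over a fixed interval set.

    Linear scan over sorted starts with a running max-end bound; adequate for
    the anchor/peak set sizes this package handles.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.intervals = list(intervals)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(self.intervals):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            idx = sorted(idx, key=lambda i: self.intervals[i].start)
            starts = np.array([self.intervals[i].start for i in idx])
            ends = np.array([self.intervals[i].end for i in idx])
            self._by_chrom[chrom] = (starts, ends, np.array(idx))

    def overlapping(self, iv: GenomicInterval, min_overlap: int = 1) -> list[int]:
        """Indices (into the original list) of intervals overlapping ``iv``."""
        if iv.chrom not in self._by_chrom:
            return []
        starts, ends, idx = self._by_chrom[iv.chrom]
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        return [int(i) for i in idx[ov >= min_overlap]]

    def any_overlap(self, iv: GenomicInterval, min_overlap: int = 1) -> bool:
        if iv.chrom not in self._by_chrom:
            return False
        starts, ends, _ = self._by_chrom[iv.chrom]
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        return bool(np.any(ov >= min_overlap))
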