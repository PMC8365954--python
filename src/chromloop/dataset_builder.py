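"""Construction of the three dataset tiers used to train interaction models.

Tier 1 — *distance-matched*: positives from a loop file, negatives sampled so
that their genomic-distance distribution matches the positives (the classifier
cannot win on distance alone). Tier 2 — *extended*: the same positives with
many more negatives, distance-matched only loosely (uniform over the positive
distance range). Tier 3 — *from open chromatin*: all candidate anchor pairs
built from open-chromatin peaks by merge-and-extend, labeled against known
loops; this is the genome-wide prediction setting with extreme class
imbalance.

Splits are by chromosome holdout: anchors never cross the train/validation/
test boundary, avoiding the leakage of random cross-validation on overlapping
anchor sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    AnchorPair,
    GenomicInterval,
    IntervalIndex,
    merge_and_extend,
)

__all__ = [
    "DatasetSplit",
    "extract_positive_pairs",
    "sample_distance_matched_negatives",
    "build_extended_negatives",
    "build_anchors_from_open_chromatin",
    "enumerate_and_label_pairs",
    "split_by_chromosome",
    "pairs_to_frame",
    "frame_to_pairs",
    "write_dataset",
    "read_dataset",
]

DEFAULT_MERGE_DISTANCE = 3000
DEFAULT_EXTENSION = 1000
DEFAULT_RATIO = 5
DEFAULT_EXTENDED_RATIO = 25
DEFAULT_MAX_SPAN = 2_000_000
DEFAULT_N_BINS = 50


@dataclass(frozen=True)
class DatasetSplit:
    """Chromosome-holdout split. The three sets must be pairwise disjoint."""

    train: frozenset[str]
    validation: frozenset[str] = frozenset()
    test: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for a, b in (
            (self.train, self.validation),
            (self.train, self.test),
            (self.validation, self.test),
        ):
            common = set(a) & set(b)
            if common:
                raise ValueError(f"split sets overlap on {sorted(common)}")

    @classmethod
    def default(cls, chromosomes: Sequence[str]) -> "DatasetSplit":
        """Hold out chr5+chr14 for test and chr4 for validation when present;
        otherwise the last two / third-last chromosomes."""
        chroms = list(chromosomes)
        test = {c for c in ("chr5", "chr14") if c in chroms}
        if not test:
            test = set(chroms[-2:])
        val = {c for c in ("chr4",) if c in chroms and c not in test}
        if not val:
            remaining = [c for c in chroms if c not in test]
            val = set(remaining[-1:])
        train = {c for c in chroms if c not in test | val}
        return cls(frozenset(train), frozenset(val), frozenset(test))

    def assign(self, chrom: str) -> str:
        if chrom in self.train:
            return "train"
        if chrom in self.validation:
            return "validation"
        if chrom in self.test:
            return "test"
        raise KeyError(f"chromosome {chrom!r} not present in any split set")


def extract_positive_pairs(
    loops: Sequence[AnchorPair],
    open_regions: Sequence[GenomicInterval] | None = None,
) -> list[AnchorPair]:
    """Positive interactions: intra-chromosomal, deduplicated, and (optionally)
    with both anchors overlapping at least one open-chromatin region."""
    index = IntervalIndex(open_regions) if open_regions is not None else None
    seen: set[tuple] = set()
    out: list[AnchorPair] = []
    for pair in loops:
        if pair.interchromosomal:
            continue
        if index is not None and not (
            index.any_overlap(pair.left) and index.any_overlap(pair.right)
        ):
            continue
        key = pair.key()
        if key in seen:
            continue
        seen.add(key)
        out.append(pair.with_label("positive"))
    if not out:
        warnings.warn("no positive pairs after filtering", stacklevel=2)
    return out


def regions_without_loop_anchors(
    regions: Sequence[GenomicInterval], loops: Sequence[AnchorPair]
) -> list[GenomicInterval]:
    """Open regions that overlap no anchor of any known loop.

    The preferred negative-candidate pool: anchors of observed loops often
    interact with additional, unobserved partners, so re-pairings of true
    anchors are enriched for false negatives.
    """
    anchors = [p.left for p in loops] + [p.right for p in loops]
    index = IntervalIndex(anchors)
    return [iv for iv in regions if not index.any_overlap(iv)]


class _AnchorPool:
    """Candidate anchors per chromosome with midpoint-range queries."""

    def __init__(self, anchors: Sequence[GenomicInterval]):
        self.by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in anchors:
            self.by_chrom.setdefault(iv.chrom, []).append(iv)
        self.mids: dict[str, np.ndarray] = {}
        for chrom, ivs in self.by_chrom.items():
            ivs.sort(key=lambda x: (x.start, x.end))
            self.mids[chrom] = np.array([iv.midpoint for iv in ivs])
        self.chroms = sorted(self.by_chrom)
        self.weights = np.array([len(self.by_chrom[c]) for c in self.chroms], float)
        self.weights /= self.weights.sum()

    def partners_in_range(
        self, chrom: str, anchor_idx: int, lo: float, hi: float
    ) -> np.ndarray:
        """Indices of anchors whose midpoint distance from anchor_idx lies in
        [lo, hi)."""
        mids = self.mids[chrom]
        m = mids[anchor_idx]
        left = np.searchsorted(mids, (m - hi, m - lo), side="left")
        right = np.searchsorted(mids, (m + lo, m + hi), side="left")
        cand = np.concatenate(
            [np.arange(left[0], left[1]), np.arange(right[0], right[1])]
        )
        return cand[cand != anchor_idx]


def _make_pair(a: GenomicInterval, b: GenomicInterval, label: str) -> AnchorPair:
    left, right = (a, b) if a.start <= b.start else (b, a)
    return AnchorPair(left, right, label=label)


def sample_distance_matched_negatives(
    positives: Sequence[AnchorPair],
    ratio: int = DEFAULT_RATIO,
    n_bins: int = DEFAULT_N_BINS,
    seed: int = 0,
    anchors: Sequence[GenomicInterval] | None = None,
) -> list[AnchorPair]:
    """Sample negative pairs whose distance distribution matches the positives.

    Positive distances are binned into ``n_bins`` log10-spaced bins; each bin
    contributes ``ratio`` times its positive count in negatives, drawn without
    replacement from same-chromosome re-pairings of the candidate anchor set.
    Candidates identical to a positive are excluded. Bins whose candidate pool
    is exhausted re-allocate their deficit to neighboring bins (warned).

    Parameters
    ----------
    anchors
        Candidate anchor set for re-pairing. Defaults to the anchors of the
        positives themselves; pass the open-chromatin region set to draw
        negatives from the full accessible landscape.
    """
    if not positives:
        raise ValueError("positives must be non-empty")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    if anchors is None:
        dedup: dict[tuple, GenomicInterval] = {}
        for p in positives:
            dedup.setdefault(p.left.key(), p.left)
            dedup.setdefault(p.right.key(), p.right)
        anchors = list(dedup.values())
    pool = _AnchorPool(anchors)

    dists = np.array([p.distance for p in positives], float)
    dists = np.maximum(dists, 1.0)
    log_d = np.log10(dists)
    edges = np.linspace(log_d.min(), log_d.max() + 1e-9, n_bins + 1)
    bin_of = np.clip(np.digitize(log_d, edges) - 1, 0, n_bins - 1)
    needed = np.bincount(bin_of, minlength=n_bins) * ratio

    forbidden = {p.key() for p in positives}
    chosen: dict[tuple, AnchorPair] = {}

    def try_fill(b: int, count: int, widen: float = 1.0) -> int:
        """Attempt to draw ``count`` negatives in bin ``b``; returns deficit."""
        lo = 10 ** edges[b] / widen
        hi = 10 ** edges[b + 1] * widen
        deficit = count
        attempts = 0
        max_attempts = 60 * count + 60
        while deficit > 0 and attempts < max_attempts:
            attempts += 1
            chrom = pool.chroms[rng.choice(len(pool.chroms), p=pool.weights)]
            ivs = pool.by_chrom[chrom]
            if len(ivs) < 2:
                continue
            i = int(rng.integers(len(ivs)))
            cand = pool.partners_in_range(chrom, i, lo, hi)
            if cand.size == 0:
                continue
            j = int(cand[rng.integers(cand.size)])
            pair = _make_pair(ivs[i], ivs[j], "negative")
            key = pair.key()
            if key in forbidden or key in chosen:
                continue
            chosen[key] = pair
            deficit -= 1
        return deficit

    total_deficit = 0
    for b in range(n_bins):
        if needed[b] == 0:
            continue
        total_deficit += try_fill(b, int(needed[b]))
    if total_deficit > 0:
        # re-allocate to neighboring distance ranges by widening the bins
        for widen in (1.5, 3.0):
            if total_deficit == 0:
                break
            for b in np.argsort(-needed):
                if total_deficit == 0:
                    break
                if needed[b] == 0:
                    continue
                got = total_deficit - try_fill(int(b), total_deficit, widen=widen)
                total_deficit -= got
        if total_deficit > 0:
            warnings.warn(
                f"distance-matched sampler short by {total_deficit} negatives "
                "(candidate pool exhausted)",
                stacklevel=2,
            )
    return list(chosen.values())


def build_extended_negatives(
    positives: Sequence[AnchorPair],
    ratio_extended: int = DEFAULT_EXTENDED_RATIO,
    seed: int = 0,
    anchors: Sequence[GenomicInterval] | None = None,
) -> list[AnchorPair]:
    """Negatives for the extended tier: uniform over candidate re-pairings
    whose distance lies within the positive distance range."""
    if not positives:
        raise ValueError("positives must be non-empty")
    dists = np.array([p.distance for p in positives], float)
    lo, hi = float(dists.min()), float(dists.max()) + 1.0
    return _uniform_negatives(positives, ratio_extended, seed, anchors, lo, hi)


def _uniform_negatives(
    positives: Sequence[AnchorPair],
    ratio: int,
    seed: int,
    anchors: Sequence[GenomicInterval] | None,
    lo: float,
    hi: float,
) -> list[AnchorPair]:
    rng = np.random.default_rng(seed)
    if anchors is None:
        dedup: dict[tuple, GenomicInterval] = {}
        for p in positives:
            dedup.setdefault(p.left.key(), p.left)
            dedup.setdefault(p.right.key(), p.right)
        anchors = list(dedup.values())
    pool = _AnchorPool(anchors)
    forbidden = {p.key() for p in positives}
    target = ratio * len(positives)
    chosen: dict[tuple, AnchorPair] = {}
    attempts, max_attempts = 0, 60 * target + 60
    while len(chosen) < target and attempts < max_attempts:
        attempts += 1
        chrom = pool.chroms[rng.choice(len(pool.chroms), p=pool.weights)]
        ivs = pool.by_chrom[chrom]
        if len(ivs) < 2:
            continue
        i = int(rng.integers(len(ivs)))
        cand = pool.partners_in_range(chrom, i, lo, hi)
        if cand.size == 0:
            continue
        j = int(cand[rng.integers(cand.size)])
        pair = _make_pair(ivs[i], ivs[j], "negative")
        if pair.key() in forbidden or pair.key() in chosen:
            continue
        chosen[pair.key()] = pair
    if len(chosen) < target:
        warnings.warn(
            f"extended sampler short by {target - len(chosen)} negatives",
            stacklevel=2,
        )
    return list(chosen.values())


def build_anchors_from_open_chromatin(
    open_regions: Sequence[GenomicInterval],
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
    extension: int = DEFAULT_EXTENSION,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Putative interaction anchors from open-chromatin peaks.

    Peaks within ``merge_distance`` bp are merged, then each merged region is
    extended by ``extension`` bp per side (defaults 3000/1000 bp).
    """
    if chrom_lengths is None:
        chrom_lengths = {}
        for iv in open_regions:
            chrom_lengths[iv.chrom] = max(
                chrom_lengths.get(iv.chrom, 0), iv.end + extension
            )
    return merge_and_extend(open_regions, merge_distance, extension, chrom_lengths)


def enumerate_and_label_pairs(
    anchors: Sequence[GenomicInterval],
    known_loops: Sequence[AnchorPair],
    max_span: int = DEFAULT_MAX_SPAN,
    min_overlap: int = 1,
) -> list[AnchorPair]:
    """Enumerate all same-chromosome anchor pairs within ``max_span`` and label
    them against known loops.

    A pair is positive iff one of its anchors overlaps (>= ``min_overlap`` bp)
    one anchor of some known loop and its other anchor overlaps the other
    anchor of the *same* loop; otherwise negative.
    """
    if max_span <= 0:
        raise ValueError("max_span must be > 0")
    index = IntervalIndex(anchors)
    positive_ij: set[tuple[int, int]] = set()
    for loop in known_loops:
        if loop.interchromosomal:
            continue
        hits_l = index.overlapping(loop.left, min_overlap)
        hits_r = index.overlapping(loop.right, min_overlap)
        for i in hits_l:
            for j in hits_r:
                if i != j:
                    positive_ij.add((min(i, j), max(i, j)))

    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(anchors):
        by_chrom.setdefault(iv.chrom, []).append(i)
    out: list[AnchorPair] = []
    for chrom in sorted(by_chrom):
        idx = sorted(by_chrom[chrom], key=lambda i: anchors[i].start)
        mids = [anchors[i].midpoint for i in idx]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if mids[b] - mids[a] > max_span:
                    break
                i, j = idx[a], idx[b]
                label = (
                    "positive"
                    if (min(i, j), max(i, j)) in positive_ij
                    else "negative"
                )
                out.append(_make_pair(anchors[i], anchors[j], label))
    return out


def split_by_chromosome(
    pairs: Sequence[AnchorPair], split: DatasetSplit
) -> tuple[list[AnchorPair], list[AnchorPair], list[AnchorPair]]:
    """Partition pairs into (train, validation, test) by chromosome."""
    buckets: dict[str, list[AnchorPair]] = {"train": [], "validation": [], "test": []}
    for p in pairs:
        buckets[split.assign(p.chrom)].append(p)
    return buckets["train"], buckets["validation"], buckets["test"]


# ---------------------------------------------------------------------------
# Tabular serialization (TSV)

_COLUMNS = ["chrom", "start1", "end1", "start2", "end2", "distance", "label", "split"]


def pairs_to_frame(
    pairs: Sequence[AnchorPair], split: DatasetSplit | None = None
) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "chrom": p.chrom,
                "start1": p.left.start,
                "end1": p.left.end,
                "start2": p.right.start,
                "end2": p.right.end,
                "distance": p.distance,
                "label": p.label,
                "split": split.assign(p.chrom) if split is not None else ".",
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_pairs(df: pd.DataFrame) -> list[AnchorPair]:
    return [
        AnchorPair(
            GenomicInterval(r.chrom, int(r.start1), int(r.end1)),
            GenomicInterval(r.chrom, int(r.start2), int(r.end2)),
            label=r.label,
        )
        for r in df.itertuples()
    ]


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_dataset(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
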