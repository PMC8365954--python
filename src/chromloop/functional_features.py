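"""The functional-genomics baseline: anchor-level track features + distance.

For each anchor pair, every supplied track (transcription-factor ChIP,
histone modification, open chromatin) contributes either the coverage-
weighted mean signal over each anchor (bedGraph representation) or the
number of peaks overlapping each anchor (peak BED representation); anchor
distance is an optional extra column. A gradient-boosted-tree classifier on
this table is the reference point the sequence model is compared against:
on properly distance-matched data a distance-only model sits at the
prevalence baseline, while signal enrichment at interacting anchors carries
real predictive information.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import AnchorPair, GenomicInterval, IntervalIndex

__all__ = [
    "mean_signal",
    "mean_signal_features",
    "peak_count_features",
    "assemble_feature_table",
]

Track = Mapping[str, np.ndarray]  # chrom -> (n, 3) array of start, end, value


def mean_signal(anchor: GenomicInterval, track: Track) -> float:
    """Coverage-weighted mean of a bedGraph track over an anchor.

    mean = sum(value x overlap bp) / anchor length; uncovered bases count 0.
    """
    segs = track.get(anchor.chrom)
    if segs is None or len(segs) == 0:
        return 0.0
    ov = np.minimum(segs[:, 1], anchor.end) - np.maximum(segs[:, 0], anchor.start)
    ov = np.clip(ov, 0, None)
    return float(np.sum(ov * segs[:, 2]) / len(anchor))


def mean_signal_features(
    pair: AnchorPair, tracks: Mapping[str, Track]
) -> dict[str, float]:
    """Per-track mean signal for both anchors, keyed ``<track>_<side>``."""
    out: dict[str, float] = {}
    for name in sorted(tracks):
        out[f"{name}_left"] = mean_signal(pair.left, tracks[name])
        out[f"{name}_right"] = mean_signal(pair.right, tracks[name])
    return out


def peak_count_features(
    pair: AnchorPair, peak_sets: Mapping[str, Sequence[GenomicInterval]],
    _indexes: Mapping[str, IntervalIndex] | None = None,
) -> dict[str, int]:
    """Number of peaks overlapping (>= 1 bp) each anchor, per peak set."""
    out: dict[str, int] = {}
    for name in sorted(peak_sets):
        idx = _indexes[name] if _indexes else IntervalIndex(peak_sets[name])
        out[f"{name}_left"] = len(idx.overlapping(pair.left))
        out[f"{name}_right"] = len(idx.overlapping(pair.right))
    return out


def assemble_feature_table(
    pairs: Sequence[AnchorPair],
    tracks: Mapping[str, Track] | None = None,
    peak_sets: Mapping[str, Sequence[GenomicInterval]] | None = None,
    feature_mode: str = "all",
    representation: str = "signal",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table + labels for the functional baseline.

    feature_mode: ``all`` (genomics + distance), ``genomics_only``, or
    ``distance_only``. representation: ``signal`` (bedGraph means) or
    ``counts`` (peak counts); ignored for distance_only (warned). Column
    order is deterministic: sorted track names x (left, right), then
    distance.
    """
    if feature_mode not in ("all", "genomics_only", "distance_only"):
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    if representation not in ("signal", "counts"):
        raise ValueError(f"unknown representation {representation!r}")
    labels = np.array([1 if p.label == "positive" else 0 for p in pairs])

    if feature_mode == "distance_only":
        if tracks or peak_sets:
            warnings.warn(
                "distance_only ignores the provided tracks/peaks", stacklevel=2
            )
        df = pd.DataFrame({"distance": [p.distance for p in pairs]}, dtype=float)
        return df, labels

    rows: list[dict] = []
    indexes = (
        {name: IntervalIndex(ps) for name, ps in peak_sets.items()}
        if representation == "counts" and peak_sets
        else None
    )
    for p in pairs:
        if representation == "signal":
            if tracks is None:
                raise ValueError("signal representation requires tracks")
            row = mean_signal_features(p, tracks)
        else:
            if peak_sets is None:
                raise ValueError("counts representation requires peak_sets")
            row = dict(peak_count_features(p, peak_sets, indexes))
        if feature_mode == "all":
            row["distance"] = float(p.distance)
        rows.append(row)
    df = pd.DataFrame(rows)
    genomics_cols = sorted(c for c in df.columns if c != "distance")
    cols = genomics_cols + (["distance"] if feature_mode == "all" else [])
    return df[cols].astype(float), labels
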