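"""Cross-sample statistics over predicted interaction sets.

All samples' predictions are expressed over one pooled anchor universe, so an
interaction is a canonical anchor-pair key and sample-to-sample comparison is
exact identity. The resulting interactions x samples presence/absence matrix
supports: conservation profiles (what fraction of interactions recur in k
samples), two-group differential tests (two-sided Fisher exact per
interaction, Benjamini-Hochberg adjusted), attribution of differential
interactions to their anchors (both / one-side / neither anchor itself
differential), and promoter-level IFC scores (fold change of the mean number
of promoter-touching interactions between groups, e.g. IGHV-unmutated vs
-mutated CLL), optionally associated with expression classes by a
Kruskal-Wallis test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import AnchorPair, GenomicInterval, IntervalIndex

__all__ = [
    "PresenceMatrix",
    "DifferentialResult",
    "fisher_exact_presence",
    "build_presence_matrix",
    "conservation_profile",
    "differential_interactions",
    "anchor_change_attribution",
    "ifc_score",
]


def fisher_exact_presence(present_a: int, n_a: int, present_b: int, n_b: int) -> float:
    """Two-sided Fisher exact p for a presence/absence 2x2 table.

    Exact integer enumeration of the hypergeometric support with fixed
    margins: the p-value sums P(k) over all k whose table probability does
    not exceed the observed one. Integer comparisons make ties exact.
    """
    for v, n in ((present_a, n_a), (present_b, n_b)):
        if not (0 <= v <= n):
            raise ValueError("counts must satisfy 0 <= present <= group size")
    x = present_a + present_b  # total present (fixed margin)
    if x == 0 or x == n_a + n_b:
        return 1.0
    # weight(k) proportional to table probability given margins
    lo, hi = max(0, x - n_b), min(n_a, x)
    weights = {k: comb(n_a, k) * comb(n_b, x - k) for k in range(lo, hi + 1)}
    obs = weights[present_a]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= obs)
    return tail / total


@dataclass(frozen=True)
class DifferentialResult:
    key: str
    pair: AnchorPair
    table: tuple[tuple[int, int], tuple[int, int]]  # (present, absent) x group
    p_value: float
    adjusted_p: float
    direction: str  # group label with the higher presence rate, or "none"
    attribution: str | None = None  # both / one-side / neither


class PresenceMatrix:
    """Interactions x samples binary occurrence table.

    ``matrix`` is a DataFrame indexed by canonical pair keys with one int8
    column per sample; ``pairs`` maps key → AnchorPair; ``groups`` maps
    sample → group label (when groups are used every sample has exactly one).
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        pairs: Mapping[tuple, AnchorPair],
        groups: Mapping[str, str] | None = None,
    ):
        if matrix.index.has_duplicates:
            raise ValueError("duplicate interaction rows")
        if groups is not None:
            missing = set(matrix.columns) - set(groups)
            if missing:
                raise ValueError(f"samples without group label: {sorted(missing)}")
        self.matrix = matrix.astype(np.int8)
        self.pairs = dict(pairs)
        self.groups = dict(groups) if groups is not None else None

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def group_columns(self) -> dict[str, list[str]]:
        if self.groups is None:
            raise ValueError("no group labels attached")
        out: dict[str, list[str]] = {}
        for sample in self.matrix.columns:
            out.setdefault(self.groups[sample], []).append(sample)
        return out


def build_presence_matrix(
    predictions: Mapping[str, Sequence],
    anchor_universe: Sequence[GenomicInterval],
    thresholds: Mapping[str, float] | None = None,
    groups: Mapping[str, str] | None = None,
) -> PresenceMatrix:
    """Presence matrix from per-sample predictions over a pooled anchor set.

    ``predictions`` maps sample → prediction records (anything with ``pair``
    and ``score``) or scored AnchorPairs. An entry is 1 iff the pair's score
    reaches that sample's threshold (default 0.5 each). Pairs referencing an
    anchor outside the universe are an error; all-zero rows are dropped.
    """
    universe = {iv.key() for iv in anchor_universe}
    columns: dict[str, dict[tuple, int]] = {}
    pairs: dict[tuple, AnchorPair] = {}
    for sample, records in predictions.items():
        thr = 0.5 if thresholds is None else thresholds[sample]
        col: dict[tuple, int] = {}
        for rec in records:
            pair = rec.pair if hasattr(rec, "pair") else rec
            score = rec.score if rec.score is not None else 1.0
            for anchor in (pair.left, pair.right):
                if anchor.key() not in universe:
                    raise ValueError(
                        f"anchor {anchor.key()} of sample {sample} outside the "
                        "pooled anchor universe"
                    )
            key = pair.id
            pairs.setdefault(key, pair)
            if score >= thr:
                col[key] = 1
        columns[sample] = col
    keys = sorted(pairs)
    mat = pd.DataFrame(
        {
            sample: [columns[sample].get(k, 0) for k in keys]
            for sample in predictions
        },
        index=pd.Index(keys, name="interaction"),
        dtype=np.int8,
    )
    nonzero = mat.sum(axis=1) > 0
    mat = mat.loc[nonzero]
    pairs = {k: pairs[k] for k in mat.index}
    return PresenceMatrix(mat, pairs, groups)


def conservation_profile(matrix: PresenceMatrix) -> pd.Series:
    """Proportion of interactions found in exactly k samples, k = 1..n."""
    n = matrix.n_samples
    if n < 1:
        raise ValueError("need at least one sample")
    row_sums = matrix.matrix.sum(axis=1).to_numpy()
    counts = np.bincount(row_sums, minlength=n + 1)[1:]
    total = counts.sum()
    props = counts / total if total else counts.astype(float)
    return pd.Series(props, index=pd.RangeIndex(1, n + 1, name="n_samples"))


def differential_interactions(
    matrix: PresenceMatrix, alpha: float = 0.05
) -> list[DifferentialResult]:
    """Two-group differential presence per interaction.

    Per row: two-sided Fisher exact p on the (present, absent) x group table;
    Benjamini-Hochberg adjustment across rows; direction = group with the
    higher presence rate. Rows present in all samples or absent everywhere are
    degenerate: p = 1 by convention, direction "none".
    """
    by_group = matrix.group_columns()
    if len(by_group) != 2:
        raise ValueError(f"need exactly two groups, got {list(by_group)}")
    (ga, cols_a), (gb, cols_b) = sorted(by_group.items())
    n_a, n_b = len(cols_a), len(cols_b)
    pres_a = matrix.matrix[cols_a].sum(axis=1).to_numpy()
    pres_b = matrix.matrix[cols_b].sum(axis=1).to_numpy()
    pvals = np.array(
        [
            fisher_exact_presence(int(a), n_a, int(b), n_b)
            for a, b in zip(pres_a, pres_b)
        ]
    )
    adj = multipletests(pvals, alpha, "fdr_bh")[1]
    results = []
    for key, a, b, p, q in zip(matrix.matrix.index, pres_a, pres_b, pvals, adj):
        rate_a, rate_b = a / n_a, b / n_b
        direction = ga if rate_a > rate_b else gb if rate_b > rate_a else "none"
        results.append(
            DifferentialResult(
                key,
                matrix.pairs[key],
                ((int(a), n_a - int(a)), (int(b), n_b - int(b))),
                float(p),
                float(q),
                direction,
            )
        )
    return results


def anchor_change_attribution(
    differential: Sequence[DifferentialResult],
    anchor_presence: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
) -> tuple[dict[str, int], list[DifferentialResult]]:
    """Attribute each significant differential interaction to its anchors.

    ``anchor_presence`` is an anchors x samples 0/1 table (index = anchor
    keys). Anchor-level Fisher tests are computed by the same procedure and
    BH-adjusted across anchors; an interaction is labeled by how many of its
    two anchors are themselves significant in the same direction at the same
    adjusted-p threshold: "both", "one-side" or "neither". Returns the counts
    (over interactions with adjusted p <= alpha) and the labeled records.
    """
    by_group: dict[str, list[str]] = {}
    for sample in anchor_presence.columns:
        by_group.setdefault(groups[sample], []).append(sample)
    (ga, cols_a), (gb, cols_b) = sorted(by_group.items())
    n_a, n_b = len(cols_a), len(cols_b)
    pres_a = anchor_presence[cols_a].sum(axis=1)
    pres_b = anchor_presence[cols_b].sum(axis=1)
    anchor_p = np.array(
        [
            fisher_exact_presence(int(a), n_a, int(b), n_b)
            for a, b in zip(pres_a, pres_b)
        ]
    )
    anchor_q = pd.Series(
        multipletests(anchor_p, alpha, "fdr_bh")[1], index=anchor_presence.index
    )
    anchor_dir = pd.Series(
        np.where(
            pres_a / n_a > pres_b / n_b, ga,
            np.where(pres_b / n_b > pres_a / n_a, gb, "none"),
        ),
        index=anchor_presence.index,
    )

    counts = {"both": 0, "one-side": 0, "neither": 0}
    labeled: list[DifferentialResult] = []
    for res in differential:
        if res.adjusted_p > alpha:
            labeled.append(res)
            continue
        n_sig = 0
        for anchor in (res.pair.left, res.pair.right):
            key = anchor.id
            if (
                key in anchor_q.index
                and anchor_q[key] <= alpha
                and anchor_dir[key] == res.direction
            ):
                n_sig += 1
        label = {2: "both", 1: "one-side", 0: "neither"}[n_sig]
        counts[label] += 1
        labeled.append(
            DifferentialResult(
                res.key, res.pair, res.table, res.p_value, res.adjusted_p,
                res.direction, label,
            )
        )
    return counts, labeled


def ifc_score(
    promoters: Sequence[GenomicInterval],
    matrix: PresenceMatrix,
    group_a: str,
    group_b: str,
    expression_classes: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Per-gene interaction fold change (IFC) between two sample groups.

    For each promoter window (gene name taken from the first BED annotation
    column), count the interactions touching it per sample; IFC = mean count
    in ``group_a`` / mean count in ``group_b``. A zero denominator leaves the
    IFC undefined (NaN, flagged); promoters overlapping no anchor are
    excluded with a note. If ``expression_classes`` maps genes to classes, a
    Kruskal-Wallis test of IFC across classes is run (second return value).
    """
    by_group = matrix.group_columns()
    cols_a, cols_b = by_group[group_a], by_group[group_b]
    pair_list = [matrix.pairs[k] for k in matrix.matrix.index]
    left_index = IntervalIndex([p.left for p in pair_list])
    right_index = IntervalIndex([p.right for p in pair_list])
    values = matrix.matrix.to_numpy()
    col_pos = {c: i for i, c in enumerate(matrix.matrix.columns)}

    rows = []
    skipped = []
    for prom in promoters:
        gene = prom.annotations[0] if prom.annotations else f"{prom.chrom}:{prom.start}"
        touching = sorted(
            set(left_index.overlapping(prom)) | set(right_index.overlapping(prom))
        )
        if not touching:
            skipped.append(gene)
            continue
        sub = values[touching]
        counts = sub.sum(axis=0)
        mean_a = float(np.mean([counts[col_pos[c]] for c in cols_a]))
        mean_b = float(np.mean([counts[col_pos[c]] for c in cols_b]))
        ifc = mean_a / mean_b if mean_b > 0 else np.nan
        rows.append(
            {
                "gene": gene,
                "mean_" + group_a: mean_a,
                "mean_" + group_b: mean_b,
                "ifc": ifc,
                "defined": bool(mean_b > 0),
            }
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} promoter(s) overlap no interaction anchor "
            f"(e.g. {skipped[:3]}); excluded",
            stacklevel=2,
        )
    df = pd.DataFrame(rows)
    kw_p = None
    if expression_classes is not None and not df.empty:
        df["expression_class"] = df["gene"].map(expression_classes)
        grouped = [
            g["ifc"].dropna().to_numpy()
            for _, g in df.groupby("expression_class")
        ]
        grouped = [g for g in grouped if len(g)]
        if len(grouped) >= 2:
            kw_p = float(stats.kruskal(*grouped).pvalue)
    return df, kw_p
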