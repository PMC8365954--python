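"""Interpretation of trained models: kernels → PWMs, motif matching, and the
convergent-orientation signature.

First-layer convolutional kernels are converted to position weight matrices
by the alignment-of-activating-subsequences recipe: collect the input windows
on which a kernel responds strongly (above a fraction of its maximal positive
response), count bases per position with a pseudocount, and normalize.
Kernel PWMs are compared against a motif database by maximal Pearson
correlation of aligned columns over all offsets and both orientations, with
an empirical column-shuffle null for the p-value (a Tomtom-style match).

The convergence analysis quantifies the hallmark of CTCF-anchored loops:
when a motif sits on the forward strand of the left anchor and on the
reverse strand of the right anchor (pointing at each other), a classifier on
orientation-resolved features concentrates importance on the left-forward
and right-reverse-complement blocks, and the per-kernel importance vectors
of cross-strand block pairs correlate while same-strand pairs do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .boosted_classifier import ImportanceRecord
from .sequence_model import BASES, ConvFeatureExtractor, _encode_batch

__all__ = [
    "PWM",
    "MotifMatch",
    "read_meme",
    "write_meme",
    "read_jaspar",
    "kernels_to_pwms",
    "pwm_similarity",
    "match_pwm_to_database",
    "motif_detection_counts",
    "convergence_analysis",
    "ConvergenceReport",
]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: (width, 4) base probabilities over A,C,G,T."""

    matrix: np.ndarray
    name: str
    source: str = "database"  # or "kernel"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if np.any(m < 0):
            raise ValueError("PWM entries must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        # reverse positions, swap A<->T and C<->G columns
        return PWM(self.matrix[::-1, ::-1], self.name, self.source)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class MotifMatch:
    query: str
    target: str
    offset: int
    orientation: str  # '+' or '-'
    similarity: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must be in (0, 1]")


# ---------------------------------------------------------------------------
# Motif file formats (MEME minimal + JASPAR PFM text)


def read_meme(path: str | Path) -> list[PWM]:
    """Read motifs from MEME minimal format."""
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    pwms.append(PWM(np.array(rows), name))
                parts = line.split()
                name = parts[1]
                rows = []
                in_matrix = False
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and line and line[0] in "0123456789.":
                rows.append([float(x) for x in line.split()[:4]])
            elif in_matrix and not line:
                in_matrix = False
    if name is not None and rows:
        pwms.append(PWM(np.array(rows), name))
    return pwms


def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_jaspar(path: str | Path) -> list[PWM]:
    """Read JASPAR PFM text: '>ID name' header then four 'A [ ... ]' rows."""
    pwms: list[PWM] = []
    name = None
    counts: dict[str, list[float]] = {}
    def flush():
        if name is None or len(counts) != 4:
            return
        mat = np.array([counts[b] for b in BASES], dtype=float).T
        mat = mat + 1e-9
        mat /= mat.sum(axis=1, keepdims=True)
        pwms.append(PWM(mat, name))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                counts = {}
            elif line and line[0] in "ACGT":
                base = line[0]
                nums = line[1:].replace("[", " ").replace("]", " ").split()
                counts[base] = [float(x) for x in nums]
    flush()
    return pwms


# ---------------------------------------------------------------------------
# Kernel → PWM


def _receptive_field(config, layer: int) -> tuple[int, int]:
    """(stride, width) in input bases of positions in conv layer ``layer``."""
    stride, width = 1, config.conv_widths[0]
    for i in range(1, layer + 1):
        stride *= config.pool_width
        width = width + (config.conv_widths[i] - 1) * stride
    return stride, width


def kernels_to_pwms(
    extractor: ConvFeatureExtractor,
    probe_sequences: Sequence[str],
    layer: str = "first",
    activation_quantile: float = 0.5,
    pseudocount: float = 1.0,
    min_sites: int = 10,
    max_sites: int = 2000,
) -> tuple[list[PWM], list[bool]]:
    """Derive one PWM per kernel of the first (or last) conv layer.

    For each kernel, the probe windows whose activation exceeds
    ``activation_quantile`` x the kernel's maximal positive response are
    aligned; base counts per position (pseudocount added) are normalized to
    probabilities. Kernels with fewer than ``min_sites`` activating windows
    are flagged inactive (second return value; their PWM is near-uniform).
    """
    if not extractor.frozen and np.allclose(extractor.conv_layers[0].b, 0):
        pass  # untrained extractors are allowed; PWMs will be near-uniform
    layer_idx = 0 if layer == "first" else len(extractor.conv_layers) - 1
    cfg = extractor.config
    stride, width = _receptive_field(cfg, layer_idx)
    L = cfg.input_length
    x = _encode_batch(probe_sequences, L)
    acts = extractor.kernel_activations(x, layer_idx)  # (B, P, K)
    B, P, K = acts.shape
    n_windows = B * P
    if n_windows < 10_000:
        warnings.warn(
            f"only {n_windows} probe subsequences; PWM estimates may be noisy",
            stacklevel=2,
        )
    windows = np.lib.stride_tricks.sliding_window_view(x, width, axis=1)
    # windows: (B, L-width+1, 4, width)
    pwms: list[PWM] = []
    active: list[bool] = []
    flat = acts.reshape(n_windows, K)
    for k in range(K):
        a = flat[:, k]
        amax = a.max()
        counts = np.full((width, 4), pseudocount, dtype=float)
        n_sites = 0
        if amax > 0:
            thr = activation_quantile * amax
            sel = np.nonzero(a > thr)[0]
            if sel.size > max_sites:
                sel = sel[np.argsort(-a[sel])[:max_sites]]
            b_idx, t_idx = np.divmod(sel, P)
            t_idx = t_idx * stride
            keep = t_idx <= L - width
            b_idx, t_idx = b_idx[keep], t_idx[keep]
            n_sites = len(b_idx)
            if n_sites:
                sites = windows[b_idx, t_idx]  # (n, 4, width)
                counts += sites.sum(axis=0).T
        counts /= counts.sum(axis=1, keepdims=True)
        pwms.append(PWM(counts, f"kernel_{layer}_{k:03d}", source="kernel"))
        active.append(n_sites >= min_sites)
    return pwms, active


# ---------------------------------------------------------------------------
# PWM similarity / database matching


def _aligned_pearson(q: np.ndarray, t: np.ndarray, min_overlap: int) -> tuple[float, int]:
    """Best Pearson correlation of flattened aligned columns over all offsets
    (offset = start of query relative to target)."""
    best, best_off = -1.0, 0
    wq, wt = q.shape[0], t.shape[0]
    for off in range(-(wq - min_overlap), wt - min_overlap + 1):
        qs = max(0, -off)
        ts = max(0, off)
        n = min(wq - qs, wt - ts)
        if n < min_overlap:
            continue
        a = q[qs : qs + n].ravel()
        b = t[ts : ts + n].ravel()
        if a.std() == 0 or b.std() == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best:
            best, best_off = r, off
    return best, best_off


def pwm_similarity(
    query: PWM, target: PWM, min_overlap: int = 5
) -> tuple[float, int, str]:
    """Max Pearson over offsets and both orientations: (similarity, offset,
    orientation)."""
    s_f, o_f = _aligned_pearson(query.matrix, target.matrix, min_overlap)
    s_r, o_r = _aligned_pearson(
        query.matrix, target.reverse_complement().matrix, min_overlap
    )
    if s_r > s_f:
        return s_r, o_r, "-"
    return s_f, o_f, "+"


def match_pwm_to_database(
    query: PWM,
    database: Sequence[PWM],
    n_shuffles: int = 200,
    seed: int = 0,
    min_overlap: int = 5,
) -> list[MotifMatch]:
    """Match a query PWM against a database; empirical p from column-shuffled
    nulls, p = (1 + #null >= observed) / (n_shuffles + 1). Sorted by p, then
    by decreasing similarity."""
    if query.width < min_overlap:
        raise ValueError(f"query width {query.width} < min overlap {min_overlap}")
    rng = np.random.default_rng(seed)
    shuffles = [
        PWM(query.matrix[rng.permutation(query.width)], "shuffled")
        for _ in range(n_shuffles)
    ]
    matches: list[MotifMatch] = []
    for target in database:
        sim, off, orient = pwm_similarity(query, target, min_overlap)
        null = np.array(
            [pwm_similarity(s, target, min_overlap)[0] for s in shuffles]
        )
        p = (1 + int(np.sum(null >= sim))) / (n_shuffles + 1)
        matches.append(MotifMatch(query.name, target.name, off, orient, sim, p))
    matches.sort(key=lambda m: (m.p_value, -m.similarity))
    return matches


def motif_detection_counts(
    models: Mapping[str, ConvFeatureExtractor],
    database: Sequence[PWM],
    probe_sequences: Sequence[str],
    activation_quantile: float = 0.5,
    alpha: float = 0.05,
    n_shuffles: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Motif x model table: how many first-layer kernels of each model match
    each database motif (best match, Benjamini-Hochberg-adjusted p <= alpha).
    """
    table = pd.DataFrame(
        0, index=[m.name for m in database], columns=list(models), dtype=int
    )
    for model_name, extractor in models.items():
        pwms, active = kernels_to_pwms(
            extractor, probe_sequences, "first", activation_quantile
        )
        best: list[MotifMatch] = []
        for pwm, is_active in zip(pwms, active):
            if not is_active:
                continue
            matches = match_pwm_to_database(pwm, database, n_shuffles, seed)
            best.append(matches[0])
        if not best:
            continue
        rejected = multipletests([m.p_value for m in best], alpha, "fdr_bh")[0]
        for m, rej in zip(best, rejected):
            if rej:
                table.loc[m.target, model_name] += 1
    return table


# ---------------------------------------------------------------------------
# Convergence analysis


@dataclass
class ConvergenceReport:
    block_means: dict[str, float]
    block_correlations: dict[tuple[str, str], float]
    convergent: bool
    top_kernel: int
    top_block: str

    @property
    def cross_strand_correlation(self) -> float:
        vals = [
            self.block_correlations[("left_F", "right_RC")],
            self.block_correlations[("left_RC", "right_F")],
        ]
        return float(np.nanmean(vals))

    @property
    def same_strand_correlation(self) -> float:
        vals = [
            self.block_correlations[("left_F", "right_F")],
            self.block_correlations[("left_RC", "right_RC")],
        ]
        return float(np.nanmean(vals))


_PAIRINGS = [
    ("left_F", "right_F"),
    ("left_F", "right_RC"),
    ("left_RC", "right_F"),
    ("left_RC", "right_RC"),
]


def convergence_analysis(importances: Iterable[ImportanceRecord]) -> ConvergenceReport:
    """Quantify the convergent-orientation importance pattern.

    Computes the mean importance per (anchor, orientation) block, the Pearson
    correlation of kernel-matched importance vectors for the four cross-anchor
    block pairings, and a convergence flag: one of the two cross-strand block
    combinations dominates in mean importance AND the cross-strand correlation
    exceeds the same-strand correlation. Also reports the kernel and block of
    the single most important sequence feature.
    """
    by_block: dict[str, dict[int, float]] = {
        b: {} for b in ("left_F", "left_RC", "right_F", "right_RC")
    }
    seq_records = []
    for rec in importances:
        if rec.block == "distance":
            continue
        if rec.block not in by_block or rec.kernel is None:
            raise ValueError(f"importance record without block mapping: {rec}")
        by_block[rec.block][rec.kernel] = rec.importance
        seq_records.append(rec)
    if not seq_records:
        raise ValueError("no sequence-feature importances provided")
    kernels = sorted(by_block["left_F"])
    vectors = {
        b: np.array([by_block[b].get(k, 0.0) for k in kernels])
        for b in ("left_F", "left_RC", "right_F", "right_RC")
    }
    means = {b: float(v.mean()) for b, v in vectors.items()}
    corrs: dict[tuple[str, str], float] = {}
    degenerate = False
    for a, b in _PAIRINGS:
        va, vb = vectors[a], vectors[b]
        if va.std() == 0 or vb.std() == 0:
            corrs[(a, b)] = float("nan")
            degenerate = True
        else:
            corrs[(a, b)] = float(np.corrcoef(va, vb)[0, 1])
    if degenerate:
        warnings.warn(
            "degenerate importance vectors: correlations undefined", stacklevel=2
        )
    top = max(seq_records, key=lambda r: r.importance)

    convergent = False
    if not degenerate:
        conv_dominant = means["left_F"] + means["right_RC"] > means["left_RC"] + means["right_F"]
        mirror_dominant = means["left_RC"] + means["right_F"] > means["left_F"] + means["right_RC"]
        same = np.nanmean([corrs[("left_F", "right_F")], corrs[("left_RC", "right_RC")]])
        if conv_dominant:
            convergent = corrs[("left_F", "right_RC")] > same
        elif mirror_dominant:
            convergent = corrs[("left_RC", "right_F")] > same
    return ConvergenceReport(means, corrs, bool(convergent), top.kernel, top.block)
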