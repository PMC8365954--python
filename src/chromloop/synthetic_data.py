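"""Synthetic fixtures emulating every input the pipeline consumes.

A random genome (i.i.d. bases at a configurable GC content), non-overlapping
open-chromatin regions, positive loops whose anchors carry a planted motif in
convergent orientation (forward instance on the left anchor, reverse
complement on the right), background motif instances elsewhere at a low
rate, signal tracks enriched at positive anchors, and cohort-style
per-sample presence with group-dependent probabilities. Everything is
deterministic under the config seed, and a ground-truth manifest records
every planted quantity so tests can verify recovery without re-simulation.

The planted motif is a bundled 19-column synthetic matrix, deliberately
asymmetric (non-palindromic) so that orientation effects are detectable; no
real transcription-factor matrix is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_io import AnchorPair, GenomeSequence, GenomicInterval, reverse_complement
from .motif_analysis import PWM, read_meme

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "default_planted_motif",
    "toy_motif_database",
    "simulate_genome_and_regions",
    "simulate_interactions_with_convergent_motifs",
    "simulate_signal_tracks",
    "simulate_cohort_presence",
    "simulate_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_planted_motif() -> PWM:
    """The bundled 19-column asymmetric planted motif."""
    with resources.as_file(
        resources.files("chromloop.data") / "planted_motif.meme"
    ) as p:
        return read_meme(p)[0]


def toy_motif_database() -> list[PWM]:
    """Small bundled motif database for tests and examples (includes the
    planted motif and several decoys)."""
    with resources.as_file(
        resources.files("chromloop.data") / "toy_motifs.meme"
    ) as p:
        return read_meme(p)


def _default_chroms() -> dict[str, int]:
    return {f"chr{i}": 3_000_000 for i in range(1, 9)}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixtures.

    Distances between loop anchors are log-normal with median 100 kb
    (sigma = 1 on the natural-log scale), loosely mirroring ChIA-PET span
    scales. Open regions default to 500 bp, matching the anchor width at
    which the sequence models are exercised.
    """

    chrom_lengths: Mapping[str, int] = field(default_factory=_default_chroms)
    gc_content: float = 0.41
    n_open_regions: int = 8000
    region_width: int = 500
    n_positive_loops: int = 2000
    reuse_anchors: bool = False
    embed_probability: float = 0.9
    background_motif_rate: float = 0.02
    convergent: bool = True
    distance_log_mean: float = float(np.log(100_000))
    distance_log_sd: float = 1.0
    min_distance: int = 5_000
    signal_baseline: float = 1.0
    signal_fold: float = 5.0
    n_samples: int = 0
    groups: tuple[str, ...] = ()
    presence_prob: float = 0.6
    differential_fraction: float = 0.1
    differential_probs: tuple[float, float] = (0.9, 0.1)
    seed: int = 13

    def __post_init__(self) -> None:
        for p in (
            self.gc_content,
            self.embed_probability,
            self.background_motif_rate,
            self.presence_prob,
            *self.differential_probs,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if min(self.chrom_lengths.values()) <= 0 or self.region_width <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class SimulatedStudy:
    genome: GenomeSequence
    regions: list[GenomicInterval]
    loops: list[AnchorPair]
    manifest: dict


def _random_chromosome(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def simulate_genome_and_regions(
    config: SimConfig,
) -> tuple[dict[str, np.ndarray], list[GenomicInterval]]:
    """Random genome (as mutable per-chromosome byte arrays) plus uniformly
    placed, non-overlapping open regions. Deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    chroms = {
        c: _random_chromosome(rng, l, config.gc_content)
        for c, l in config.chrom_lengths.items()
    }
    total = sum(config.chrom_lengths.values())
    regions: list[GenomicInterval] = []
    w = config.region_width
    for chrom, clen in config.chrom_lengths.items():
        n_c = int(round(config.n_open_regions * clen / total))
        if n_c * w > clen:
            raise ValueError(f"cannot fit {n_c} regions of {w} bp on {chrom}")
        starts: set[int] = set()
        placed: list[int] = []
        for _ in range(200 * n_c):
            if len(placed) >= n_c:
                break
            s = int(rng.integers(0, clen - w))
            if all(abs(s - t) >= w for t in placed):
                placed.append(s)
        if len(placed) < n_c:
            raise ValueError(f"could not place {n_c} regions on {chrom}")
        for i, s in enumerate(sorted(placed)):
            regions.append(GenomicInterval(chrom, s, s + w, annotations=(f"{chrom}_r{i}",)))
    return chroms, regions


def _sample_pwm(rng: np.random.Generator, pwm: PWM) -> str:
    idx = [rng.choice(4, p=row / row.sum()) for row in pwm.matrix]
    return "".join("ACGT"[i] for i in idx)


def _write_motif(
    chrom_arr: np.ndarray, region: GenomicInterval, instance: str, rng
) -> int:
    w = len(instance)
    if len(region) < w:
        raise ValueError(f"anchor {region.key()} shorter than motif ({w} bp)")
    pos = region.start + int(rng.integers(0, len(region) - w + 1))
    chrom_arr[pos : pos + w] = np.frombuffer(instance.encode(), dtype=np.uint8)
    return pos


def simulate_interactions_with_convergent_motifs(
    config: SimConfig,
    chrom_arrays: dict[str, np.ndarray],
    regions: Sequence[GenomicInterval],
    motif: PWM | None = None,
) -> tuple[list[AnchorPair], dict, GenomeSequence]:
    """Draw positive loops and plant convergent motif instances.

    For each positive loop a motif instance sampled from the planted PWM is
    written into the left anchor on the forward strand and (as its reverse
    complement) into the right anchor, each with ``embed_probability``.
    Open regions that anchor no loop receive instances at
    ``background_motif_rate`` in random orientation. Returns the loops, the
    ground-truth manifest, and the finished (immutable) genome.
    """
    rng = np.random.default_rng(config.seed + 1)
    if motif is None:
        motif = default_planted_motif()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        if len(ivs) < 2:
            raise ValueError(f"need >= 2 regions per chromosome ({chrom})")
        ivs.sort(key=lambda x: x.start)
    chrom_names = sorted(by_chrom)
    weights = np.array([len(by_chrom[c]) for c in chrom_names], float)
    weights /= weights.sum()
    mids = {c: np.array([iv.midpoint for iv in by_chrom[c]]) for c in chrom_names}

    loops: list[AnchorPair] = []
    seen: set[tuple] = set()
    used: dict[str, set[int]] = {c: set() for c in chrom_names}
    attempts, max_attempts = 0, 400 * config.n_positive_loops
    while len(loops) < config.n_positive_loops and attempts < max_attempts:
        attempts += 1
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        ivs = by_chrom[chrom]
        i = int(rng.integers(len(ivs)))
        if not config.reuse_anchors and i in used[chrom]:
            continue
        d = float(np.exp(rng.normal(config.distance_log_mean, config.distance_log_sd)))
        d = max(d, float(config.min_distance))
        sign = 1 if rng.random() < 0.5 else -1
        target = mids[chrom][i] + sign * d
        j0 = int(np.searchsorted(mids[chrom], target))
        # nearest eligible region midpoint to the target
        candidates = sorted(
            (j for j in range(j0 - 3, j0 + 4) if 0 <= j < len(ivs) and j != i),
            key=lambda j: abs(mids[chrom][j] - target),
        )
        j = None
        for cand in candidates:
            if config.reuse_anchors or cand not in used[chrom]:
                j = cand
                break
        if j is None:
            continue
        actual = abs(mids[chrom][j] - mids[chrom][i])
        if actual < config.min_distance or abs(actual - d) > 0.5 * d:
            continue
        left, right = (ivs[i], ivs[j]) if ivs[i].start < ivs[j].start else (ivs[j], ivs[i])
        pair = AnchorPair(left, right, label="positive")
        if pair.key() in seen:
            continue
        seen.add(pair.key())
        used[chrom].update((i, j))
        loops.append(pair)
    if len(loops) < config.n_positive_loops:
        raise ValueError(
            f"could only place {len(loops)}/{config.n_positive_loops} loops"
        )

    planted: list[dict] = []
    loop_anchor_keys: set[tuple] = set()
    for li, pair in enumerate(loops):
        for role, anchor in (("left", pair.left), ("right", pair.right)):
            loop_anchor_keys.add(anchor.key())
            if rng.random() >= config.embed_probability:
                continue
            instance = _sample_pwm(rng, motif)
            if config.convergent:
                strand = "+" if role == "left" else "-"
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            written = instance if strand == "+" else reverse_complement(instance)
            pos = _write_motif(chrom_arrays[anchor.chrom], anchor, written, rng)
            planted.append(
                {
                    "loop": li,
                    "role": role,
                    "chrom": anchor.chrom,
                    "pos": pos,
                    "strand": strand,
                    "instance": instance,
                }
            )
    for iv in regions:
        if iv.key() in loop_anchor_keys:
            continue
        if rng.random() >= config.background_motif_rate:
            continue
        instance = _sample_pwm(rng, motif)
        strand = "+" if rng.random() < 0.5 else "-"
        written = instance if strand == "+" else reverse_complement(instance)
        pos = _write_motif(chrom_arrays[iv.chrom], iv, written, rng)
        planted.append(
            {
                "loop": None,
                "role": "background",
                "chrom": iv.chrom,
                "pos": pos,
                "strand": strand,
                "instance": instance,
            }
        )

    genome = GenomeSequence(
        {c: arr.tobytes().decode("ascii") for c, arr in chrom_arrays.items()}
    )
    manifest = {
        "motif_name": motif.name,
        "motif_consensus": motif.consensus(),
        "loops": [
            {
                "chrom": p.chrom,
                "start1": p.left.start,
                "end1": p.left.end,
                "start2": p.right.start,
                "end2": p.right.end,
            }
            for p in loops
        ],
        "planted_instances": planted,
        "embed_probability": config.embed_probability,
        "background_motif_rate": config.background_motif_rate,
        "seed": config.seed,
    }
    return loops, manifest, genome


def simulate_signal_tracks(
    config: SimConfig,
    regions: Sequence[GenomicInterval],
    loops: Sequence[AnchorPair],
    track_names: Sequence[str] = ("tf_a", "histone_b", "open_chromatin"),
) -> dict[str, dict[str, np.ndarray]]:
    """bedGraph-style signal tracks: background noise over every open region,
    fold-enriched at anchors of positive loops."""
    rng = np.random.default_rng(config.seed + 2)
    anchor_keys = set()
    for p in loops:
        anchor_keys.add(p.left.key())
        anchor_keys.add(p.right.key())
    tracks: dict[str, dict[str, np.ndarray]] = {}
    for name in track_names:
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv in regions:
            value = config.signal_baseline * float(rng.lognormal(0.0, 0.25))
            if iv.key() in anchor_keys:
                value *= config.signal_fold
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
        tracks[name] = {
            c: np.array(sorted(rows), dtype=float) for c, rows in per_chrom.items()
        }
    return tracks


def simulate_cohort_presence(
    config: SimConfig, loops: Sequence[AnchorPair]
) -> tuple["np.ndarray", list[str], dict[str, str], dict]:
    """Per-sample loop presence with group-dependent probabilities.

    Most loops are present in any sample with ``presence_prob``; a planted
    ``differential_fraction`` of loops uses ``differential_probs`` — the
    higher probability in one group, the lower in the other (direction
    alternating) — so differential testing has known ground truth. Returns
    (presence matrix loops x samples, sample names, sample→group map, truth).
    """
    if config.n_samples < 2 or len(config.groups) != config.n_samples:
        raise ValueError("cohort simulation needs n_samples >= 2 with group labels")
    rng = np.random.default_rng(config.seed + 3)
    n_loops = len(loops)
    samples = [f"sample_{i:02d}" for i in range(config.n_samples)]
    group_of = dict(zip(samples, config.groups))
    group_names = sorted(set(config.groups))
    if len(group_names) != 2:
        raise ValueError("cohort simulation expects exactly two groups")
    n_diff = int(round(config.differential_fraction * n_loops))
    diff_idx = rng.choice(n_loops, size=n_diff, replace=False)
    hi, lo = config.differential_probs
    direction = {}  # loop index -> group with the high probability
    probs = np.full((n_loops, config.n_samples), config.presence_prob)
    for rank, li in enumerate(sorted(diff_idx)):
        high_group = group_names[rank % 2]
        direction[int(li)] = high_group
        for si, s in enumerate(samples):
            probs[li, si] = hi if group_of[s] == high_group else lo
    presence = (rng.random((n_loops, config.n_samples)) < probs).astype(np.int8)
    truth = {
        "differential_loops": {int(k): v for k, v in direction.items()},
        "presence_prob": config.presence_prob,
        "differential_probs": list(config.differential_probs),
    }
    return presence, samples, group_of, truth


def simulate_study(
    config: SimConfig, motif: PWM | None = None, with_tracks: bool = False
) -> SimulatedStudy:
    """Full fixture: genome + open regions + convergent-motif loops
    (+ optional signal tracks in the manifest)."""
    chrom_arrays, regions = simulate_genome_and_regions(config)
    loops, manifest, genome = simulate_interactions_with_convergent_motifs(
        config, chrom_arrays, regions, motif
    )
    study = SimulatedStudy(genome, regions, loops, manifest)
    if with_tracks:
        study.manifest["tracks"] = simulate_signal_tracks(config, regions, loops)
    return study


def export_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write FASTA / BED / BEDPE / manifest JSON for CLI use."""
    from .genome_io import write_bed, write_bedpe

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.genome.to_fasta(outdir / "genome.fa")
    write_bed(study.regions, outdir / "open_regions.bed")
    write_bedpe(study.loops, outdir / "loops.bedpe")
    manifest = {k: v for k, v in study.manifest.items() if k != "tracks"}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
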