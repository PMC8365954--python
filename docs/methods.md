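# Methods

## The prediction problem

Chromatin loops bring two genomic "anchors" — typically open-chromatin
regions — into spatial contact. `chromloop` asks whether such contacts can
be predicted from DNA sequence and anchor distance alone, and packages the
full workflow: dataset construction from loop calls (BEDPE) and
open-chromatin peaks (BED), a staged sequence model, genome-wide prediction
from peaks alone, interpretation of what the model learned, and cohort
statistics over predicted interaction sets.

## Dataset tiers and why distance must be controlled

Anchor distance separates interacting from random pairs almost perfectly, so
a naive negative set lets a classifier win on distance and learn nothing
about sequence. Three tiers are built:

1. **Distance-matched** (`sample_distance_matched_negatives`). Positive
   distances are binned into `n_bins = 50` log10-spaced bins; each bin
   contributes `ratio = 5` times its positive count in negatives, drawn
   without replacement from same-chromosome re-pairings of a candidate
   anchor pool. Exhausted bins re-allocate their deficit to progressively
   widened neighboring ranges (with a warning). A two-sample KS statistic
   between positive and negative log-distance distributions of ~0.01–0.03 is
   typical. On distance-matched data a distance-only gradient-boosted model
   sits at the prevalence baseline — the control that validates the sampler.
2. **Extended** (`build_extended_negatives`): `ratio = 25`, distances only
   uniform over the positive range. This is the tier the stage-2 classifier
   and its feature-importance analysis are trained on, where harder
   imbalance sharpens the importance signal.
3. **From open chromatin** (`enumerate_and_label_pairs`): peaks are merged
   (gap ≤ 3000 bp, inclusive, gap defined as `next.start − current.end`) and
   extended by 1000 bp per side; all same-chromosome anchor pairs within
   `max_span = 2 Mb` are enumerated and labeled against known loops (a pair
   is positive only when its two anchors overlap the two anchors of one
   loop). This is the genome-wide setting with extreme (hundreds-to-one)
   imbalance.

**Negative candidate pool.** By default the samplers re-pair the positive
anchors themselves. The canonical study pipeline instead passes the open
regions that anchor *no* known loop (`regions_without_loop_anchors`): anchors
of observed loops frequently contact additional, unobserved partners, so
re-pairings of true anchors are systematically contaminated with false
negatives. With convergently oriented motifs this is not a subtlety — a
re-pairing of a left anchor of one loop with a right anchor of another
carries the exact sequence signature of a positive, which caps attainable
auPRC far below what a clean negative set allows.

**Splits** are chromosome holdouts (default test = {chr5, chr14}, validation
= {chr4} when present): random pair-level splitting leaks anchors between
train and test and inflates performance.

Coordinates are BED-convention (0-based, half-open) throughout; pair
distance is midpoint-to-midpoint, which is stable under anchor extension.
Soft-masked (lowercase) bases are uppercased, not masked.

## The staged sequence model

**Stage 1 — convolutional feature extractor.** Each anchor sequence is
one-hot encoded (A,C,G,T channels; N = all-zero row; sequences centered,
padded or center-cropped to the input length) and passed through
convolution → ReLU → max-pool (width 10) → convolution → ReLU → global max
pooling. Every last-layer kernel contributes one feature: its maximal
activation anywhere on the sequence. A pair is represented by four feature
blocks — left-forward, left-reverse-complement, right-forward,
right-reverse-complement — in that fixed order. This makes motif
*orientation* explicit: a motif on the forward strand of the left anchor and
its reverse complement on the right anchor (the convergent geometry of CTCF
loops) activates the same kernel in the left-F and right-RC blocks. By
construction, reverse-complementing an anchor exactly swaps its F and RC
blocks.

The extractor is pretrained end-to-end with a two-layer dense head (hidden
ReLU → sigmoid) on the distance-matched tier: weighted binary cross-entropy
(negatives down-weighted to an effective 1:1), Adam at 1e-3, batch 128, ≤ 30
epochs with early stopping on validation auPRC (patience 5). The network is
implemented directly on NumPy (forward and backward passes, Adam); at these
sizes this is fast, dependency-light and bit-reproducible under a fixed
seed in a single thread.

One optimization detail matters: randomly initialized motif kernels spend a
long plateau drifting into alignment with informative subsequences before
the loss moves. Training the first convolutional layer at 10× the base
learning rate shortens that plateau several-fold without destabilizing the
head; this multiplier is exposed (`first_layer_lr_multiplier`) and on by
default.

Library default architecture: 64 kernels × 19 bp, pool 10, 32 kernels × 11,
input length 1000 bp (DeepBind-scale sizes; two layers so that both
first-layer kernels and last-layer features are interpretable). The
reference experiments and acceptance run use a desk-scale setting — 32/16
kernels and a 500 bp window matching the 500 bp synthetic anchors — chosen
so the full study trains in minutes on one core.

**Stage 2 — gradient-boosted trees.** The extractor is frozen (contract:
any further training attempt raises; parameters are bit-identical after
downstream use) and XGBoost is trained on the 4-block features of the
extended tier, optionally plus raw distance in bp (trees are invariant to
monotone transforms, so no log scaling). Defaults: 500 rounds, depth 6,
learning rate 0.05, subsample 0.8, early stopping on validation aucpr (50
rounds), single-threaded with a fixed seed for determinism. Evaluation of
the staged model is reported on the *distance-matched* held-out tier, where
prevalence is interpretable (1:6).

**Stage 3 — from open chromatin.** The same frozen extractor and a
classifier trained on enumerated, loop-annotated anchor pairs yield the
genome-wide predictor: peaks in, scored BEDPE out, with an operating
threshold chosen by F1 scan.

## Interpretation

**Kernel → PWM** (`kernels_to_pwms`): for each first-layer kernel, probe
windows activating above 0.5 × the kernel's maximal positive response are
aligned and base counts (pseudocount 1) normalized to a PWM — the DeepBind
extraction recipe. Kernels with < 10 activating windows are flagged
inactive. PWMs are matched to a database (MEME minimal and JASPAR PFM
readers included; a small synthetic database ships for tests) by maximal
Pearson correlation of aligned columns over all offsets (min overlap 5) and
both orientations, with an empirical p-value from column-shuffled nulls
(Tomtom-style) and Benjamini–Hochberg control across kernels when counting
detections per model.

**Convergence analysis** (`convergence_analysis`): from the gain-based
importances of the stage-2 model, mapped through the block structure,
compute the mean importance per (anchor, orientation) block and the Pearson
correlation of kernel-matched importance vectors for the four cross-anchor
block pairings. The convergence flag is set when one of the two cross-strand
block combinations dominates in mean importance *and* its cross-strand
correlation exceeds the mean same-strand correlation. On convergent data the
expected pattern is concentrated importance in left-F and right-RC at the
same kernel indices, hence corr(left-F, right-RC) ≫ corr(left-F, right-F).
A trained extractor typically also hosts kernels for the reverse-complement
of the motif, which fire in the mirror blocks; the mirror condition in the
flag covers models that settled on that equivalent solution.

## Evaluation

auPRC is the headline metric (baseline = prevalence; ROC is uninformative at
these imbalances). Integration is the average-precision convention:
stepwise over recall increments at each distinct score threshold, ties
grouped — no trapezoidal interpolation, which is optimistic on PR curves.
Operating thresholds come from an F1 scan over all distinct scores (ties
break toward the larger threshold; empty prediction sets score F = 0).
Cross-sample evaluation fills a model × dataset auPRC matrix; feature-space
mismatches are recorded as missing, never as zero.

## Cohort statistics

Per-sample predictions over one pooled anchor universe give an
interactions × samples presence matrix (exact-identity matching of pairs;
predictions referencing anchors outside the universe are an error).
Conservation profiles are row-sum histograms. Differential interactions
between two groups use a two-sided Fisher exact test computed by exact
integer enumeration of the hypergeometric support (ties compared as
integers, so the test is reproducible to machine precision), BH-adjusted
across interactions; degenerate rows (present or absent everywhere) get
p = 1 by convention. Each significant interaction is attributed to its
anchors by running the same test at anchor level: "both", "one-side" or
"neither" anchor significantly differential in the same direction. Promoter
IFC scores are the ratio of mean promoter-touching interaction counts
between groups (undefined and flagged when the denominator group has mean
zero); association with expression classes delegates to the standard
Kruskal–Wallis test.

## The synthetic-data generator

The generator emulates every input: an i.i.d. random genome at GC 0.41 over
eight 3 Mb chromosomes; 8,000 non-overlapping 500 bp open regions placed
uniformly; 2,000 positive loops drawn between regions with log-normal
distances (median 100 kb, σ = 1 natural-log, minimum 5 kb), anchors drawn
without reuse; a motif instance sampled from the planted PWM written into
the left anchor forward and the right anchor reverse-complemented
(convergent), each with embedding probability 0.9; background instances in
non-anchor regions at rate 0.02 in random orientation. The planted matrix
is a bundled 19-column synthetic PWM, non-palindromic so orientation is
detectable, with high information content (dominant base 0.92, two
degenerate columns) comparable to CTCF's sharp motif. Signal tracks put
log-normal background noise on every region and a 5× fold on loop anchors;
cohort fixtures make each loop present per sample with probability 0.6,
except a planted 10% of loops that switch between 0.9 and 0.1 across the
two groups. Everything is deterministic under the config seed and a JSON
manifest records every planted instance and probability.

What the generator does *not* emulate: genomic sequence composition (no
repeats, no GC heterogeneity, no Markov structure), cooperative or degenerate
motif grammars, anchor reuse across loops, assay noise in loop calls, and
realistic loop density. Passing tests therefore demonstrate that the
machinery recovers a planted, cleanly convergent signal — not that real
ChIA-PET or Hi-C performance would match.

Two regime facts surfaced by pilot simulation are worth recording. First,
when negatives are re-pairings of the positive anchors themselves, a quarter
of them carry the full convergent signature and the task's auPRC ceiling
drops to ≈ 0.45 — hence the non-anchor candidate pool above. Second, in the
genome-wide enumeration setting, negative pairs joining the left anchor of
one loop to the right anchor of another are intrinsically indistinguishable
by sequence; end-to-end recovery (≈ 0.9 recall at ≈ 0.24 FDR in the
functional test) is therefore demonstrated in a sparse-loop regime
(36 loops / 12 Mb within a 250 kb span cap) where such cross-loop pairs are
rare. At realistic loop densities this confound is exactly why genome-wide
prediction is much harder than pair classification.

## Reference problem sizes

The reference study used by the test suite and the acceptance script:
2,000 positive loops (≈ 9,000 / 1,400 / 1,500 train/validation/test
distance-matched pairs), stage-2 on ≈ 52,000 extended pairs, 32+16 kernels,
500 bp windows. On one core: stage-1 ≈ 4 min, stage-2 ≈ 1.5 min, the
permuted-label null ≈ 2 min. Typical results: stage-1 held-out auPRC ≈ 0.97
(prevalence 0.16), stage-2 ≈ 0.97, best kernel–PWM Pearson vs the planted
motif ≈ 0.99, corr(left-F, right-RC) ≈ 0.96 vs corr(left-F, right-F) ≈ 0.29.

## Known limitations

- The NumPy network is CPU-bound and intended for desk-scale experiments;
  it is not a route to training on full ENCODE-scale compendia.
- Wide merged anchors interact with the fixed input window: the window is
  centered on the anchor midpoint, so motifs far off-center in multi-peak
  merged anchors can fall outside it. Use a larger `input_length` when
  anchors are wide.
- Scores are not calibrated to contact frequencies; thresholds are F1-based.
- Inter-chromosomal pairs are parsed but excluded from all modeling.
- bigWig signal is not read directly; convert to bedGraph first.
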