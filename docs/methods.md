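# Methods

This note documents the models, parameter choices, and numerical
conventions behind `fewpick`, and what the synthetic experiments do and
do not demonstrate about real cryo-EM data.

## Synthetic micrographs

The simulator (`fewpick.simulate`) emulates the statistics that matter to
a picking pipeline rather than the physics of image formation.

**Particle rendering.** Each particle is a radially symmetric Gaussian
profile `A·exp(−r²/(2σ²))` with `σ = d/4`, truncated at radius `d/2`, so
the edge falls to ≈0.14·A — a soft-edged disk resembling a low-contrast
projection without modeling the contrast transfer function. Ground-truth
masks are *hard* disks of diameter `d` (the annotation convention for
point-labeled particles), rasterized by the exact center-in-circle test;
contaminants are excluded from the mask. Particles are rendered bright on
dark; real particles are dark, but the pipeline is sign-agnostic because
the model learns the contrast from the shots.

**Noise and SNR.** i.i.d. Gaussian noise of standard deviation
`A/snr` is added, so `snr` is the peak-amplitude-to-noise ratio. Measured
SNR on a particle-free margin recovers the requested value within 20%
for `snr ∈ [0.5, 10]`.

**Placement.** A base set is placed by rejection sampling with minimum
spacing of one diameter; a fraction `overlap_fraction` of particles is
then placed at distance `U(0.5, 1.0)·d` from a random existing particle,
deliberately exercising the watershed splitter and the dual-pass
recovery. Ice-like contaminants are soft blobs with amplitude
`U(2, 5)·A` and radius `U(0.5, 3)·(d/2)`, reproducing the classic
false-positive hazard qualitatively.

**Defaults** (chosen once as a realistic low-SNR regime): 128-px images,
25 particles of diameter 16 px, snr 2.0, overlap fraction 0.1, 2 ice
blobs, contrast jitter 0.2. The end-to-end few-shot demonstrations use
the easier high-SNR condition (snr 8, no contaminants, no deliberate
overlap) because they test the learning loop, not robustness limits.

**Determinism.** All randomness flows through `numpy` generators seeded
from `SimParams.seed`; multi-micrograph datasets derive child seeds as
`SeedSequence([parent, index])`, reproducible yet mutually distinct.

**What passing tests show.** That the architecture trains, the gradients
are correct, and the geometric pipeline recovers known coordinates under
controlled noise. They do not show performance on real micrographs:
there is no CTF, no structured background (carbon, crystalline ice), no
projection heterogeneity, and the toy backbone carries no pretrained
visual prior.

## Encoder and adapters

The stage layout follows the published large hierarchical encoder: dims
(144, 288, 576, 1152), depths (2, 6, 36, 4), spatial scales (4, 8, 16,
32), 1024-px input. The toy preset divides the dims by 8 and keeps the
depths, so every adapter code path is exercised.

**Adapter form.** Pre-block residual bottleneck:
`x + W_up·GELU(W_down·x)`. The bottleneck width defaults to 0.25 of the
stage dim (standard adapter practice; no inner dimension is published).
Down-projections are initialized `N(0, 0.02²)`, up-projections at zero,
so the encoder starts exactly at the frozen backbone's function
(residual identity — verified bitwise in tests).

**Sharing semantics.** The up-projection is described as shared across
adapters, but stages have different widths, and the residual sum forces
the adapter output dimension to equal the stage dimension — a single
literally global matrix cannot satisfy both. Two interpretations are
implemented: `per_stage` (default; one shared up-projection per stage)
and `global` (one bottleneck-space core shared across *all* stages plus
per-stage output projections, requiring an explicit common bottleneck
width). Neither is claimed to be the original authors' exact choice.

**Toy backbone.** A strided patch-embedding pyramid: each stage flattens
non-overlapping patches and projects linearly to the stage width (a
strided convolution), then applies frozen random residual-MLP blocks
`x + GELU(xW + b)` with `W ~ N(0, (0.5/√dim)²)`. It implements the
backbone contract (stage specs, per-block transform, freeze flag, and
vector-Jacobian products so upstream adapters receive gradients); a real
pretrained encoder can be plugged in through the same contract.

## Training

All model arithmetic is float64 numpy with hand-written backward passes,
validated against central finite differences (relative error < 1e-4 on
every parameter family). The optimizer is standard Adam (β = 0.9/0.999,
ε = 1e-8).

**Loss.** "Balanced" binary cross-entropy is interpreted as
foreground-weighted BCE with logits, `pos_weight = (#background)/(#foreground)`
of the batch in `auto` mode (fixed and unweighted modes are exposed).
The stable form `pw·t·softplus(−z) + (1−t)·softplus(z)` avoids sigmoid
overflow.

**Decoder.** A small upsampling head: per-stage linear projection to one
logit channel, nearest-neighbor upsampling to the input size, summed
with a learnable skip from the normalized input intensity. The skip
restores full-resolution boundary detail that the coarse stage grids
cannot carry; the whole head has `Σ dims + 2` parameters, keeping the
trainable surface minimal, which is the point of adapter fine-tuning.

**Profiles.** The published full-scale recipe (batch 2, Adam lr 1e-4,
4000 epochs, 1024-px input) is preserved as `PAPER_PROFILE`. The
desk-scale default is batch 2, lr 5e-3, 400 epochs, 64-px input: at this
scale 400 epochs at 5e-3 converges consistently across initialization
seeds, while shorter schedules occasionally stall. No learning-rate
schedule or augmentation is used (none is described for the original).

**Input normalization** (unspecified in the original): clip to the
1st–99th intensity percentiles, then min-max to [0, 1], robust to hot
pixels; constant images proceed as zeros with a warning.

## Post-processing

Defaults (the detailed original algorithm is in unavailable supplementary
material; these are this package's own, exposed in `PostprocParams`):
logit threshold 0, peak scales {0.5d, 0.75d} (minimum peak separations),
area bounds (0.3, 2.5)·π(d/2)², circularity minimum 0.6 in pass 1 and
0.4 in pass 2, dedup distance 0.5d.

Numerical conventions: exact Euclidean distance transform; watershed
with 8-connectivity (4-connectivity fragments round regions along axes);
centers are region centroids rather than seed positions (robust to peak
jitter); deduplication keeps the larger-area region, with deterministic
(row, col) tie-breaks; circularity is capped at 1 since rasterized
perimeters can push 4πA/P² slightly above 1, and zero-perimeter
single-pixel regions are treated as round (they fail the area bound for
any realistic diameter anyway). Seeds that fall on background are
dropped with a warning rather than failing the whole micrograph.

## Evaluation

The matching criterion is not published; the package uses greedy
one-to-one matching by ascending center distance with a threshold of
d/2, the common convention in picking benchmarks, with the brute-force
optimal assignment retained as a test oracle (greedy is within one match
of optimal on all tested ≤6-particle configurations). IoU rasterizes
both particle sets as hard disks at the ground-truth diameter and
counts pixels. Degenerate denominators (no predictions / no ground
truth / empty union) yield 0 with a flag so dataset means stay defined.
Dataset aggregation is the unweighted arithmetic mean across
micrographs.

## Statistics

Wilcoxon signed-rank: zero differences are dropped (Wilcoxon's original
treatment) and counted; tied absolute differences are mid-ranked; the
two-sided p-value is exact for N ≤ 15 without ties (the W⁺ null
distribution is built by dynamic programming over rank sums; equivalent
to full 2ᴺ sign enumeration, which the tests perform independently) and
otherwise uses the tie-corrected normal approximation with continuity
correction. The z sign is positive when the reference method exceeds
the competitor. Under a simulated null (N = 30 pairs) the rejection rate
at α = 0.05 is ≈0.05 (slightly conservative from the continuity
correction).

Effect sizes are reported in both circulating forms — `z/N` (the printed
convention) and `z/√N` (the conventional normalization) — because the
two conflict in the source literature; both are labeled, and `N` is the
number of pairs actually used by the test. Benjamini–Hochberg adjustment
(via statsmodels) is applied within each metric's family; non-informative
tests (all differences zero) are excluded from the family and carry no
p-value rather than a misleading one.

## Coordinate and file conventions

Coordinates are (x = column, y = row), 0-based, origin at the top-left
pixel center, in either `model` (resized) or `native` (original) space;
conversions scale by the ratio of extents and round-trip within 0.5 px.
STAR output uses one `data_` block, `loop_`, `_rlnCoordinateX/Y`
columns, 6-decimal floats, native pixels — stated here prominently
because downstream tools disagree on indexing conventions. Particle
diameter is not written to STAR (coordinate files conventionally carry
positions only). MRC support covers mode 2 (float32) single images with
pixel size taken from the cell dimensions.

## Known limitations

- The toy backbone has no pretrained visual prior; absolute detection
  numbers on synthetic data say nothing about real-data accuracy.
- The post-processing thresholds are this package's defaults, not the
  original supplementary algorithm's; heavily aggregated or irregular
  particles will break the circularity/area assumptions, producing
  merged picks or missed centers.
- Greedy matching can differ from optimal assignment by one match in
  adversarial configurations.
- The decoder head is linear per stage; it suffices for disk-like
  synthetic particles but is not a substitute for a full mask decoder on
  complex shapes.
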