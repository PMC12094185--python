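# Methods

This note documents the models, estimators and numerical conventions behind
each `satquant` module, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Coordinate and unit conventions

Images are 2D rasters indexed `[row, col]`; physical coordinates are
continuous micrometres with the origin at the image corner and the centre of
pixel `(i, j)` at `((j + 0.5)·px, (i + 0.5)·px)`. All distances, areas and
speeds are in µm, µm² and µm/s; LFQ intensities are log2. Time-lapse data
default to a 5-s frame interval (0.2 frames/s), the standard acquisition
rate for satellite imaging in S2 cells; it is configurable everywhere it
matters.

## Synthetic data (`synthgen`)

Every generator takes an explicit `seed` and threads a single
`numpy.random.Generator` through the call; identical seeds give bit-identical
outputs, and there is no global random state. Each output is paired with a
`GroundTruth` record (generator parameters + per-entity true labels) that
round-trips through JSON.

**Punctate images.** Foci are isotropic Gaussians (default σ = 0.15 µm,
a diffraction-limited spot at ~100× magnification) with per-spot amplitudes
uniform within ±50% of a nominal brightness, on a Gaussian noise floor.
Positions are uniform, or — when emulating centrosome-proximal enrichment —
drawn with *spatial density* ∝ exp(−r/λ) around supplied centres, i.e. radii
from Gamma(2, λ) with uniform angles, rejection-sampled against the image
bounds. The per-area convention is what makes the measured ring-mean radial
profile decay as exp(−r/λ), so the generator's λ is directly the quantity
the radial module estimates.

**Two-channel pairs.** Exactly `floor(n·shared_fraction)` channel-B spots
sit at channel-A positions plus isotropic Gaussian jitter; the rest are
independent. The floor rule makes planted counts exact for tests.

**Trajectories.** Four motion models, all 2D:

- *normal*: Gaussian steps, per-axis variance 2·D·dt;
- *subdiffusive*: fractional Brownian motion with Hurst H = α/2, generated
  by Cholesky factorisation of the fractional-Gaussian-noise covariance and
  scaled so the per-axis MSD is 2·D·t^α — the exponent is exactly
  controllable, which is the point;
- *confined*: Brownian steps radially reflected at the boundary of a disc
  of radius L centred on the start position (the simplest model with a
  genuine MSD plateau, < 2·L²);
- *directed*: Brownian steps plus a constant drift of speed v in a random
  per-track direction.

Detections are emitted in the tracker-export CSV dialect with the track
identity held only in the ground truth, so linking can be tested blind.
Optional localization noise is added to emitted positions, not to the path.

**LFQ matrices.** Per-protein baselines ~ Normal(25, 2) on the log2 scale
(typical LFQ intensity range); replicate scatter with SD `sd_log2`; the
first `n_enriched` proteins receive `effect_log2` in the bait group.
Missingness is left-censored: P(missing | x) is a logistic falling in
intensity with slope `censor_strength` per log2 unit (default 3.0, i.e. the
detection probability drops from ~95% to ~5% over about two log2 units — a
realistic steepness for LC-MS detection), whose midpoint is calibrated by
bisection so the realized overall missing fraction matches `missing_rate`.
`censor_strength = 0` degenerates to uniform (MCAR) missingness. Deleted
true values are recorded so censoring can be verified (observed mean must
exceed deleted mean). Peptide counts (1 + Poisson(3)) and contaminant flags
give the downstream filters something to act on.

**Hit tables.** Planted ortholog pairs receive mutual hits with E-values
log-uniform in the requested range; every gene additionally receives decoy
hits with E-values in 0.5–10, above the conventional 0.1 cutoff, so the
planted pairs are the exact reciprocal-best-hit answer by construction.
Tie-breaking logic is exercised separately by brute-force oracle tests on
random tables.

What the generator does **not** emulate: 3D, realistic camera noise chains
(EMCCD gain, shot noise), photobleaching/blinking, spot shape anisotropy,
peptide-level quantification, or sequence content of any kind. Passing
tests therefore demonstrate correctness of the estimators under their
stated models, not robustness to every artifact of real microscopes or
mass spectrometers.

## Segmentation (`segmentation`)

Foci are segmented by thresholding (Otsu or fixed, with optional Gaussian
pre-smoothing; measurements are always on the raw image) and connected
components; `split_touching` applies a watershed on the distance transform
seeded at local maxima with ≥ 2 px separation. Two equal Gaussian spots
closer than ~2.5σ merge into a mask with no waist (at exactly 2σ the summed
intensity is already unimodal), so watershed splitting is only claimed for
separations of ~3σ and beyond. The pixel-classifier segmentation used in
practice for real data is deliberately replaced by deterministic
thresholding: it is dependency-free, reproducible, and sufficient for
synthetic benchmarks; no claim is made of matching a trained classifier's
masks.

The overexpression-artifact filter removes objects with equivalent diameter
> 0.7 µm or mean intensity > 2× the mean over all detected objects.
Object→cell assignment is by centroid containment (unambiguous, matches
per-cell counting semantics); objects in excluded regions (nucleus, mitotic
cells) are dropped, objects in no mask are reported as unassigned, and
per-cell background is the mean of in-mask pixels outside all object
footprints.

Bleach correction fits a·exp(−b·t)+c to frame means by bounded least
squares and rescales each frame to the frame-0 fit value; a non-decaying
series is returned unchanged with a warning. Centrosome intensity is the
mean in a fixed 4.88 × 4.88 µm ROI minus the average of three same-sized
cytoplasmic ROIs; offsets are caller-supplied (they are placed manually on
real data) or proposed at three fixed angles 1.5 ROI-widths out. A ROI is
the set of pixels whose centres fall inside the square.

## Colocalization (`coloc`)

Pearson's r is computed on raw intensities over all pixels of the ROI — no
threshold masking (the common default in colocalization plugins); a
threshold-masked variant can be had by pre-masking the images. The
randomization null rotates the ROI *content* of one channel by quarter
turns (default 90°) about the ROI centre, preserving the intensity
histogram while destroying correspondence; rotation of the full image would
move different content into the ROI and change the marginal statistics.
ROIs are 2D; on z-stacks, analyse projections or single planes. Per-ROI
p-values use the add-one permutation convention
(1 + #{null ≥ obs}) / (1 + #null); group-level inference is a two-sided
Mann–Whitney rank-sum test of observed vs null correlations. Random ROI
placement is rejection sampling against an exclusion mask with a fixed
seed; centrosome-anchored placement puts the anchor 3/8 of the side length
from the centre toward a chosen corner, i.e. at one extreme of the ROI.

## Radial profiles (`radial`)

Rings are half-open annuli [r, r + w) out to 5 µm; every pixel within range
belongs to exactly one ring. Ring values are **mean** (per-area) intensity,
not raw sums: a raw ring sum grows ∝ r and would make even a uniform field
appear structured, which would contradict the flat-equals-one presentation
of normalized profiles. Default ring width is one pixel. Background (the
mean of three cytoplasmic boxes — caller-supplied, or auto-proposed as the
three dimmest 1-µm boxes beyond the analysis radius; an empty list skips
subtraction) is subtracted before normalizing each centrosome's profile to
its central ring. Centres whose central ring is non-positive after
subtraction are skipped with a warning. Profiles are averaged across
centres; SEM is SD/√n over centres; mirroring plots the central ring once
at r = 0 and every other ring at ±its centre radius. The decay-length
estimator is a linear fit of log(value) against ring-centre radius.

## Tracking and motion classification (`tracking`)

Linking is greedy mutual-nearest per frame: among all (open track, new
spot) pairs within the gate, the globally closest is linked first. Gates:
5 µm for frame-adjacent links, 5 µm across gaps of up to 2 missing frames.
Greedy assignment is exact on sparse, slow scenes (typical satellite
densities at 0.2 frames/s); a global assignment optimiser would differ only
in crowded crossings, which are outside this package's scope.

Time-averaged MSD uses all ordered pairs ℓ frames apart, up to half the
track span. The ensemble curve weights each track's MSD by its pair count
(equivalent to pooling displacement pairs), and the diffusion fit is
weighted least squares of MSD on lag with D = slope/4.

Classification computes three features per sliding 10-position window:

- α — slope of log MSD vs log lag over lags 1..5 (half the window, keeping
  ≥ 5 pairs per lag);
- confinement ratio — MSD at the full window span (lag 9) divided by
  4·D̂·τ₉, with D̂ the through-origin slope over lags 1–2. Free diffusion
  gives ≈ 1 (MSD ∝ τ), a plateau pushes the ratio toward 0, directed motion
  above 1;
- straightness — net displacement over path length.

Decision rule: confined if ratio < 0.3 and α < 0.65; else subdiffusive if
α < 0.65; else directed if α > 1.4 and straightness > 0.6; else normal.
Per-window classes are reported, but the final class applies the rule to
the across-window **mean** features: 10-position windows give noisy feature
estimates, and on tracks whose motion type does not switch, majority-voting
the noisy window labels systematically leaks subdiffusive tracks into the
confined class (the confined branch wins any window whose ratio estimate
dips below threshold). Averaging features first raised worst-mode recovery
from ~0.77 to ~0.85–0.90 on held-out synthetic data. The thresholds were
tuned once on an independent synthetic seed and frozen; they are explicit
and configurable, and no claim is made that they reproduce the per-track
labels of random-forest classifiers trained on other feature sets. Tracks
shorter than 11 frames are excluded from classification.

## Proximity (`proximity`)

Distances are first-nearest centre–centre, strictly 2D, via a k-d tree.
The null redistributes only channel B (the direction is the caller's
choice by argument order), drawing each centroid uniformly over the usable
mask (a uniform pixel, then a uniform position within it); objects are
treated as points and may coincide — no footprint-exclusion rule is
imposed. The test statistic is the mean nearest distance; p uses the
add-one convention against the shuffle means, with small p meaning "closer
than uniform placement explains". Calibration: under independence the
rejection rate at p ≤ 0.05 is ~5% (binomially distributed around 0.05
across cells).

## LFQ statistics (`lfq`)

Filtering keeps non-contaminant proteins with ≥ 2 peptides quantified in
≥ 2 replicates of at least one group. Mode normalization estimates, for
every sample pair, the mode of the per-protein log2 differences (Gaussian
KDE, Silverman bandwidth, argmax on a 512-point grid over the sample range
— deterministic and robust to the asymmetric tails that genuine enrichment
creates), then solves a zero-sum least-squares system for additive
per-sample factors; for two samples offset by c this reduces exactly to
±c/2. Normalization is idempotent to numerical precision and can be
disabled.

Imputation: *lowest of detection* replaces every missing entry with the
global minimum observed log2 intensity (deterministic; a per-sample variant
is available behind a flag — the whole-matrix statistic is the default
because the imputation distribution is modelled on the whole dataset).
*Left-censored normal* draws from Normal(μ + shift·σ, (width·σ)²) with
μ, σ from all observed values and defaults shift = −1.8, width = 0.3.
Neither method ever alters an observed value.

Differential testing: per-protein unpaired t-test (classic Student by
default; "unpaired t test" without qualification conventionally means the
pooled-variance form, and Welch is selectable), two-sided, with
log2FC = mean(bait) − mean(control). Rows with zero variance in both
groups are flagged degenerate and given p = 1 when the means coincide
(p = 0 otherwise) rather than NaN. Enrichment requires log2FC strictly
greater than 1 **and** p strictly below 0.05; Benjamini–Hochberg adjustment
is available but off by default, since the calling convention thresholds
raw p-values.

A calibration caveat worth stating explicitly: at replicate SD 0.5 with
3-vs-3 groups, a null protein's log2FC has SD ≈ 0.41, so ≈ 0.7% of null
proteins exceed the fold-change cut by chance; in a 2000-protein experiment
with 50 true targets this puts a floor of roughly 0.15 on the
false-discovery proportion of the raw-p calling rule, before
lowest-of-detection imputation adds its own bait-only-observed false calls.
The rule is faithful to standard proximity-proteomics practice; it is not
an FDR-controlled procedure, and the acceptance script reports the realized
FDP so the behaviour is visible rather than hidden.

## Orthology (`orthomap`)

Best hits per query keep the subject with minimal E-value at the cutoff
(default 0.1), ties broken by higher bitscore then lexicographic subject id
— tabular hit files routinely contain exact E-value ties, and the fixed
chain makes results deterministic and row-order independent. Duplicate
query/subject rows are collapsed to their best row first. Reciprocal best
hits are pairs best in both directions; the result is one-to-one by
construction. Dataset overlap through the map reports both conventions in
use for cross-species Venn diagrams: conserved-only unique counts (in-map
members whose partner is absent from the other set) and total unique counts
(including proteins with no ortholog at all).

## Problem sizes

The test suite and acceptance script use 100–200 tracks of 50 frames,
200 colocalization ROIs, 30 radial centres, 500 proximity cells × 100
shuffles, and 2000–5000-protein LFQ matrices — sizes at which every
recovered quantity is stable to well within its acceptance band while the
whole battery runs in under a minute on one CPU.

## Known limitations

Strictly 2D throughout; no sub-pixel spot re-localization or
motion-model (Kalman) linking; no Manders/Costes colocalization variants;
no Ripley-type spatial statistics; no peptide-to-protein roll-up or
match-between-runs; orthology consumes precomputed hit tables and does not
run searches, handle many-to-many orthogroups, or use synteny. The motion
classifier's boundary between confined and subdiffusive motion is an
explicit threshold rule, not a learned classifier, and its labels are only
claimed accurate under the four generative models above.
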