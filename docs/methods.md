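# Methods

This note documents the models, estimators, defaults and numerical
choices behind `beadpull`, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Bead pull-down scoring

**Model.** A bead is an opaque sphere imaged in one plane: a circular
region whose rim carries the fluorescent coat and whose core is dark.
Binding strength is read out as the rim-over-background contrast.

**Detection.** The built-in reference detector thresholds at the
background median + 5·MAD (strict `>`), fills holes (cores are darker
than rims), labels connected components, and discards components below
100 px area or with fill fraction < 0.6 against the smallest enclosing
circle around the centroid. The fill-fraction gate rejects merged
doublets deterministically (a touching pair fills ≈ 0.5 of its enclosing
circle). External segmenters (e.g. deep-learning models) register as
backends returning the same label-mask contract; the package never
ships or trains a model itself. A constant image yields zero labels, not
an error.

**Circle fit.** Center = centroid of the labeled pixels; radius =
√(area/π). This is exact for disks, parameter-free, and adequate for
convex bead masks; boundary least-squares fitting would add parameters
without changing the score, which depends on the profile path only
weakly once the profile extends past the rim.

**Profiles.** Default 8 rays, angles equally spaced from 0 (the +x
axis, counterclockwise; 0-based pixel-center coordinates), sampled every
1 px by bilinear interpolation out to 1.2·radius (final grid point ≤
that length). All three values are configuration keys — the number of
rays and the extension distance are conventions of this implementation.
A ray with any sample outside the image is excluded (`out-of-bounds`);
a ray whose rounded sample position lands on another bead's label is
excluded (`adjacent-bead`). Excluded rays are reported, never silently
dropped, replacing interactive inspection with an auditable log.

**Score.** max − min of the sampled gray values. The per-bead summary is
the mean and sample SD (ddof = 1; a single retained ray has SD 0 by
convention, logged) over retained rays' scores. "Points of measurement"
are the per-ray scores, not the raw pixels; the per-pixel alternative
can be recomputed from the profile objects, which retain all samples.

**QC rule.** A bead is excluded iff SD ≥ mean/2. The boundary case
(SD exactly half the mean) is excluded, and a zero-mean bead is excluded
by the same inequality since its SD ≥ 0 = mean/2. The filter is
idempotent.

**Known estimator bias.** The min–max score is a range statistic. For a
profile of ~25 samples with additive noise σ, the expected score of an
*empty* bead is E[range of the noise] ≈ 2σ, while a coated bead's score
gains only the expected maximum over the few rim samples (≈ 0.6σ).
The coated-minus-empty separation is therefore biased below the true rim
intensity by ≈ 1.4σ (measured on the default geometry: −1.40 at σ = 1,
−2.80 at σ = 2 gray values). This bias is intrinsic to min–max scoring
and does not average away with more beads or more rays; comparisons
between conditions of similar noise level are unaffected (the bias
cancels in differences of coated beads), but absolute rim intensities
are underestimated by ~2σ relative to an empty-bead baseline.

## Condensate counting and colocalization

**Rolling ball.** Background is estimated by rolling a ball of the given
radius under the intensity surface (scikit-image's implementation of the
standard construction, equivalent to grayscale opening with a ball
element), subtracted, and clipped at 0. The default radius is 2 px,
matching the small radii appropriate for diffraction-limited puncta; a
radius larger than half the image warns and proceeds.

**Counting.** Pixels strictly above the threshold are labeled
(8-connectivity); components below `min_area` = 4 px are discarded,
which rejects single-pixel noise while passing 1–2 px-scale features
that survive the small rolling-ball radii. The default threshold policy
is Otsu on the corrected channel; `fixed:<v>` and `background+<k>*sd`
are available. *Limitation:* Otsu assumes a bimodal histogram; on an
image containing no condensates at all it splits the noise and
overcounts. Kinetics series that may start empty should use a fixed or
background-derived threshold, or noise-free validation data; the
package deliberately does not second-guess the policy it is given.

**Colocalization.** A reference spot is positive in the probe channel
iff its mean probe intensity inside the spot mask exceeds the probe
background mean + k·SD, background = probe pixels outside all spot
masks. k = 3 by default and is always reported alongside the fraction;
the matching is by mask overlap, not centroid distance, reflecting a
"probe signal contained in the condensate" reading. An empty reference
set returns fraction 0 with an explicit flag.

## FRAP

Traces are normalized as (I(t) − I_bleach)/(I_pre − I_bleach) with I_pre
the mean over pre-bleach frames, so pre-bleach = 1 and the bleach frame
= 0 by construction; a trace with I_pre = I_bleach is rejected as
degenerate. The mobile fraction is the mean of the last `tail_frames`
(default 5) normalized values, clamped to [0, 1]. The tail mean is
assumption-light and adequate for a qualitative mobile/immobile readout;
it underestimates m by m·e^(−k·t_tail) when recovery is slow relative to
the observation window (< 10⁻⁶ at the default k = 0.5 s⁻¹ over 30 s at
1 frame/s). A single-exponential fit m·(1 − e^(−kt)) is provided as a
secondary estimator. No acquisition-bleaching correction is applied (no
reference region is modeled).

## Hierarchical statistics

Per-bead scores share well- and replicate-level variation, so condition
effects are estimated with a linear mixed model: response = condition
(fixed) + replicate intercept + well-within-replicate intercept +
residual, REML via statsmodels MixedLM. Well labels are internally
disambiguated as `replicate:well` so reused names stay nested. The
balanced special case is the classical nested ANOVA; one engine serves
both.

Fixed-effect p-values use the Wald statistic referred to a t
distribution with containment degrees of freedom, df = n_wells −
n_conditions − (n_replicates − 1): wells are the experimental units for
a between-well condition contrast, and with ~12 wells the asymptotic
normal reference is anticonservative (simulated type-I error ≈ 0.08 at
α = 0.05 versus ≈ 0.05 with the containment-t reference, matching the
exact balanced well-mean ANOVA to within Monte-Carlo error). Singular
fits (variance component at the 0 boundary) are flagged in the result,
and the estimate then coincides with OLS.

The t test is the pooled-variance Student version, two-sided. Zero
pooled variance is resolved explicitly: equal means → t = 0, p = 1;
unequal means → p = 0, flagged degenerate. Two-way ANOVA uses Type II
sums of squares (robust to imbalance in main effects); a constant
response reports F = 0, p = 1 by convention rather than 0/0.

## PRM normalization

Modified (GG-remnant) peptide intensities are divided, per sample, by
the summed intensity of exactly five unmodified reference peptides; a
missing or non-positive reference aborts rather than renormalizing over
a smaller set, since silently changing the reference set biases
between-sample ratios. The paired readout is log2(normalized wt /
normalized mutant); zero or missing values are flagged and excluded from
the ratio table, never imputed. Peptides sharing a site are reported per
peptide (a twice-covered site contributes two data points); site-level
aggregation is an explicit option. The reference-peptide identities are
a required input and are never defaulted. Gel-section normalization
divides site intensity by the parent protein's intensity of the same
section; sections are never mixed.

## Synthetic data

Generators emulate the study designs the pipeline targets, each
returning ground truth (per-object programmed parameters, coloc flags,
variance components) alongside the data:

- **Bead scenes** — hard-edged annuli (rim over core) on a constant
  background, optional Gaussian blur for PSF emulation, additive
  Gaussian noise clipped at 0. Hard edges make the scoring oracle exact.
  Defaults: radius ~14–20 px, rim 3 px; bead diameter in px depends on
  optics the underlying assays do not pin down, so geometry is fully
  configurable.
- **Condensate series** — symmetric 2-D Gaussian spots (σ = 1.5 px,
  truncated at 4σ) placed by rejection sampling with a minimum
  separation of 8σ; each reference spot carries probe signal with the
  programmed Bernoulli probability. Time points carry programmed counts.
- **FRAP traces** — I(t) = post + m·(pre − post)·(1 − e^(−kt)) after the
  bleach frame, 1 frame/s for 30 s by default, 5 pre-bleach frames.
- **Bead tables** — response = 100 + condition effect + replicate
  intercept (SD 5) + well intercept (SD 5) + residual (SD 10), for 3
  replicates × 4 wells × 30 beads with wells assigned round-robin to
  conditions. SDs in gray values, chosen so that well-to-well and
  replicate-to-replicate variation are comparable and the residual
  dominates at the bead level, the regime hierarchical imaging data
  usually occupy.
- **PRM tables** — paired samples with five reference peptides and
  modified peptides at programmed fold changes.

Determinism: every generator consumes a single
`numpy.random.default_rng(seed)` stream in documented order, so
identical spec + seed reproduces bitwise-identical output; the pipeline
rerun from a saved config is byte-identical.

**What the synthetic benchmarks do not show.** No PSF beyond optional
Gaussian blur, no Poisson/photon statistics, no 3-D structure, no
photobleaching during acquisition, no camera gain, no uneven
illumination, no fibril morphology (spots are symmetric Gaussians), and
bead masks are ideal disks. Passing tests demonstrate the correctness of
the measurement and inference machinery given its stated image model —
not the adequacy of that model for any particular microscope.

## Problem sizes

The simulation studies run at sizes chosen to bound Monte-Carlo error
while staying cheap: 20 scenes × 6 beads for oracle agreement, 100 bead
pairs for signal separation, 200 spots per colocalization level, 500
tables for mixed-model type-I calibration (binomial SE ≈ 0.01) and 200
for effect recovery, 300 tables for generator variance-component
checks. The full suite runs in well under a minute on one core.
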