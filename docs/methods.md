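# Methods

## Saliency model

`gazesal.saliency` implements the classic Itti–Koch bottom-up saliency
architecture for static images. Input images are resized to the display
resolution (1280 × 1024) and decomposed into a 9-level Gaussian pyramid
(σ ≈ 1 px blur, ×2 decimation per level). Per-level features:

* **intensity** I = (r + g + b)/3;
* **opponency** — r, g, b are divided by I where I exceeds 1/10 of the
  level maximum (hue is meaningless in the dark), broad-tuned
  R/G/B/Y channels are formed, and the signed RG = R − G and BY = B − Y
  planes are kept;
* **orientation** — quadrature Gabor energy at four bar orientations
  (0°, 45°, 90°, 135°), one spatial frequency (0.2 cycles/px) applied at
  every level so scale is carried by the pyramid. The even component of
  each kernel is made zero-DC and images are reflect-padded, so constant
  regions and borders produce exactly no energy; at pyramid levels
  smaller than the kernel the energy pyramid is continued by blur +
  decimation rather than filtered.

Center–surround contrast is |center − upsampled surround| for centers
c ∈ {2, 3, 4} and surrounds s = c + {3, 4}. Each contrast map passes
through Itti's normalization N(·): rescale to [0, 1], then multiply by
(1 − m̄)², where m̄ is the mean of local maxima excluding one instance of
the global maximum — promoting maps with a single dominant peak and
suppressing maps with many rivals (local maxima are found in a window
scaled to ~1/10 of the map's short side, with a 0.05 peak floor).
Normalized contrasts are summed across scales at pyramid level 4 — which
is exactly 80 × 64 for the display resolution — into per-channel
conspicuity maps (orientation sums its four per-θ maps after a second
N(·) pass each), and the full map is the equal-weight mean of the three
normalized conspicuity maps. Every emitted map is finally normalized to
a probability density (sum 1); an identically zero map (e.g. the color
channel of an achromatic image, or any channel of a constant image)
falls back to the uniform density 1/5120.

Design choices made where the classic literature leaves room: single-pass
max-promotion N(·) rather than iterative difference-of-Gaussians
normalization (the original primary formulation, and easier to reason
about); the standard (c, s) pairs and 9 levels; nearest upsampling order 1.
Absolute map values therefore differ from any particular toolbox; all
claims in this package concern the pipeline's behavior, which is checked
by construction (pop-out localization, channel separation, contract
invariants), not by matching another implementation's numbers.

## Screen geometry

A 19-inch 5:4 display (1280 × 1024) viewed from 70 cm gives a pixel pitch
of 0.0295 cm and a small-angle conversion of 0.0241 deg/px, evaluated at
the screen centre and applied uniformly (the tangent error is < 3% at the
screen corners). Gaze coordinates are degrees from the centre, x
rightward, y downward; saliency-map cells are 16 × 16 px. All modules
share this mapping through `gazesal.geometry`.

## Event detection

Positions are smoothed with a zero-phase windowed-sinc FIR (order 51)
whose cutoff is solved numerically so the gain at 30 Hz is exactly
10^(−3/20) ≈ 0.708 (−3 dB); DC gain is 1. Velocity and acceleration use
a two-point central difference (±1 sample; forward difference available
by configuration). Blinks are maximal pupil = 0 runs padded by ±25 ms
with positions invalidated (gaps are interpolated before filtering so
NaNs do not leak). Saccades open where speed exceeds 30 deg/s for at
least 8 ms and extend outward until speed falls below 10 deg/s;
fixations are the remaining valid runs of ≥ 50 ms. Saccades with
amplitude strictly greater than 1° are *regular*, the rest *micro*.
The thresholds are standard eye-tracking values — the recording protocol
this pipeline mirrors does not publish its own — and are all exposed in
`DetectionParams` / the YAML configuration.

## Salience score

For one image, the score is the mean map density at the endpoints of the
regular saccades made during that image's 8-s presentation (nearest-cell
lookup — the maps are density histograms, so interpolation would mix
cell masses; off-screen endpoints are missing). A subject's score per
channel is the unweighted mean of per-image means over the analysis
images — the four achromatic noise images are excluded (no color
contrast), leaving 16 of 20. The aggregation order (per image first, not
pooled endpoints) is part of the definition. Microsaccade endpoints are
excluded by default and can be included by configuration. On a uniform
map the score is exactly 1/5120 regardless of the gaze data.

## Statistics

*Per-site effect size.* Within each site, score ~ group + age + sex is
fitted by least squares; the group coefficient divided by the residual
SD gives d, multiplied by the Hedges correction J = 1 − 3/(4·df − 1) at
the residual df. Standardizing by the residual SD (not the raw pooled
SD) matches the covariate-adjusted regression formulation; with no
covariates it reduces exactly to textbook Hedges g (verified to 1e−10).
The SE uses var(d) = (n₁+n₂)/(n₁n₂) + d²/(2·df). A covariate without
variation in a site (e.g. a single-sex cell) is dropped with a warning.

*Meta-analysis.* Fixed-effects inverse-variance pooling:
d̄ = Σ(dᵢ/seᵢ²)/Σ(1/seᵢ²), se = (Σ1/seᵢ²)^(−1/2), two-sided normal p.
Random-effects models and heterogeneity statistics are out of scope.

*Cross-disorder GLM.* score ~ diagnosis + age + sex + site with
categorical coding; type-II F test for the diagnosis main effect (equal
to type III here, as the model has no interactions). Estimated marginal
means are model predictions with age fixed at 35.75 years and sex/site
averaged over their observed joint distribution (the SPSS EMMEANS
convention); all 10 pairwise diagnosis contrasts are Bonferroni-adjusted
(adjusted p = min(1, 10·p)). Correlation screens use Pearson r with
Bonferroni over the number of tests in the screen.

## Synthetic-data generator

The generator emulates the study conditions the analysis assumes: 20
trials per subject (one per image, subject-specific random order), 8 s
at 1 kHz, five stimulus categories with four procedural images each
(noise images are achromatic by construction), and a five-group,
multi-site cohort.

*Traces.* A trial alternates fixation epochs (constant position +
Gaussian jitter, σ = 0.05° per sample) with raised-cosine saccade ramps
of 30 ms — detectable events, deliberately not physiologic
main-sequence kinematics. Default 20 regular saccades and 2
microsaccades per trial; endpoints closer than 1.2° to the current
position are redrawn so programmed regular saccades stay unambiguously
above the 1° classification threshold. Blinks (Poisson, mean 1/trial,
100–300 ms) zero the pupil and invalidate position, and are placed
inside fixation epochs. Trials begin at image onset; the pre-trial
fixation-spot period is not modelled.

*Endpoint mixture.* Each regular-saccade endpoint is drawn from the
image's full-model saliency density with probability π (a categorical
draw over the 80 × 64 cells followed by uniform within-cell jitter) and
uniformly over the screen otherwise. π is the subject's
salience-following bias.

*Calibration.* Because the score is linear in π —
E[score | π] = π·slope + 1/N with slope = mean over images of
(Σp² − 1/N) — and the endpoint-sampling variance of a subject's score is
computable exactly from the map densities, the group-mean biases needed
to realize target standardized shifts are solved in closed form:
Δπ = d_target · σ_score / slope, where
σ_score² = (σ_π·slope)² + σ_ε². Per-subject π is Beta-distributed around
the group mean (σ_π = 0.05); sites are offset by ±0.02 in π (which
cancels within-site). Defaults: HC bias 0.30 and group shifts of 0.8
(SZ), 0.55 (BD), 0.35 (MDD), 0.10 (ASD) within-group SDs, so the
headline HC-vs-SZ effect d = 0.8 is a recoverable ground truth. With the
default stimuli, σ_ε (endpoint-sampling noise at 20 endpoints × 16
images) is ~2.5× σ_π·slope, so within-group score variance is dominated
by measurement rather than trait dispersion — a property of how flat the
maps are, reported by the calibration object.

*Cohort structure.* The packaged `cohort_reference.csv` carries the
demographic structure of the seven-site study the pipeline emulates
(per site × diagnosis: counts by sex, age mean/SD; totals 550 HC,
238 SZ, 41 BD, 50 MDD, 133 ASD = 1012). Ages are drawn normal per cell
(clipped to 13–80), sex Bernoulli at the cell's ratio. Symptom-scale and
medication-dose columns are generated with no built-in association to π;
note that site offsets in π can still couple with chance site
differences in those columns, so small within-group correlations
occasionally survive correction in the smallest groups.

*Fast path.* `simulate_scores` draws the same endpoint mixture at the
score level (cells → channel densities → per-image means → across-image
mean) without synthesizing traces. It is used for experiments whose
subject counts make 1 kHz synthesis pointless (parameter recovery at
50 × 600 subjects, ordering at 40 × 1012); the trace path is validated
separately by the detection-recovery experiments, and the two paths
agree by construction up to detection endpoint error (~0.1°, which only
slightly attenuates the realized slope in trace-based scores).

*Ordering experiment.* The five-group ordering check uses wider group
spacing (0, 0.28, 0.76, 1.34, 1.82 SDs for HC/ASD/MDD/BD/SZ) than the
defaults: a normal-approximation power calculation at the reference
sample sizes shows a joint five-group ordering needs ~1.5 SDs of total
spread for ~98% joint probability, which the default 0.8-SD span cannot
provide. The spacing was fixed from that calculation, not tuned.

## What the synthetic study does and does not show

Passing tests demonstrate that the pipeline is internally correct: maps
satisfy their contract and localize pop-out, detection recovers
programmed events, scores respond linearly to the planted bias, and the
statistics recover planted effects with honest coverage. They do not
show that real clinical gaze data would yield any particular effect
size: the generator's images are procedural, its saccade kinematics are
schematic, π is the *only* subject trait (no scanpath narrowing, no
fixation-duration or pupil effects, no age/sex effects on salience), and
measurement noise enters only through endpoint sampling. Absolute map
values also depend on the saliency implementation's parameter set, so
scores are comparable within this package only.

## Numerical choices and degenerate inputs

Feature maps at rounding magnitude (max ≤ 1e−12) are treated as zero by
N(·), and densities whose total is at rounding magnitude fall back to
uniform — a constant image yields the uniform density in all four
channels. All-blink trials segment to empty saccade/fixation lists. A
point-mass endpoint density can defeat the minimum-amplitude redraw; the
resulting small movement is recorded truthfully as a microsaccade.
Problem sizes in the standard checks (50 replicates × 3 sites × 200
subjects for recovery; 40 runs × 1012 subjects for ordering; 100 trials
for detection; 50 + 50 pop-out placements) were chosen so Monte-Carlo
error is small relative to each check's margin. Seeds propagate through
`numpy.random.SeedSequence` spawning, making every pipeline run
bit-reproducible from its configured seed.
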