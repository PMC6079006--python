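# Methods

`freqtag` re-implements, as a tested pipeline on synthetic data, the
frequency-tagging approach to auditory statistical learning: listeners hear a
rapid stream of pure tones that either hides a triplet structure ("tritones",
ordered triples with within-triple transitional probability 1) or is random,
and the magnetoencephalographic (MEG) response is read out in the frequency
domain at the tone presentation rate and at the triple rate. A spectral peak
at the triple rate can only arise if the brain groups the tones — it is a
direct neural signature of stream segmentation, independent of behaviour.

## Stimulus model

Twelve pure tones (C4–B4, equal temperament, A4 = 440 Hz) of 150 ms with 5 ms
raised-cosine ramps are presented with a 25 ms inter-stimulus interval; an
extra 20 ms blank follows every third tone. The tone rate is therefore
1/(0.175 + 0.020/3) = 5.505 Hz and the triple rate 1.835 Hz, with a triple
period of exactly 0.545 s. Three stream types:

* **STAT** — four tritones (`G#CD`, `AC#G`, `FA#D#`, `EF#B`) alternate at
  random without immediate repetition. Within-triple tone transitions have
  probability 1; the successor triple is uniform over the other three, so
  triple-to-triple transitions converge to 1/3.
* **RDM** — the same tones in random order, no immediate repetition, on the
  same timing grid; every tone-to-tone transition converges to 1/11 ≈ 9%.
* **HAB** — ascending then descending chromatic scales; each ascending scale
  repeats independently with probability 0.3 (the vigilance target). HAB
  streams use the plain 175 ms grid: the 20 ms blank is a segmentation cue
  that has no role during habituation. Inter-repeat interval statistics are
  left emergent from the Bernoulli repeats rather than enforced.

A second tritone set (`DG#F`, `D#A#A`, `BC#F#`, `GCE`) that shares no
bigram, initial or final tone with the exposure set serves as foil in the
16-trial two-alternative forced-choice (2AFC) test (each exposure × foil
pairing once, presentation order counterbalanced 8/8). A rejection-sampling
search (`find_tritone_set`) can generate fresh admissible sets under the
same constraints.

## Recording simulator

The synthetic-data generator stands in for a 306-channel whole-scalp
neuromagnetometer: 102 chipsets (one magnetometer + two orthogonal planar
gradiometers) on a deterministic helmet-like planar layout of concentric
rings, with neighbourhood defined by Delaunay triangulation (a tiny seeded
jitter makes the triangulation unique; mean degree ≈ 5–6, graph connected).

A recording at 1 kHz is the sum of

1. a **tone response**: a damped-sinusoid kernel (10 Hz carrier, 40 ms
   decay, 160 ms support with a smooth fade) repeated on the uniform
   181.667 ms grid of the nominal tone rate. The 20 ms acoustic blank is
   modelled as imperceptible, so a tone-only signal is exactly 5.505 Hz
   periodic and carries *no* 1.835 Hz line (residual < 1e-6 of the tone
   line; kernels are evaluated at exact continuous offsets rather than
   rounded onset samples). Any kernel shape would do — tagging depends only
   on periodicity — and the kernel is configurable.
2. a **segmentation response**: a slow kernel (2 Hz carrier, 150 ms decay)
   on triple-initial tones, amplitude `tritone_amp`, optionally ramping
   linearly over the stream to emulate gradual learning. The slow carrier
   matters: a kernel train at 1.835 Hz necessarily has harmonics at every
   multiple of that rate including 5.505 Hz, and a fast kernel would leak
   enough power onto the tone bin to fake a tone-rate STAT-RDM difference;
   with the 2 Hz carrier the leak is < 4% of the 1.835 Hz line power and
   stays far below the tone-bin noise. `tritone_amp = 0` reproduces the
   no-segmentation regime.
3. **background noise**: per-channel 1/f^β Gaussian noise (β = 1)
   synthesised in the frequency domain and calibrated analytically to a
   time-domain standard deviation of `noise_sd`, plus flat sensor noise
   folded into the same draw. In the sleep regime a 4× power boost is
   applied below 2 Hz *after* calibration — the boost adds power, as the
   sleeping brain's low-frequency dominance does, and directly degrades the
   noise floor under the 1.835 Hz tag. The boost rolls off smoothly
   (sigmoid, 0.25 Hz width) around the 2 Hz edge: a hard step in the noise
   floor would sit inside the tag bin's neighbourhood and bias the
   neighbour-ratio SNR upward by ~20%; with the smooth edge the residual
   curvature bias is ~1%.

Spatial structure: per-chipset gains are bilateral temporal Gaussian patches
(the tritone map left-dominant), jittered ±10% per subject. The chipset
signal is split over the gradiometer pair as (cos φ, sin φ) with a fixed
per-chipset angle, so the combined-gradiometer power (grad1 + grad2) is
orientation-invariant; magnetometers carry a scaled copy. All amplitudes are
arbitrary units — the SNR readout is a ratio and unit-free.

Amplitude defaults (`tone_amp = 1`, wake `tritone_amp = 0.15`,
`noise_sd = 1`, `white_noise_sd = 0.1`) were fixed once so that the analysis
lands in the regime reported for this paradigm: 5-min tone SNR in the tens
at temporal sensors, tritone SNR ≈ 1.5–2 at responsive sensors at wake and
≈ 1 everywhere in the sleep-null regime. The wake scenario ramps the
segmentation amplitude linearly by ±60% around its mean across the stream,
mirroring the reported linear development of the response over the first
five minutes; the sleep scenario sets it to zero. RDM streams never carry a
segmentation component in either scenario.

Scenario cohorts derive per-subject seeds from the master seed by
`SeedSequence` spawning, so cohorts are reproducible and extensible. The
pipeline consumes subjects through a generator: one 5-minute recording is
~370 MB in float32 and a materialised cohort would not fit in ordinary
memory.

## Spectral readout

Epochs start at the trigger after the first 12 tones (transient guard) and
span an integer number of 0.545 s triple cycles — 560 cycles (305.20 s,
resolution 0.0033 Hz) for full streams, 112 cycles (61.04 s, 0.0164 Hz) for
minute-wise windows — so both tag frequencies fall on exact DFT bins.
Repeated runs are averaged in the time domain (phase-locked averaging:
tagged lines are conserved, noise power drops ≈ 1/k; verified as a property
test). Power is the Hann-tapered FFT magnitude squared in the 1.5–12 Hz
band; the normalisation cancels in the SNR ratio. Gradiometer pairs are
combined by summing power.

The SNR at each bin is its power over the mean power of the flanking bins —
200 neighbours (100 per side) for full epochs, 40 (20 per side) for minute
windows — always skipping the 2 closest bins per side against spectral
leakage. Neighbour counts are read as totals split symmetrically; the
parameter accepts any even total. Near band edges the short side is
truncated and the long side extended to preserve the neighbour count where
possible; such bins are flagged. Under a flat spectrum the SNR is exactly 1
(oracle-tested bin-for-bin against a brute-force loop). FOI lookup demands
the nearest bin within a quarter of the resolution — a half-bin criterion
can never fire on a uniform grid — so a misaligned (non-integer-cycle)
epoch raises instead of silently reading a neighbouring bin. The first
harmonic of a tag frequency is twice the fundamental (3.67 Hz for the
triple rate), matching the field's counting.

## Cluster statistics and sensors of interest

STAT-vs-RDM topography differences are tested with the standard
nonparametric cluster construction: per-chipset paired t statistic,
cluster-forming threshold at the unilateral t(n−1) quantile (direction
STAT > RDM), clusters as connected components in the sensor graph, cluster
mass as the sum of t ("maxsum"), and a Monte-Carlo null of the maximum
cluster mass under within-subject sign flips (10 000 permutations,
plus-one p estimator so p > 0 always). When 2^n ≤ n_perm the sign-flip null
is enumerated exhaustively instead of sampled; observed-mass comparisons
carry a 1e-9 relative tolerance so the identity flip is never lost to
round-off. Degenerate zero-variance sensors map to a large finite t rather
than ±inf.

SOIs: tritone sensors by an uncorrected per-chipset sign-flip test of
mean(SNR − 1) > 0 at α = 0.05; tone sensors by thresholding the group-mean
tone SNR during minutes 1–2 of RDM streams (> 5 at wake, > 2 in the sleep
regime, where overall SNR is lower); a plain `threshold_soi` at SNR > 1.25
approximates the permutation mask on effect cohorts. In the sleep session
the tritone *dynamics* use the tone SOIs rather than the
tritone-significance mask: no sleep sensor is expected to pass, and sensors
picked on the same STAT data would be noise-selected upward, biasing the
STAT-RDM comparison (the original design solved this by importing SOIs from
the later wake session; the tone SOIs play that role here).

## Temporal dynamics and model selection

Per subject, stream and tag frequency, the five 1-min block spectra are
averaged over successive pairs (windows 1–2 … 4–5) before the 40-neighbour
SNR, and SNR is averaged over the SOIs. The resulting table (subject ×
window × stream × group) feeds a two-step linear-mixed-model selection:

1. **Covariance structure.** Candidates: random intercept, plus optional
   random slopes for MINUTES and/or STREAM (four structures, intercept
   always present). Each is fitted under REML with the saturated fixed
   model (STREAM × categorical MINUTES, × GROUP at wake); the AICc
   minimiser wins. Comparing REML fits is valid here because the fixed part
   is held constant across candidates.
2. **Fixed effects.** With the winning structure, every admissible formula
   over STREAM, MINUTES (categorical windows, continuous 1–4, or orthogonal
   linear+quadratic polynomial — encodings mutually exclusive) and GROUP
   (wake only) is fitted under ML, hierarchy respected (interactions imply
   their main effects; the three-way implies all two-ways); intercept-only
   is always a candidate. The AICc minimiser is reported with Wald-normal
   p-values.

AICc = AIC + 2k(k+1)/(n−k−1) with n the number of observations and k the
number of estimated parameters (fixed effects + covariance parameters +
residual variance). Fitting is delegated to statsmodels' MixedLM;
enumeration, AICc accounting and selection are this package's code.
Non-converging candidates are dropped with a warning (the selection then
runs over the rest); p-values are Wald-normal approximations rather than
Satterthwaite, which the fitter does not provide — with ≥ 80 observations
per table the difference is small. Parameter recovery is tested: a planted
linear trend of 0.15 SNR/window (subject-intercept SD 0.2, residual 0.1,
n = 11) is recovered by the selected model with the slope within ±0.05 on
average, and null tables select the intercept-only model in the large
majority of replicates.

## Behavioural analysis

2AFC responses are scored against the trial key (correct = the exposure-set
member; 8/16 = 50% = chance). Group performance against chance uses the
one-sample Wilcoxon signed-rank test (reported as V, the sum of positive
ranks — R's convention; the procedure is sometimes loosely called a "rank
sum test against chance", but a one-sample comparison is a signed-rank
test); group differences use the independent rank-sum (Mann-Whitney) test.
Null results are quantified with JZS Bayes factors: the marginal likelihood
of the observed t under a Cauchy(0, √2/2) prior on the standardised effect
size (the JASP 0.9 default), integrated by adaptive quadrature over the
noncentral-t likelihood, against the central-t null. The chance-level test
is unilateral in the learning direction (scores > 50); the between-group
comparison is the independent-samples variant, two-sided. BF₁₀ > 3 counts
as substantial evidence for an effect, < 1/3 for the null. The quadrature
is verified against an independent oracle using the inverse-gamma mixture
(g-prior) representation and against pingouin's implementation.

## Pipeline scenarios and what they show

`run_experiment` chains simulation → spectral topographies → cluster tests →
SOI selection → minute-wise dynamics with model selection → a simulated
2AFC block (chance-level responders by default), writing TSV/JSON artifacts
stamped with a configuration hash. Two presets reproduce the study's
structure:

* **sleep_null** (the nap): no segmentation response, boosted low-frequency
  noise. Expected outcome: strong tone SNR at temporal SOIs, tritone SNR at
  baseline 1 everywhere, no STAT–RDM cluster.
* **wake_effect** (the wake session): ramping segmentation response in STAT
  streams only. Expected outcome: STAT > RDM tritone clusters over temporal
  sensors and a MINUTES trend in the selected mixed model.

Default problem sizes — 10 subjects per scenario, 564-triple streams (so a
full 560-cycle epoch survives the 12-tone skip), two runs per stream at
wake and one in sleep — keep a full double-scenario run within minutes on a
single CPU while preserving the study's epoch lengths and bin spacings.

## What the synthetic data do and do not show

The generator reproduces the *signal structure* the analysis relies on
(exact-bin periodic responses, orientation-split gradiometers, 1/f and
state-dependent noise, subject-level topography variation) but not real MEG
physics: no forward model from cortical sources, no head movement, no
environmental interference or its compensation, no sleep microstructure
(spindles, K-complexes), and gain maps are only qualitatively
bilateral-temporal. Passing tests therefore demonstrate that the analysis
chain is correct and well-calibrated — that it recovers planted effects and
stays at baseline under planted nulls — not that it would behave
identically on any particular real recording.

One caution on the SNR readout itself: a noise-only combined-gradiometer
SNR value is approximately a χ²₄/4 ratio (sd ≈ 0.71 per sensor), so even a
10-subject group mean fluctuates by ±0.2 at single sensors. Group-level
"SNR ≈ 1" claims are therefore asserted on means over sensors and on
cluster/SOI statistics, not as a per-sensor band.

## Numerical choices

* Epochs are truncated to integer triple-cycle counts; FOI lookup raises on
  misalignment beyond a quarter bin.
* DFT power normalisation |X|²/(Σw)²; irrelevant to SNR.
* Cluster p uses the plus-one estimator under sampling, the exact fraction
  under enumeration.
* A 5-minute stream is defined as the canonical 560-cycle epoch (305.20 s);
  the nominal "5 minutes" (300 s) would span a non-integer 550.5 cycles and
  misalign the tag bins.
* Per-subject seeds: `SeedSequence(master).spawn(n)`, one child per
  subject, consumed in subject order.
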