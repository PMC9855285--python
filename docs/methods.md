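# Methods

This note documents the models, numerical choices and validation logic behind
`cdakit`: what the synthetic generator produces, how the analysis chain
measures it, and what the tests do and do not establish about real data.

## The measurement chain

Epoched EEG (µV, trials × channels × samples) passes through a fixed stage
order: bad-channel interpolation → average reference → low-pass filter →
baseline correction → artifact flagging → lateralized averaging. Each stage
is a pure function returning a new `EpochSet`.

**Epoch convention.** Epochs run −200…1100 ms around memory-array onset with
both endpoints on the sampling grid, so 1000 Hz gives 1301 samples including
the sample at t = 0. All window means (baseline −200…0 ms, CDA 500–1000 ms)
are arithmetic means over samples with both endpoints inclusive.

**Interpolation.** Neighbour-mean over a caller-supplied adjacency map. This
is deliberately simple — the package does not model electrode geometry — and
suffices because interpolated channels never enter the lateralized montage in
the default configuration. Spherical-spline interpolation would be the
natural upgrade if bad channels ever sat at analysis sites.

**Average reference.** The per-sample mean over all scalp channels is
subtracted from each scalp channel; the bipolar HEOG channel is excluded from
both the average and the subtraction (standard practice for non-scalp
channels). Because the reference term is common to both hemispheres it
cancels exactly in every contra-minus-ipsi difference; the reference
therefore affects single-channel quantities (e.g. the ±80 µV artifact check)
but not the CDA.

**Low-pass filter.** Zero-phase (linear-phase, centred) FIR, Hamming window,
half-amplitude at cutoff + transition/2 with defaults 17 Hz cutoff and 8 Hz
transition width (413 taps at 1000 Hz), applied by FFT convolution with
zero-padded edges. Attained stopband attenuation is ≈53 dB from 25 Hz
(−71 dB at 34 Hz), far beyond the 20 dB the pipeline requires at twice the
cutoff. Only the cutoff is a scientific choice; the family/order are
implementation choices, which is why all component measures are *window
means* — they are first-order insensitive to any unit-DC-gain zero-phase
filter (measured distortion of the injected plateau's window mean: +0.02 %).

**Artifact rejection.** Two independent peak-based criteria over the full
epoch including baseline: |HEOG| > 60 µV (lateral eye movements invalidate
the contra/ipsi assignment) and any scalp |amplitude| > 80 µV. Both use
strict inequality on the epoch extremum; a peak-to-peak variant is available
(`RejectionPolicy(peak_to_peak=True)`). Flags are reported per rule so
HEOG-specific rejection rates can be analysed (condition × hemifield × group
ANOVA), but a trial failing either rule is removed from ERP averaging.
Participants are excluded when their *combined* rejection rate exceeds 30 %
(strict; exactly 30 % is retained). Whether the exclusion threshold should
count HEOG-only or combined rejections is ambiguous in the literature this
design follows; combined is the default and the policy is configurable.

**Lateralized averaging.** Averaging order is trials (within cue side) →
sites → the two cue sides with equal weight. The equal cue-side weighting
matters: artifact rejection can leave unequal trial counts per side, and
trial-pooled averaging would then weight the hemifields unequally and bias
contra/ipsi asymmetries. Each condition requires at least one usable trial
per cue side. The montage defaults to P7/P8, P9/P10, PO7/PO8; outputs are
invariant to pair order.

Earlier lateralized components (N2pc, Ppc) are measured with the same
window-mean operator under configurable windows. The defaults
(200–300 ms and 100–200 ms) are conventional placeholders only, **not**
calibrated values; set them explicitly for substantive use.

## Behavioural model and measures

Cowan's K = N·(H − F) for whole-display probes at set size N (fixed at 6 for
the capacity task), with negative estimates preserved. d′ = Z(H) − Z(F);
extreme rates are mapped to 1/(2n) and 1 − 1/(2n) by default (the class-wise
trial counts supply n), and `correction="none"` raises instead of returning
infinities. Accuracy is computed over all responded trials, not only
EEG-clean ones — the behavioural and ERP trial sets are analysed
independently.

The generator's response model is a slots model: of the N display items,
`true_k` are stored; a probed change is detected iff the probed item is
stored, otherwise the observer guesses "change" with probability g (default
0.5); a lapse (probability λ) replaces the response with a fair coin. With
λ = 0 this yields H = k/N + (1−k/N)g and F = (1−k/N)g, hence E[K̂] = k for
every g — the identity the estimator-recovery tests verify by Monte Carlo.
In the filtering task the same model runs at target load 2 (capacity capped
at the load) with λ = 0.10, which places simulated accuracies in the
mid-90 % range typical of this design; storage of distractor faces is not
modelled behaviourally (no accepted generative link exists), so behavioural
condition effects are null in expectation.

## The synthetic EEG

Per trial the generator adds, to baseline noise, a component of unit shape:
a plateau spanning the component window (default 500–1000 ms) with 50-ms
raised-cosine onset/offset ramps *outside* the window, so the unfiltered
window mean equals the plateau amplitude exactly. The three sites
contralateral to the cue receive the plateau scaled by the participant's
per-condition ground-truth amplitude; all six analysis sites additionally
receive a common bilateral deflection (−1 µV by default) that cancels in the
difference. The HEOG channel is flat until artifacts are injected: saccades
are ±amplitude steps (default 100 µV) from a random post-onset latency;
high-amplitude "blasts" are 100-ms boxcars (default ±120 µV) on one random
scalp channel. Injection returns ground-truth flag tables so the rejection
stage can be tested as an oracle.

Noise is white Gaussian per sample by default; an AR(1) option (φ = 0.97,
innovations scaled to the same stationary SD) mimics EEG autocorrelation.
Because scientific statements about the noise are naturally made at the level
of the *measured quantity*, `calibrate_noise_sd` converts a target SD of the
single-trial contra-minus-ipsi window-mean estimate into the per-sample SD,
exactly: for white noise the estimate is a fixed linear functional of the
data, so its variance is (2/P)·σ²‖h ⊛ (b_win − b_base)‖², with P electrode
pairs, h the FIR kernel and b the boxcar weights restricted to the epoch
support. The filter term matters — ignoring it miscalibrates by ≈5 % because
the low-pass removes the boxcar's sidelobe noise bandwidth.

Ground-truth defaults are the study conditions this package emulates: two
groups of 18, BDI-II sampled from N(26.83, 6.76²) truncated to ≥14
(depressed) and N(2.56, 1.79²) truncated to 0–9 (control); DASS-A means
8 (4.17) and 1.83 (2.77); capacities N(2.42, 0.688²) and N(2.66, 1.005²)
truncated to [0, 6]; per-condition CDA amplitudes centred on the group ×
condition means (−0.68/−0.71/−0.80 µV depressed, −0.42/−0.85/−0.67 µV
control) with a 0.5-µV between-participant SD. The design is 3 conditions ×
200 trials in 12 blocks with exactly counterbalanced change occurrence and
cue side (stratified assignment, not Bernoulli, so small simulated runs are
exactly balanced), plus a 100-trial capacity task. Group differences in CDA
are *injected*, not mechanistic: no generative model links depression scores
to filtering, so passing tests show the chain recovers what was injected,
not that the group effect would arise from the scores.

What the simulator does **not** emulate: volume conduction and realistic
topographies (no forward model), eye-tracking, stimulus rendering, blinks as
a separate artifact class, drifts, or line noise. Tests passing on this
synthetic data validate the *analysis arithmetic and decision rules*, not
robustness to every real-world contaminant.

## Statistics

The mixed (split-plot) ANOVA is computed by the univariate contrast
approach: within-subject effects on orthonormal (Helmert) contrast variables
of the repeated measures, between-subject effects on subject means, each
stratum with its own error term; effects are Type III with sum-to-zero
coding (the convention of JASP/SPSS workflows). Degrees of freedom are
uncorrected by default — matching how such designs are usually reported —
with Greenhouse–Geisser ε available as an option. Sums of squares below
1e−12 of the data's squared scale are treated as exact zeros so that
degenerate (constant) inputs yield F = 0 rather than round-off ratios. The
same machinery yields the rm-ANCOVA (centred participant-level covariate in
both strata; with 36 participants and 3 conditions the interaction is tested
on (2, 66) df) and the two-within-factor mixed ANOVA used for rejection
rates (condition × hemifield × group), for which no established Python
implementation exists. Correctness is established two ways in the tests:
against literal brute-force sums-of-squares oracles, and against
`pingouin.mixed_anova` where applicable; Type-I calibration of the
interaction test is verified at α = 0.05 over 2000 null studies.

t-tests and correlations delegate to `scipy.stats` (pooled-variance Student
t, accepting either raw vectors or printed summary triples; paired t;
Pearson r). Independent-samples Cohen's d is the mean difference over the
pooled SD. For paired designs no single d convention is standard, so the
result carries d_z (mean difference / SD of differences, the default), d_av
and pooled-SD variants side by side.

The JZS Bayes factor uses the default Cauchy(0, √2⁄2) prior on the
standardized effect, evaluated through the inverse-gamma mixture
representation by adaptive quadrature (`scipy.integrate.quad`, relative
tolerance 1e−8, convergence checked); the paired/one-sample and two-sample
cases differ only in the effective N and df. Two-sided priors throughout.
Planned comparisons are reported uncorrected for multiplicity, as is
conventional for this design's small set of a-priori contrasts.

## Study-level fitting and reproducibility

`CDAStudy.fit()` measures every participant, excludes by rejection rate,
and derives *all* group-level tables from the per-participant records alone;
`make_report` re-derives them from persisted records, which makes
regeneration exactly reproducible and is verified as an identity test. A
master seed fans out to per-participant, per-stage child seeds via
`SeedSequence` keyed on a CRC-32 stage tag, so any subset of the simulation
can be regenerated in isolation and adding stages never disturbs existing
streams. Tiny simulated cohorts can produce degenerate cells (zero-variance
paired differences); individual planned tests then report NaN with the
reason rather than aborting the fit, while the low-level functions keep
their strict error contracts.

**Problem sizes.** The validation suite favours designs large enough to be
statistically meaningful but small enough to iterate on: the
injection-recovery check uses one participant × 200 trials per seed and 500
seeds (estimate SE 2/√200 ≈ 0.14 µV per seed, 0.006 µV for the 500-seed
mean); estimator-recovery uses 2000 replicates of 100-trial capacity runs;
ANOVA calibration uses 2000 simulated 18 + 18 studies. Unit tests run
reduced designs (e.g. 12 trials per condition, 250 Hz) where only
arithmetic, not power, is at stake.

## Known limitations

- Neighbour-mean interpolation ignores electrode geometry.
- The N2pc/Ppc windows are placeholders; the operator is validated, the
  defaults are not.
- The two-group design is assumed throughout the report layer (the ANOVA
  machinery itself handles ≥2 groups).
- BrainVision support covers the multiplexed binary core dialect
  (IEEE float32 written; float32/int16 read) with stimulus markers only.
- No ocular *correction* (ICA/regression) is provided — contaminated trials
  are rejected, matching the design this package emulates.
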