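# Methods

## Spine turnover model and estimators

Spine presence over an ordered session schedule is modelled per dendrite as
a discrete-time birth–death process. A spine present at session *t−1*
survives to *t* with probability 1 − e_t; the number of newly formed spines
at *t* is Poisson with mean f_t · N_{t−1}, where N_{t−1} is the dendrite's
spine count at the previous session. Formation is multiplicative in the
previous count precisely so that the formation-rate estimator — formed
spines divided by the previous session's total, times 100 — is unbiased for
100·f_t; the elimination-rate estimator is likewise unbiased for 100·e_t.
Between every consecutive session pair two conservation identities hold by
construction and are asserted everywhere: stable + eliminated = previous
total, and stable + formed = current total. A spine id that disappears and
later reappears is counted as a new formation event (the simulator disables
reappearance by default, but the analysis layer accepts arbitrary binary
codes). Rates for a pair with zero spines at the previous session are
carried as NaN markers, excluded from aggregation with an explicit
exclusion count — never coerced to zero.

The persistence index of a spine is the mean of its binary presence code
over the scored sessions. Which sessions are scored is a genuine design
choice: for pre-existing spines (present at every baseline session) the
default scores only post-baseline sessions, since the baselines define
pre-existence rather than test persistence; for newly formed spines it
scores sessions strictly after the birth session. This makes the two
classes comparable survival fractions. The alternative convention —
dividing over all sessions from the first baseline (or from birth) — is
available as `denominator="all_sessions"`, and both are verified against
exhaustive enumeration of every binary code up to length 6. A spine born at
the final session has an empty scoring window and receives a NaN index.

Session labels are opaque and ordered by explicit configuration, never
sorted; mean ± SEM aggregation uses sd/√n with ddof = 1 over the chosen
unit (dendrite by default).

## Calcium simulation and activity calls

The spike-to-fluorescence simulator draws a Poisson number of events
(rate × duration) placed uniformly over the recording and convolves them
with a difference-of-exponentials kernel (defaults: rise 0.08 s, decay
0.6 s, GCaMP6m-like; peak-normalized, amplitude additive per event, default
50 intensity units on a baseline of 100). The neuropil trace is an
independent AR(1)-smoothed Gaussian process scaled to a target sd. The
observed ROI trace adds α·(neuropil − median(neuropil)) plus white Gaussian
noise; centring the contamination on the neuropil median makes the standard
compensation formula its exact algebraic inverse, so compensation
correctness is testable to machine precision (the implementation groups the
two neuropil terms for the same reason). Rendered movies place each neuron
in a 16 px tile of a 64×64 frame (configurable), a disk of radius 3 px
carrying the observed trace and an annulus (4.5–7 px) carrying the neuropil
trace; there is no optics or motion modelling, so movie round-trips test
bookkeeping, not segmentation.

Analysis filters both traces with a zero-phase (forward–backward)
second-order Butterworth low-pass at 10 Hz — forward-backward so event
onsets are not shifted — then compensates with α = 0.7 and the session-wide
neuropil median. "Prominent transient" is operationalized as a maximal run
of at least 20 consecutive frames (~0.7 s at 30 Hz) strictly above
median + k·1.4826·MAD with k = 3; both k and the minimum duration are
exposed. The robust threshold makes detection scale-invariant, so no ΔF/F
normalization is applied. A constant trace has zero MAD and yields zero
events rather than a division error. Event frequency is
60 · events · frame_rate / frames per minute; a neuron is active with ≥ 1
event, and baseline level splits at 1 transient/min into high vs low.

Detectability constraint worth knowing: with the 0.6 s decay kernel, a
single event stays above a threshold of k·σ for
decay · ln(amplitude / (k·σ)) seconds, so the ≥ 20-frame rule resolves
isolated events only when k·σ ≲ 0.33 · amplitude — about SNR ≥ 9 at k = 3.
The frequency-recovery checks therefore run at amplitude/noise = 10;
recordings noisier than that trade sensitivity for the duration criterion,
which is the intended behaviour of the rule, not a detection defect.

The fate taxonomy is a pair of partitions over (baseline, mid, late)
activity flags: baseline-active neurons are persistently_active /
silent_at_mid / silent_at_late_only / regained, late-active neurons are
persistently_active / regained / newly_active. Both partitions are verified
over the full 8-row truth table. Neuron identity across sessions comes from
the input id mapping; no registration is attempted.

## Connectivity ratios

The whole-brain starter estimate scales the counted starters by
sections_total / sections_imaged; under the simulator's binomial thinning
this interpolation is unbiased, which is checked over 500 replicate brains.
The connectivity ratio is region presynaptic count / starter estimate; a
brain with zero detected starters gets NaN ratios and is excluded from
group means with its exclusion counted, rather than coerced to infinity.
Group tables report mean ± SEM over brains with t-tests against the
matching control group (pairs configurable, defaulting to 7 d and 42 d
injury-vs-control).

One numerical subtlety: the group statistic is a mean of per-brain ratios,
and 1/starter-estimate is convex, so the statistic carries an upward Jensen
bias of order CV² of the starter estimate. At the default thinning (6 of 20
sections, 60 true starters) that bias is ≈ 4% — comparable to the 5%
consistency tolerance — so the ratio-consistency check runs at full section
sampling, where starters are known exactly and the check isolates the ratio
stage; thinning itself is covered by the separate unbiasedness check. Users
with few starters and sparse section sampling should expect the same
small upward bias in real tables.

## Bootstrap inference

Fractions are resampled at the unit level (neuron by default; the unit is
configuration, since pooling across FOVs or animals changes the
interpretation) with replacement, 10,000 iterations, percentile intervals
at 95% — the simplest method consistent with a nonparametric bootstrap; BCa
is deliberately not the default. The two-group difference test resamples
each group independently and reports p = 2·min(P(diff ≤ 0), P(diff ≥ 0)),
floored at 2/iterations so a p-value of exactly zero is never reported.
Calibration is measured, not assumed: simulated coverage at n = 139 and
true fraction 0.3 (the cohort size and activity level typical of the
labelled population here) and type-I error at n = 100 per group are
recomputed by `scripts/acceptance.py` on every run. Percentile intervals on
a discrete fraction at this n undershoot nominal coverage slightly
(~94%), which is expected behaviour of the method. Classic tests
(Friedman, repeated-measures ANOVA, Dunnett, Tukey, t, Mann–Whitney, KS)
are delegated to scipy/statsmodels behind a single façade that records the
delegated routine; the only local convention is that a Friedman design with
fully tied conditions reports statistic 0 and p 1 instead of scipy's NaN.

## Morphometry

Lesion volume uses the rectangular (Cavalieri) rule — Σ area × spacing —
with the section spacing an explicit input (default 0.05 mm for 50 µm
serial sections) because section subsampling schemes vary; cortical
thickness is the mean of exactly three medio-lateral measurements; cell
density and synaptic-pair density are straight quotients with zero-length
and zero-area denominators rejected. All are exact closed forms; their
tests are hand arithmetic plus invariances (refinement of the section
series, permutation of measurements, pooling of dendritic segments).

## What the synthetic data does and does not show

The generators reproduce the statistical structure the estimators consume
— per-session hazards, Poisson event trains with known contamination,
Poisson region counts with thinned starters — and none of the physics that
produces real images: no optics, motion, photobleaching, segmentation
error, spine-detection ambiguity, or atlas registration. Passing tests
therefore demonstrate that the estimators are correct for well-formed
inputs at realistic sizes (10,000+ spines, 100 neurons × 18,000 frames,
tens of brains), not that upstream image processing is solved; detection
and annotation quality must be established by the upstream tools that
produce the input tables.

## Problem sizes

Default verification sizes: 1,000 dendrites for conservation, 100 dendrites
× ~100 spines for hazard recovery (matching the scale of a chronic imaging
cohort), 100 neurons × 18,000 frames for detection, 50–500 replicate brains
for tracing, 1,000 replicate datasets × 10,000 bootstrap iterations for
calibration. All randomness descends from one seed through named
SeedSequence children, and reruns are bit-identical.
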