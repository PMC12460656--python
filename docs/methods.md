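# Methods

## Single-channel Lempel-Ziv complexity (LZc)

For each channel and 5-second calculation window the signal is mapped
to its analytic-signal envelope (modulus of x + i·H[x], no edge
tapering — windows are long relative to the Hilbert edge artifact), and
binarized at the envelope median computed *within that window*; a
sample maps to 1 only if it strictly exceeds the median, so ties and
constant envelopes map to 0.  The LZ76 word count follows the
Kaspar–Schuster exhaustive-history parsing, with the final incomplete
word counted.  Normalization divides by the word count of the same
binary sequence after one uniform random shuffle, which preserves the
0/1 multiset; an incompressible envelope therefore scores near 1.

The shuffle is seeded from the global seed together with a CRC-32 of
the window's binarized sequence.  This makes the value reproducible,
independent of the order in which windows are processed, and invariant
under channel or epoch permutations of the input.

Recording values average over 5-s windows within each channel and then
over channels.  Trailing segments shorter than 5 s are dropped.
Because envelope, median, and shuffle all commute with positive
rescaling, LZc is exactly invariant under global amplitude scaling.
The time-resolved variant applies the identical per-window pipeline on
a sliding window.

## PCIst

The evoked response is the trial mean, baseline-corrected (per-channel
mean of the −250…−5 ms window subtracted) and re-referenced to the
channel average.  An SVD over the 0–300 ms response window supplies
spatial components; the full-epoch projections onto the leading left
singular vectors are the component time courses.  Components are kept
up to 99% of cumulative response energy, at most 10, and only if their
response/baseline RMS ratio reaches `min_component_snr`.

Per component, distance matrices D(i,j)=|y(i)−y(j)| are built for the
baseline and response segments separately.  With T = [D > ε], the
number of state transitions (NST) is the mean over reference columns of
the count of sign changes along consecutive rows.  ε is selected from
100 quantiles of the pooled off-diagonal distances to maximize
NST_resp/L_resp − k·NST_base/L_base with k = 1.2 (ties resolved toward
the smaller ε).  The component contribution is
ΔNST = L_resp·(NST_resp/L_resp − NST_base/L_base) at ε*, clipped at
zero; PCIst is the sum over components.  Every stage is
scale-equivariant or quantile-based, so PCIst is invariant under global
amplitude scaling.

Defaults: baseline (−250, −5) ms, response (0, 300) ms inside the
−250…+500 ms epoch, variance retained 0.99, at most 10 components,
k = 1.2, 100 threshold candidates, `min_component_snr` = 1.6.  The SNR
gate is deliberately stricter than the 1.1 often quoted for this family
of measures: because the SVD is taken over the response window, it
*selects* directions of maximal response energy, which inflates the
apparent response/baseline ratio of pure-noise components to roughly
1.1–1.8 under pink trial noise at this channel count.  At 1.1 such
components leak through and contribute ΔNST ≈ 5–15 each, giving
stimulus-free data a substantial floor; at 1.6 the noise floor is
essentially zero while genuine responses (component SNR well above 2)
are unaffected.  All parameters are exposed in `PcistParams`.

A transition pair of consecutive rows exists exactly while
min(d₁,d₂) ≤ ε < max(d₁,d₂), so the NST–ε curve is unimodal, not
monotone; only the count of suprathreshold distances decreases
monotonically in ε.  The threshold optimizer evaluates the exact NST
curve on the candidate grid using this interval representation.

GMFP is the across-channel standard deviation at each time point
(population convention, ddof = 0: two channels at ±a give |a|).  ITPC
band-filters each trial (4th-order zero-phase Butterworth), takes the
analytic phase, and returns the modulus of the trial-mean unit phase
vector.

## Report classification

The default rule, applied in order: Q1 ∈ {white, vague, vivid} →
experience; else Q2 = yes → experience; else Q1 = nothing or Q2 = no →
no_experience; else no_information.  Two cells deserve comment.  A
detailed Q1 with Q2 = "no" is classed *experience*: with the published
marginals (23 positive Q1 answers, 8 Q2-no answers, class totals
24/23/5) exactly three such conflicts must exist and only this
resolution is arithmetically consistent with the totals.  "maybe" with
an uninformative Q1 is *no_information*: uncertain evidence is not
treated as suggestive of experience.  The rule is a plain lookup table
and can be replaced wholesale.

The published joint Q1 × Q2 table is only available as a color-coded
figure, so the packaged fixture is a constraint-consistent
reconstruction: a deterministic backtracking search (row-major cell
order, larger counts first) over non-negative integer tables matching
all three marginal vectors.  Any table satisfying the constraints
shares the forced cells discussed above; cell values that are not
forced are a reconstruction, not data.

## Statistics

The mixed model is `value ~ class + (1 | participant)` fitted by REML
(statsmodels MixedLM is the optimizer).  The Type-III F for the class
effect uses the GLS coefficient covariance at the estimated variance
components; denominator degrees of freedom default to a Satterthwaite
approximation computed from the closed-form REML likelihood of the
random-intercept model (numeric Hessian for the variance-component
covariance, delta method per eigencontrast, contributions averaged as
in the standard mixed-model testing literature).  "between_within" and
"residual" df methods are available; with the random intercept removed
the fit reduces to OLS and the F equals the one-way ANOVA F exactly.
EMMs are the per-class predictions at u = 0 with GLS standard errors;
the reference class is `no_experience` (EMMs are invariant to this
choice).  A fit with zero random-intercept variance is flagged
singular, not failed.

Wilcoxon signed-rank: differences y − x, zeros dropped, midranks for
ties, tie-corrected normal approximation without continuity
correction — 20 fully concordant pairs give Z = −3.92, 17 give −3.62,
15 give −3.41.  Holm–Bonferroni compares the i-th smallest p-value to
α/(m−i+1) and stops at the first failure.  Outlier screening flags
values beyond 1.5·IQR outside [Q1, Q3], with quartiles by linear
interpolation (numpy default); the convention is pinned by tests
because flags can differ across quantile conventions.

The full battery mirrors the study design: four Wilcoxon contrasts
(PCIst wake vs sedation mean; LZc eyes-open and eyes-closed vs
sedation mean; LZc eyes-open vs eyes-closed), two class LMMs on the
sedation rows, Holm across all six, complete-case pair handling with
logged warnings, and duplicate measure rows dropped up front (the
measure-table key is unique by contract).

## Synthetic data

`gen_spontaneous` sums per-channel 1/f^α background noise with one
amplitude-modulated oscillator per band (delta/theta/alpha/beta),
mixed through smooth random channel topographies; oscillator envelopes
are slow (~0.5 s) rectified Gaussian processes, so the analytic
envelope is non-degenerate for median binarization.  The default
profiles encode the study's three conditions: wake eyes-open (α
exponent 1.0, 10 µV background, moderate band amplitudes), wake
eyes-closed (identical but alpha amplitude doubled), sedation (delta
amplitude 1.8× background, spectral slope 2.0, 15 µV background).
These choices give the orderings the measures are expected to show —
LZc eyes-open > eyes-closed > sedation with ≥3 SD separation across
seeds — and were fixed once at design time.

`gen_tep` builds each trial as independent pink noise plus one
deterministic evoked waveform that is exactly zero before the pulse.
The trial noise is pink above a 2 Hz second-order high-pass shoulder:
cleaned, baseline-corrected epochs are drift-free at sub-window
time scales, and unshaped pink noise would instead be dominated by
within-epoch wander that has no counterpart in cleaned data.  The wake
recipe uses eight damped cosines (8–48 Hz carriers, 15–100 ms
latencies, ~220 ms damping, 16–40 µV amplitudes on unit-norm
topographies); the sedation recipe is a single 3 Hz slow wave — a
stereotyped, low-complexity response.  `make_tep_spec` can normalize
total evoked energy so recipes with different component counts are
directly comparable.

`gen_reports` expands the packaged joint table into (Q1, Q2) pairs and
assigns them to awakening slots by one uniform shuffle; cohorts of the
study size reproduce the printed marginals exactly, other sizes sample
i.i.d. from the joint-table proportions.  The default cohort layout is
20 participants with awakening counts 14×3 + 4×2 + 2×1 = 52.

What the generators do *not* emulate: real electrode geometry (channel
topographies are smoothed random vectors over a 1-D ordering — the
measures are topography-agnostic), EOG/muscle/TMS artifacts,
pharmacokinetics, arousal dynamics, non-stationarity within a
recording, or any dependence of the EEG on the report class.  Passing
tests therefore demonstrate that the measures and statistics behave
correctly on signals with the assumed spectral and evoked structure;
they say nothing about whether real sedated EEG carries a class
signal — in the synthetic cohorts the class null is true by
construction.

## Problem sizes and numerical choices

Synthesis runs at 250 Hz for spontaneous EEG and 500 Hz for evoked
epochs with desk-scale defaults (16 channels, 40 s recordings, 60
trials); all of these are configuration fields, and the complexity
measures themselves are sampling-rate-agnostic within the band limits.
Windows are half-open sample ranges with floor-at-start /
ceil-at-end millisecond conversion.  Seeds propagate through
`numpy.random.default_rng`; each generated recording draws its own
child seed from the run seed, so runs are reproducible bitwise from
the run log.  Degenerate inputs are defined, not special-cased:
constant envelopes binarize to all zeros (LZc ratio 1), an all-equal
distance matrix yields ε* at that distance with objective 0, a
zero evoked matrix retains no components (PCIst 0), saturated
mixed-model fits floor the residual variance instead of dividing by
zero.

Known limitations: the desk-scale LZc magnitudes (~0.2–0.76) are not
calibrated to values obtained from band-limited 1000 Hz recordings,
and PCIst magnitudes depend on the synthetic evoked strength; only
orderings and invariances are meaningful at this scale.  The
Satterthwaite implementation covers the single-random-intercept model
used here, not general mixed designs.
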