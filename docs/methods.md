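# Methods

This package implements the loudness dependence of the auditory evoked
potential (LDAEP) analysis as a complete, testable chain: synthetic cohort
generation, EEG preprocessing, N1/P2 peak measurement, the slope statistic,
test–retest reliability, and cohort-level statistics. Because no raw EEG is
distributed with the package, a synthetic-cohort generator emulates the
study conditions; every claim the test suite makes should be read against
what that generator does and does not model.

## The LDAEP statistic

An auditory evoked potential to a brief tone contains a negative deflection
near 100 ms (N1) and a positive deflection near 180 ms (P2). With tones at
55, 65, 75, 85 and 95 dB, the amplitude of these components grows with
loudness. The LDAEP is the ordinary-least-squares slope of component
amplitude (µV) on intensity (dB):

    slope = Σ(x−x̄)(y−ȳ) / Σ(x−x̄)²,  x in dB, y in µV

computed per subject for N1, P2 and the N1P2 peak-to-peak difference
(p2 − n1) at the midline channels Fz, FCz and Cz (nine cells per subject
and session).

**Unit label.** The LDAEP literature labels slopes "µV/10 dB", yet the
published per-channel values are numerically the per-dB regression
coefficients (e.g., FCz N1P2 amplitudes rising from 9.64 to 23.10 µV over
40 dB give 0.331 per dB, printed as 0.331 "µV/10 dB"). The package computes
and reports the per-dB coefficient and carries the conventional label; the
numbers take precedence over the label.

## Synthetic cohort model

Each subject carries a "true" per-channel N1P2 slope

    slope(ch) = base_mean(ch) + β_sex·I(male) + β_age·(age − mean age)
                + β_hc·I(HC user) + u(ch)

with defaults base_mean = (0.267, 0.331, 0.293) for (Fz, FCz, Cz),
β_sex = −0.084 (male coded 1; females higher), β_age = −0.003 per year and
β_hc = +0.101 for hormonal-contraceptive users (defined for females under
42; 19/43 of them use HC). The subject deviation u is multivariate normal
across channels (correlation 0.9, a design choice reflecting how similar
neighbouring midline electrodes are) with its SD chosen so the *marginal*
slope SD equals the configured value (0.137/0.164/0.144); if the covariate
effects alone imply more variance than the target SD, generation fails
loudly. The covariate part of the variance includes the covariances induced
by HC use being confined to young females. Note that with non-zero effects
the marginal mean sits slightly below base_mean (by β_sex·P(male) +
β_hc·P(HC)); base_mean is the female-non-HC-at-mean-age intercept.

N1 and P2 component slopes derive from the N1P2 slope by a fixed split
(N1 = −0.45, P2 = +0.55 of N1P2), which reproduces the internal relations
of the published component slopes (e.g., FCz −0.150/+0.180/0.331).

Ages are uniform on 18–71 — chosen for covariate spread, not demographic
realism. Sex counts are deterministic (round(n·0.65) females). Depression
(BDI-II) and stress (PSS-10) totals are negative-binomial draws matched to
the published mean/SD (4.83 ± 5.59 and 10.80 ± 5.46), clipped to instrument
bounds, independent of the slope by default (optional couplings exist for
power studies only). Cognitive domain T-scores are modestly correlated
normals (r = 0.3) with the published domain means/SDs; the global index is
their mean.

**Sessions.** A session realizes the true slope plus independent
within-subject noise with variance σ_w² = σ_b²(1−ρ)/ρ, where σ_b is the
marginal between-subject SD and ρ the target single-measure reliability
(default 0.8). Two-session data then have expected single-measure ICC ρ and
expected average-measures ICC 2ρ/(1+ρ) = 0.889.

## Continuous recording synthesis

A session recording (2048 Hz, 21-channel 10–20 subset + EOG) is a sum of:

- 1/f background noise (default exponent 1, RMS 10 µV per channel),
- optional line-noise sinusoid (off by default; a notch is available),
- blink transients (300 ms sin² lobes, 100 µV at the EOG, propagated over
  the frontal scalp with fixed coefficients),
- occasionally a "bad" channel replaced by 80 µV white noise (never the
  midline analysis channels, mastoids or EOG — the generator emulates a
  recording in which the analysis channels were usable),
- the evoked response: at each tone, Gaussian lobes for N1 (centered
  100 ms, σ = 15 ms) and P2 (centered 180 ms, σ = 20 ms), negative and
  positive respectively.

Tone sequencing follows the paradigm: 80 trials per level (5 levels),
pseudo-random order with no immediate intensity repeats, ISI uniform
1200–1800 ms. Onsets are locked to a 4-sample grid (≈2 ms frame clock) so
decimation to 512 Hz preserves trial alignment exactly.

**Amplitude model.** The injected N1P2 peak-to-peak at a midline channel
follows the subject's session slope, with the line anchored at the softest
level: amplitude(dB) = A₅₅ + slope·(dB − 55), where A₅₅ is the cohort mean
amplitude at 55 dB (base amplitude at 75 dB minus 20·mean slope). Anchoring
at the soft end makes a subject's overall response size covary with their
loudness dependence — steep subjects have big responses at loud levels —
instead of allowing impossible negative amplitudes at 55 dB for steep
subjects, while preserving the published mean amplitude at every level.
Targets are floored at 0.5 µV (evoked components do not invert); when the
floor binds (rare, ≈0.1% of channel-sessions) the injected series is no
longer exactly linear and the generated slope is defined as the OLS slope
of the injected series. Mastoid-adjacent channels (P9/P10) carry no evoked
signal, which makes linked-mastoid referencing transparent to the evoked
response; non-midline scalp channels carry 0.6× the FCz response.

**Injection calibration.** The measurement chain (polyphase decimation and
zero-phase 1–30 Hz filtering) attenuates the template peak-to-peak by
≈1%, which would bias every recovered slope multiplicatively. The
generator therefore calibrates the two lobe amplitudes against the chain: a
2×2 Newton solve on the filtered unit-lobe responses (a deterministic
function of the configuration, cached) chooses injection amplitudes such
that the standard pipeline reads back exactly the configured N1 and P2
values. With calibration the full chain recovers generated slopes to
< 0.001 µV/dB; `calibrate_injection=False` restores raw nominal templates
(N1 depth 0.45·A, P2 height 0.55·A).

## Preprocessing chain

Fixed order: resample to 512 Hz (polyphase, events re-indexed rounding half
down) → zero-phase Butterworth filters (1 Hz high-pass order 4, 30 Hz
low-pass order 5, optional notch) → robust average reference → 1 s-window
segment rejection → noisy-channel removal → EOG regression →
spherical-spline interpolation of bad channels → epoching ([−100, 450] ms)
→ baseline correction (mean of [−100, 0) ms) → linked-mastoid
re-referencing (P9/P10 mean) → 50 µV epoch rejection at Fz/FCz/Cz.

Numerical and boundary choices:

- Filter orders: forward–backward application doubles the roll-off; order 5
  for the low-pass keeps a 50 Hz line component below 1% of its input
  amplitude, while the gentler order-4 high-pass limits slow ringing tails
  that would otherwise leak between neighbouring trials. Both exceed 40 dB
  attenuation one octave outside the cutoffs.
- Robust reference: channels with raw SD below 1 µV are dead and excluded
  up front (relative to any reference they would merely mirror the
  reference). The remaining channels are tested against the mean of the
  surviving set — re-referenced SD must lie in [1, 25] µV — iterating, with
  re-admission allowed, until the included set is a fixed point. Exclusions
  affect the reference estimate only: excluded channels stay in the data
  and are not interpolated. On data violating the rule's amplitude
  assumptions (e.g., fully noise-free simulations) the pipeline falls back
  to the plain average reference and records that in provenance. Since
  epochs are later re-referenced to the linked mastoids, any common
  reference cancels exactly and the choice cannot bias the slopes.
- "More than 50% of channels", "more than 10% of data points" and "above
  50 µV" are strict inequalities. Segment rejection uses within-window
  peak-to-peak > 100 µV as its noise criterion (window length 1 s).
- Epoch sample indices run −floor(0.100·rate) … floor(0.450·rate)
  inclusive — 282 samples at 512 Hz with epoch index 51 at stimulus onset.
- EOG regression (OLS of each EEG channel on the EOG, estimated on the full
  recording) stands in for component-based ocular artifact removal; the
  notch stands in for dedicated line-noise removal. Both stand-ins are
  recorded in run provenance. The regression is skipped, with a provenance
  note, when the EOG channel is flat (nothing to remove).
- Spherical-spline interpolation uses order m = 4 with the Legendre series
  truncated at 7 terms; electrode positions come from the standard 10–20
  montage projected to the unit sphere.

## Peak measurement and slopes

Per intensity, retained epochs are averaged; N1 is the most negative value
in the closed window 60–140 ms, P2 the most positive in 150–250 ms, ties
breaking earliest, window membership decided on exact sample latencies and
reported latencies rounded to the nearest ms. No local-extremum requirement
is imposed (a window-edge extremum is accepted). Manual peak selection is
an explicit override table (channel, intensity, component → latency); the
amplitude is read at that latency and the row flagged. Slopes are then OLS
per component × channel; reported to 3 decimals in output tables.

## Reliability

The primary coefficient is the two-way, absolute-agreement,
average-measures ICC, ICC(A,k) = (MSR − MSE)/(MSR + (MSC − MSE)/n), with
the F-based 95% interval of McGraw & Wong. The protocol this package
follows describes "a two-way mixed model with absolute agreement, average
measures" while bracketing it "ICC(3,k)" — a Shrout–Fleiss *consistency*
label. The verbal description is the more specific statement, so the
agreement form is primary; the consistency form ICC(C,k) is available via
`form="consistency"`. The agreement coefficient is identically the
Spearman–Brown step applied to the single-measure agreement coefficient,
and it is penalized by systematic between-session offsets that leave the
Pearson correlation untouched — the sense in which it is the more
conservative reliability estimate. A subject whose session difference
exceeds 3.5 SD from the group mean on *all* nine cells (conjunction) is
flagged as a probable technical error but not auto-removed.

## Cohort statistics

The group model is a linear mixed model fitted by REML (statsmodels
MixedLM): N1P2 slope ~ channel (within-subject, Fz reference) + group +
centered age, subject random intercept; group is sex (female reference) or
HC use (non-user reference, analysis restricted to females under 42).
Degrees of freedom use a containment-style approximation in the
Satterthwaite spirit: between-subject terms are tested on subject-level df
(n_subjects − #between terms), within-subject terms on residual df; a plain
residual-df option exists. Kenward–Roger adjustment is deliberately not
implemented — at n ≈ 100 subjects its effect on these tests is negligible
relative to its implementation weight. Estimated marginal means are
computed from the fixed effects at the covariate mean per channel × group;
the post hoc contrast (reference − coded group) is a Wald t on the EMM
difference, and Cohen's d uses the pooled *observed* per-group slope SDs
(the conventional pooled-SD form, since the published effect sizes are not
defined further). Correlations are Pearson with Bonferroni-corrected
significance flags (the divisor m is configurable; the age analysis uses
m = 4 following the source convention); partial correlations residualize
both variables on the control and use n − 3 df. The depression split uses
total ≥ 10 (inclusive) with a Welch t-test per channel.

Estimation uses lbfgs with gradient-free fallbacks (Powell, Nelder–Mead)
because near-singular variance profiles — which arise legitimately in
noise-free simulations — break gradient-based REML; singular fits are
flagged, not hidden.

## Simulation studies and problem sizes

The replicated studies in `ldaep.experiments` use these sizes, chosen to
estimate each quantity to well under its tolerance:

- Noise-free transparency: 10 subjects × 9 cells, 4 trials/level (noise-free
  epochs are identical, so averaging more trials is a no-op).
- Reliability: one cohort of n = 2000 (ICC standard error ≈ 0.004) plus 500
  replicates at the study's n = 38.
- Covariate recovery: 200 replicates of n = 100 (65 F / 35 M), generated
  with only the sex and age effects active — the recovery model contains
  exactly those terms, and a non-zero HC effect would confound both since
  HC use is confined to young females.
- Null calibration: 500 replicates of n = 100 (rejection-rate standard
  error ≈ 0.010 at the nominal 0.05).

These studies run at the slope level (no continuous EEG), which is exact
because session slopes, not waveforms, carry all the statistical structure;
the EEG path is validated separately by the transparency study.

## What passing tests do and do not show

The generator embodies the analysis' own assumptions: linear
amplitude–intensity growth, stationary Gaussian-ish background, additive
blinks, a fixed N1:P2 split, and session noise that is independent and
homoscedastic. Passing recovery tests therefore demonstrates that the
pipeline and estimators are faithful to that model — not that real EEG
satisfies it. Known divergences from real data: no alpha rhythm or other
narrowband activity, no latency jitter or habituation across trials, no
amplitude saturation at high intensities, simplistic blink topography, and
stimulus timing locked to a 2 ms grid. Published coefficients from the
motivating study (ICCs, t and d values, β estimates) are used as generator
defaults and recovery nominals; they are not reproducible from raw data
within this package.
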