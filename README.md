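# ldaep

Loudness dependence of the auditory evoked potential (LDAEP): a complete,
tested analysis chain for EEG researchers who measure how the N1/P2
components of the auditory evoked potential grow with tone intensity.
The LDAEP — the slope of component amplitude on stimulus loudness — is
studied as a putative inverse proxy of central serotonergic activity and as
a candidate predictor of SSRI treatment response; using it in clinical or
repeated-measures designs requires exactly the machinery packaged here:
a reproducible preprocessing and peak-measurement pipeline, the slope
statistic, test–retest reliability, and cohort statistics for the
covariates known to move the LDAEP (sex, age, hormonal-contraceptive use).

## The statistic

For tones at 55–95 dB, per-level evoked amplitudes y (µV) are regressed on
intensity x (dB):

    LDAEP = Σ(x − x̄)(y − ȳ) / Σ(x − x̄)²

for the N1 (most negative value 60–140 ms), P2 (most positive value
150–250 ms) and the N1P2 peak-to-peak difference, at midline channels Fz,
FCz, Cz. Reliability across sessions is the two-way absolute-agreement
average-measures intraclass correlation ICC(A,k) with its F-based 95% CI;
group effects are estimated with a linear mixed model (channel as
within-subject factor, subject random intercept, age covariate) followed by
estimated-marginal-mean contrasts with Cohen's d.

Because raw study EEG is not distributed, the package includes a
first-class synthetic-cohort generator that emulates the study conditions
(100 subjects, 65 F/35 M, ages 18–71; 5 intensities × 80 trials, ISI
1.2–1.8 s, 2048 Hz; two sessions at controllable reliability; 1/f noise,
blinks, bad channels) so every downstream stage is testable end to end.
See `docs/methods.md` for the model and its limits.

## Worked example

The packaged reference table of per-level mean amplitudes doubles as a
worked example: regressing each row on intensity must reproduce the
published mean slope. From the shell:

```bash
$ ldaep check-table2
channel component  computed_slope  printed_slope  abs_diff  pass
     Fz        N1         -0.1261         -0.126    0.0001  True
     Fz        P2          0.1404          0.140    0.0004  True
     Fz      N1P2          0.2664          0.267    0.0006  True
    FCz        N1         -0.1502         -0.150    0.0002  True
    FCz        P2          0.1803          0.180    0.0003  True
    FCz      N1P2          0.3307          0.331    0.0003  True
     Cz        N1         -0.1301         -0.130    0.0001  True
     Cz        P2          0.1631          0.163    0.0001  True
     Cz      N1P2          0.2931          0.293    0.0001  True
```

Every deviation is within the ±0.002 rounding tolerance of two-decimal
amplitude inputs, confirming the published slopes are plain per-dB OLS
coefficients (despite the conventional "µV/10 dB" column label). The same
check is available in Python as `ldaep.reproduce_table2_check()`.

An end-to-end simulated run (generate → preprocess → peaks → slopes →
reliability → statistics):

```bash
ldaep run-all --n-subjects 12 --sessions 2 --seed 2026 --out demo_run
```

writes `cohort_table.tsv`, `summary.tsv`, `reliability.tsv`,
`group_stats.json`, `report.txt` and `provenance.json`. With 12 subjects at
reduced trial counts, `python analysis/06_pipeline_demo.py` prints, for the
N1P2 component:

```
channel component  pearson_r   icc  ci_low  ci_high      band
     Cz      N1P2      0.771 0.875   0.566    0.964      good
    FCz      N1P2      0.872 0.931   0.761    0.980 excellent
     Fz      N1P2      0.858 0.911   0.694    0.974 excellent
```

i.e., measured slopes correlate strongly across the two simulated sessions
and the agreement ICC lands near the value implied by the generator's
session-reliability setting.

## Analysis scripts

The numbered drivers under `analysis/` run the package's computational
studies and write their tables under `results/`:

1. `01_reference_slope_consistency.py` — the worked example above.
2. `02_noise_free_transparency.py` — noise-free subjects pass the full
   pipeline with slope errors below 0.001 µV/dB (worst observed ≈ 7e-4).
3. `03_reliability_simulation.py` — ICC(A,k) converges to 2ρ/(1+ρ) at
   large n and scatters widely at the study's n = 38.
4. `04_covariate_recovery.py` — the mixed model recovers the generating
   sex (−0.084) and age (−0.003) coefficients, within 2 SE in ≈95% of
   replicate cohorts.
5. `05_null_calibration.py` — distress tests reject at the nominal 5%
   under null couplings.
6. `06_pipeline_demo.py` — the noisy end-to-end demonstration above.

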