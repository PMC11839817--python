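"""Replicated simulation studies over the synthetic cohort.

These are the package's computational experiments: noise-free end-to-end
transparency, reliability recovery at large and study-sized n, mixed-model
fixed-effect recovery, and type-I-error calibration of the distress and
cognition tests under null couplings. Each function is deterministic given
its seed and returns plain data structures so the analysis drivers, the
test suite and the acceptance script can share them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import GeneratorConfig, PreprocessParams
from .pipeline import process_recording
from .recording import generate_recording, subject_rng
from .reliability import icc_agreement_k
from .slopes import CHANNELS, COMPONENTS
from .stats import MixedModelSpec, bdi_dichotomize_compare, correlate, \
    fit_channel_mixed_model
from .synthetic import cohort_with_sessions, covariates_frame, \
    generate_cohort, slopes_frame


def noise_free_config(seed: int, n_subjects: int = 10,
                      trials_per_level: int = 4) -> GeneratorConfig:
    """Study paradigm with every noise source disabled; trial count reduced
    because noise-free epochs are identical and averaging is a no-op."""
    return GeneratorConfig(
        n_subjects=n_subjects, trials_per_level=trials_per_level,
        noise_rms_uv=0.0, blink_rate_per_min=0.0, bad_channel_prob=0.0,
        line_noise_amplitude_uv=0.0, seed=seed)


def noise_free_recovery(seed: int = 0, n_subjects: int = 10
                        ) -> pd.DataFrame:
    """Generate noise-free subjects, run the full preprocessing + peak +
    slope chain, and compare recovered slopes with the slopes of the
    generated (injected) amplitude series for all 9 component x channel
    cells. Whenever the amplitude floor does not bind, the generated N1P2
    slope equals the subject's session slope exactly."""
    from .recording import target_amplitudes
    from .slopes import ldaep_slope

    config = noise_free_config(seed, n_subjects)
    params = PreprocessParams()
    subjects = cohort_with_sessions(config, n_sessions=1)
    frac = {"N1": -config.n1_fraction, "P2": 1.0 - config.n1_fraction,
            "N1P2": 1.0}
    rows = []
    for idx, subject in enumerate(subjects):
        rng = subject_rng(config, idx, 1)
        recording, events = generate_recording(subject, 1, config, rng,
                                               params)
        result, _, _ = process_recording(recording, events, params,
                                         subject.subject_id, 1)
        targets = target_amplitudes(subject, 1, config)
        for ch in CHANNELS:
            gen_n1p2 = ldaep_slope(
                [targets[ch][lvl] for lvl in config.intensities],
                config.intensities)
            for comp in COMPONENTS:
                truth = frac[comp] * gen_n1p2
                rows.append({"subject_id": subject.subject_id,
                             "channel": ch, "component": comp,
                             "generated": truth,
                             "session_slope": subject.component_slope(
                                 comp, ch, 1, config.n1_fraction),
                             "recovered": result.slope[(comp, ch)],
                             "abs_error": abs(result.slope[(comp, ch)]
                                              - truth)})
    return pd.DataFrame(rows)


def reliability_large_n(seed: int = 0, n_subjects: int = 2000,
                        rho: float = 0.8, channel: str = "FCz"
                        ) -> dict:
    """Average-measures agreement ICC of two-session slopes at large n,
    against the Spearman-Brown value 2*rho/(1+rho)."""
    config = GeneratorConfig(n_subjects=n_subjects, session_reliability=rho,
                             seed=seed)
    subjects = cohort_with_sessions(config, n_sessions=2)
    matrix = np.array([[s.session_slopes[0][channel],
                        s.session_slopes[1][channel]] for s in subjects])
    icc, ci = icc_agreement_k(matrix)
    return {"icc": icc, "ci": ci, "nominal": 2 * rho / (1 + rho),
            "n": n_subjects}


def reliability_replicates(seed: int = 0, n_subjects: int = 38,
                           n_replicates: int = 500, rho: float = 0.8,
                           channel: str = "FCz") -> np.ndarray:
    """Sampling distribution of the agreement ICC at study-sized cohorts."""
    root = np.random.SeedSequence([seed, 38])
    iccs = np.empty(n_replicates)
    for i, child in enumerate(root.spawn(n_replicates)):
        config = GeneratorConfig(n_subjects=n_subjects,
                                 session_reliability=rho,
                                 seed=int(child.generate_state(1)[0]
                                          % 2**31))
        subjects = cohort_with_sessions(config, n_sessions=2)
        matrix = np.array([[s.session_slopes[0][channel],
                            s.session_slopes[1][channel]]
                           for s in subjects])
        iccs[i], _ = icc_agreement_k(matrix)
    return iccs


def sex_age_recovery(seed: int = 0, n_replicates: int = 200,
                     n_subjects: int = 100) -> pd.DataFrame:
    """Fit the channel mixed model to replicate cohorts generated with the
    reference sex and age coefficients; one row per replicate with the
    estimates, their SEs, and whether each estimate falls within 2 SE of
    the generating value.

    Only the sex and age effects are switched on (the model being recovered
    contains exactly those terms; a nonzero contraceptive effect would
    confound both, since it is confined to young females)."""
    root = np.random.SeedSequence([seed, 100])
    rows = []
    for child in root.spawn(n_replicates):
        config = GeneratorConfig(n_subjects=n_subjects, beta_hc=0.0,
                                 seed=int(child.generate_state(1)[0]
                                          % 2**31))
        subjects = cohort_with_sessions(config, n_sessions=1)
        table = slopes_frame(subjects, config, sessions=(1,)).merge(
            covariates_frame(subjects), on=["subject_id", "session"])
        model = fit_channel_mixed_model(table, MixedModelSpec())
        sex = model.coefficient("group01")
        age = model.coefficient("cov_c")
        rows.append({
            "sex_estimate": sex["estimate"], "sex_se": sex["se"],
            "sex_within_2se": bool(abs(sex["estimate"] - config.beta_sex)
                                   <= 2 * sex["se"]),
            "age_estimate": age["estimate"], "age_se": age["se"],
            "age_within_2se": bool(abs(age["estimate"] - config.beta_age)
                                   <= 2 * age["se"]),
        })
    return pd.DataFrame(rows)


def null_calibration(seed: int = 0, n_replicates: int = 500,
                     n_subjects: int = 100, alpha: float = 0.05) -> dict:
    """Type-I-error rates of the distress tests under null couplings.

    For each replicate cohort (distress and cognition independent of slope
    by construction) the Pearson test of the FCz N1P2 slope against the
    depression total and the dichotomized Welch test are run at level
    ``alpha``; returns empirical rejection rates."""
    root = np.random.SeedSequence([seed, 500])
    rej_corr = rej_group = 0
    n_group = 0
    for child in root.spawn(n_replicates):
        config = GeneratorConfig(n_subjects=n_subjects,
                                 seed=int(child.generate_state(1)[0]
                                          % 2**31))
        subjects = cohort_with_sessions(config, n_sessions=1)
        table = slopes_frame(subjects, config, sessions=(1,)).merge(
            covariates_frame(subjects), on=["subject_id", "session"])
        sub = table[(table["component"] == "N1P2")
                    & (table["channel"] == "FCz")]
        res = correlate(sub["bdi_total"].to_numpy(),
                        sub["slope"].to_numpy())
        if res["p"] < alpha:
            rej_corr += 1
        try:
            welch = bdi_dichotomize_compare(table)
            n_group += 1
            if welch.loc[welch["channel"] == "FCz", "p"].iloc[0] < alpha:
                rej_group += 1
        except ValueError:
            pass  # a replicate with an empty group contributes no test
    return {"correlation_rejection_rate": rej_corr / n_replicates,
            "group_rejection_rate": rej_group / max(n_group, 1),
            "n_replicates": n_replicates,
            "n_group_tests": n_group,
            "alpha": alpha}


def slope_moment_check(seed: int = 0, n_subjects: int = 2000) -> pd.DataFrame:
    """Empirical cohort slope mean/SD vs configured values at large n."""
    config = GeneratorConfig(n_subjects=n_subjects, seed=seed)
    subjects = generate_cohort(config)
    rows = []
    for ch in CHANNELS:
        vals = np.array([s.slope_n1p2[ch] for s in subjects])
        rows.append({"channel": ch,
                     "mean": vals.mean(),
                     "sd": vals.std(ddof=1),
                     "configured_mean": config.base_slope_mean[ch],
                     "configured_sd": config.base_slope_sd[ch]})
    return pd.DataFrame(rows)
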