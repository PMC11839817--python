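"""Synthetic LDAEP cohorts.

Subjects carry a per-channel "true" N1P2 loudness-dependence slope built
from a linear covariate model (sex, age, hormonal-contraceptive use) plus a
subject deviation whose SD is chosen so that the marginal slope SD matches
the configured value. N1 and P2 component slopes are derived from the N1P2
slope by the configured split (N1 negative share, P2 positive share), which
reproduces the internal consistency of the published component slopes.

Sessions realize the true slope with independent within-subject noise whose
variance is set from the target single-measure reliability rho:
sigma_w^2 = sigma_b^2 (1 - rho)/rho, so two-session data have expected
single-measure ICC equal to rho.

All randomness flows from the single config seed through a SeedSequence
tree, so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import defaults as d
from .config import GeneratorConfig

CHANNELS = d.MIDLINE_CHANNELS


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject."""

    subject_id: str
    sex: str                      # 'F' or 'M'
    age: float
    hc_use: bool | None           # defined for females only
    slope_n1p2: dict              # channel -> true N1P2 slope (uV/dB)
    session_slopes: list = field(default_factory=list)  # per session: channel -> slope
    bdi_total: int = 0
    pss_total: int = 0
    cognitive_T: dict = field(default_factory=dict)

    def component_slope(self, component: str, channel: str,
                        session: int | None = None,
                        n1_fraction: float = 0.45) -> float:
        """Derive a component slope from the (true or session) N1P2 slope."""
        base = (self.slope_n1p2[channel] if session is None
                else self.session_slopes[session - 1][channel])
        if component == "N1P2":
            return base
        if component == "N1":
            return -n1_fraction * base
        if component == "P2":
            return (1 - n1_fraction) * base
        raise ValueError(f"unknown component {component!r}")


def covariate_variance(config: GeneratorConfig) -> float:
    """Variance of the covariate part of the slope model, including the
    sex/HC and age/HC covariances induced by HC being confined to young
    females."""
    p_m = 1 - config.sex_ratio
    lo, hi = config.age_range
    var_age = (hi - lo) ** 2 / 12.0
    p_young = min(max((config.hc_age_cutoff - lo) / (hi - lo), 0.0), 1.0)
    p_h = config.sex_ratio * p_young * config.hc_fraction
    bs, ba, bh = config.beta_sex, config.beta_age, config.beta_hc
    var = (bs ** 2 * p_m * (1 - p_m) + ba ** 2 * var_age
           + bh ** 2 * p_h * (1 - p_h))
    var += 2 * bs * bh * (-p_m * p_h)
    if p_young > 0:
        mean_young = (lo + min(config.hc_age_cutoff, hi)) / 2.0
        cov_ah = p_h * (mean_young - (lo + hi) / 2.0)
        var += 2 * ba * bh * cov_ah
    return var


def generate_cohort(config: GeneratorConfig,
                    rng: np.random.Generator | None = None
                    ) -> list[SubjectTruth]:
    """Draw a cohort of subjects with covariates and true slopes.

    Raises if the covariate effects already imply a marginal slope SD larger
    than the configured one (impossible variance decomposition).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_subjects
    var_cov = covariate_variance(config)
    resid_sd = {}
    for ch in CHANNELS:
        resid_var = config.base_slope_sd[ch] ** 2 - var_cov
        if resid_var < -1e-15:
            raise ValueError(
                f"covariate effects imply marginal slope SD "
                f"{np.sqrt(var_cov):.3f} exceeding configured "
                f"{config.base_slope_sd[ch]:.3f} at {ch}")
        resid_sd[ch] = np.sqrt(max(resid_var, 0.0))

    # deterministic sex counts, shuffled order
    n_f = int(round(n * config.sex_ratio))
    sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sexes)
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n)
    mean_age = (lo + hi) / 2.0

    # subject deviations: correlated across channels
    rho = config.channel_correlation
    corr = np.full((3, 3), rho)
    np.fill_diagonal(corr, 1.0)
    sds = np.array([resid_sd[ch] for ch in CHANNELS])
    cov = corr * np.outer(sds, sds)
    devs = rng.multivariate_normal(np.zeros(3), cov, size=n, method="svd")

    subjects = []
    for i in range(n):
        sex, age = str(sexes[i]), float(ages[i])
        hc: bool | None = None
        if sex == "F":
            hc = bool(age < config.hc_age_cutoff
                      and rng.random() < config.hc_fraction)
        slope = {}
        for j, ch in enumerate(CHANNELS):
            val = (config.base_slope_mean[ch]
                   + config.beta_sex * (sex == "M")
                   + config.beta_age * (age - mean_age)
                   + config.beta_hc * bool(hc)
                   + devs[i, j])
            slope[ch] = float(val)

        z = 0.0
        if config.base_slope_sd["FCz"] > 0:
            z = (slope["FCz"] - config.base_slope_mean["FCz"]) \
                / config.base_slope_sd["FCz"]
        bdi = _draw_count(rng, d.BDI_MEAN, d.BDI_SD, d.BDI_MAX,
                          config.bdi_slope_coupling * z)
        pss = _draw_count(rng, d.PSS_MEAN, d.PSS_SD, d.PSS_MAX,
                          config.pss_slope_coupling * z)
        cog = _draw_cognitive(rng, config.cognitive_slope_coupling * z)

        subjects.append(SubjectTruth(
            subject_id=f"S{i + 1:03d}", sex=sex, age=age, hc_use=hc,
            slope_n1p2=slope, bdi_total=bdi, pss_total=pss,
            cognitive_T=cog))
    return subjects


def _draw_count(rng: np.random.Generator, mean: float, sd: float,
                upper: int, shift: float = 0.0) -> int:
    """Right-skewed bounded count via a negative binomial matched to the
    instrument's mean and SD (distress scores pile up near zero in healthy
    cohorts)."""
    var = sd ** 2
    if var <= mean:   # fall back to Poisson if under-dispersed
        val = rng.poisson(mean)
    else:
        r = mean ** 2 / (var - mean)
        p = r / (r + mean)
        val = rng.negative_binomial(r, p)
    return int(np.clip(round(val + shift), 0, upper))


def _draw_cognitive(rng: np.random.Generator, shift: float = 0.0) -> dict:
    """Cognitive domain T-scores (modestly inter-correlated) plus the global
    index as the domain mean."""
    names = list(d.COGNITIVE_DOMAINS)
    means = np.array([d.COGNITIVE_DOMAINS[k][0] for k in names])
    sds = np.array([d.COGNITIVE_DOMAINS[k][1] for k in names])
    corr = np.full((len(names), len(names)), 0.3)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sds, sds)
    vals = rng.multivariate_normal(means, cov, method="svd") + shift
    out = {k: float(v) for k, v in zip(names, vals)}
    out["global_index"] = float(np.mean(vals))
    return out


def realize_sessions(truth: SubjectTruth, config: GeneratorConfig,
                     n_sessions: int = 2,
                     rng: np.random.Generator | None = None) -> SubjectTruth:
    """Realize per-session slopes with within-subject noise set by the target
    single-measure reliability."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    rho = config.session_reliability
    if not 0.0 < rho <= 1.0:
        raise ValueError("session_reliability must lie in (0, 1]")
    sessions = []
    for _ in range(n_sessions):
        real = {}
        for ch in CHANNELS:
            sb2 = config.base_slope_sd[ch] ** 2
            if sb2 == 0:
                raise ValueError("between-subject slope variance is zero; "
                                 "session reliability undefined")
            sw = np.sqrt(sb2 * (1 - rho) / rho)
            real[ch] = float(truth.slope_n1p2[ch] + rng.normal(0.0, sw))
        sessions.append(real)
    truth.session_slopes = sessions
    return truth


def cohort_with_sessions(config: GeneratorConfig, n_sessions: int = 2
                         ) -> list[SubjectTruth]:
    """Cohort plus realized sessions, all driven by the config seed."""
    root = np.random.SeedSequence(config.seed)
    ss_cohort, ss_sessions = root.spawn(2)
    subjects = generate_cohort(config, np.random.default_rng(ss_cohort))
    rng = np.random.default_rng(ss_sessions)
    for s in subjects:
        realize_sessions(s, config, n_sessions, rng)
    return subjects


def covariates_frame(subjects: Sequence[SubjectTruth],
                     sessions: Sequence[int] = (1,)) -> pd.DataFrame:
    """Tidy covariate table (one row per subject x session)."""
    rows = []
    for s in subjects:
        for sess in sessions:
            row = {"subject_id": s.subject_id, "session": sess,
                   "sex": s.sex, "age": s.age, "hc_use": s.hc_use,
                   "bdi_total": s.bdi_total, "pss_total": s.pss_total}
            row.update({f"cog_{k}": v for k, v in s.cognitive_T.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def slopes_frame(subjects: Sequence[SubjectTruth], config: GeneratorConfig,
                 sessions: Sequence[int] = (1,),
                 use_session_slopes: bool = True) -> pd.DataFrame:
    """Long table of generated (not pipeline-measured) slopes, one row per
    subject x session x channel x component; the fast path for statistical
    simulation studies that do not need continuous EEG."""
    rows = []
    for s in subjects:
        for sess in sessions:
            for ch in CHANNELS:
                for comp in ("N1", "P2", "N1P2"):
                    val = s.component_slope(
                        comp, ch, sess if use_session_slopes else None,
                        config.n1_fraction)
                    rows.append({"subject_id": s.subject_id, "session": sess,
                                 "channel": ch, "component": comp,
                                 "slope": val})
    return pd.DataFrame(rows)
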