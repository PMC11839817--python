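"""Group-level statistics for LDAEP slopes.

The central model is a linear mixed model with the per-channel N1P2 slope as
response, channel (Fz/FCz/Cz) as a within-subject factor, a two-level group
factor (sex, or hormonal-contraceptive use within young females), age as a
covariate, and a subject random intercept estimated by REML. Post hoc
group contrasts are taken on estimated marginal means (EMMs) at the
covariate mean, with Cohen's d from the observed per-group slope SDs.

Degrees of freedom use a containment-style (Satterthwaite-flavoured)
approximation: between-subject terms are tested against subject-level df,
within-subject terms against residual df; a plain residual-df fallback is
available. Kenward-Roger adjustment is not implemented — at cohort sizes of
about 100 subjects the difference is negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class MixedModelSpec:
    component: str = "N1P2"
    group_factor: str = "sex"       # column in the cohort table
    group_levels: tuple[str, str] = ("F", "M")   # (reference, coded 1)
    covariate: str = "age"
    interaction: bool = False       # channel x group interaction
    df_method: str = "satterthwaite"  # or "residual"


@dataclass
class ModelResult:
    coefficients: pd.DataFrame      # term, estimate, se, stat, df, p, ci
    variance_subject: float
    variance_residual: float
    converged: bool
    singular: bool
    spec: MixedModelSpec = None
    channels: tuple[str, ...] = ()
    covariate_mean: float = 0.0
    _params: np.ndarray = field(default=None, repr=False)
    _cov: np.ndarray = field(default=None, repr=False)
    _names: list = field(default_factory=list, repr=False)
    _data: pd.DataFrame = field(default=None, repr=False)

    def coefficient(self, term: str) -> pd.Series:
        sub = self.coefficients[self.coefficients["term"] == term]
        if sub.empty:
            raise KeyError(f"no coefficient {term!r}")
        return sub.iloc[0]


def _term_df(names, n_subjects: int, n_rows: int, method: str) -> dict:
    """Approximate denominator df per fixed-effect term."""
    p = len(names)
    between = [n for n in names if "channel" not in n]
    within = [n for n in names if "channel" in n]
    out = {}
    for n in names:
        if method == "residual":
            out[n] = n_rows - p
        elif n in between:
            out[n] = n_subjects - len(between)
        else:
            out[n] = n_rows - n_subjects - len(within) + 1
    return out


def fit_channel_mixed_model(table: pd.DataFrame, spec: MixedModelSpec
                            ) -> ModelResult:
    """Fit the channel-within-subject mixed model by REML.

    ``table`` is the long cohort table; rows are filtered to the requested
    component and complete cases on response, group and covariate.
    """
    df = table[table["component"] == spec.component].copy()
    df = df.dropna(subset=["slope", spec.group_factor, spec.covariate])
    if df.empty:
        raise ValueError("no complete cases for the mixed model")
    ref, coded = spec.group_levels
    levels = set(df[spec.group_factor].unique())
    if not levels <= {ref, coded}:
        raise ValueError(f"group factor has levels {levels}, expected "
                         f"{spec.group_levels}")
    df["group01"] = (df[spec.group_factor] == coded).astype(float)
    cov_mean = float(df.drop_duplicates("subject_id")[spec.covariate].mean())
    df["cov_c"] = df[spec.covariate] - cov_mean

    rhs = "C(channel, Treatment('Fz')) + group01 + cov_c"
    if spec.interaction:
        rhs += " + C(channel, Treatment('Fz')):group01"
    model = smf.mixedlm(f"slope ~ {rhs}", df, groups=df["subject_id"])
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=True, method=method)
            except np.linalg.LinAlgError:
                continue  # near-singular profile; try a gradient-free method
            if fit.converged:
                break
    if fit is None or not fit.converged:
        raise RuntimeError("mixed model failed to converge")

    names = list(fit.fe_params.index)
    n_subjects = df["subject_id"].nunique()
    dfs = _term_df(names, n_subjects, len(df), spec.df_method)
    var_subj = float(fit.cov_re.iloc[0, 0])
    singular = var_subj < 1e-10

    rows = []
    for name in names:
        est = float(fit.fe_params[name])
        se = float(fit.bse_fe[name])
        d = dfs[name]
        t = est / se
        p = 2 * sps.t.sf(abs(t), d)
        crit = sps.t.ppf(0.975, d)
        rows.append({"term": name, "estimate": est, "se": se, "stat": t,
                     "df": d, "p": p, "ci_low": est - crit * se,
                     "ci_high": est + crit * se})
    coefs = pd.DataFrame(rows)
    k = len(names)
    return ModelResult(
        coefficients=coefs, variance_subject=var_subj,
        variance_residual=float(fit.scale), converged=bool(fit.converged),
        singular=singular, spec=spec,
        channels=tuple(sorted(df["channel"].unique())),
        covariate_mean=cov_mean,
        _params=fit.fe_params.to_numpy(),
        _cov=np.asarray(fit.cov_params())[:k, :k],
        _names=names, _data=df)


def _design_row(result: ModelResult, channel: str, group01: float
                ) -> np.ndarray:
    """Fixed-effects design row for a channel x group cell at the covariate
    mean (centered covariate = 0)."""
    x = np.zeros(len(result._names))
    for i, name in enumerate(result._names):
        if name == "Intercept":
            x[i] = 1.0
        elif name == "group01":
            x[i] = group01
        elif name == "cov_c":
            x[i] = 0.0
        elif f"[T.{channel}]" in name:
            x[i] = group01 if ":group01" in name else 1.0
    return x


def emm_posthoc(result: ModelResult, channel: str) -> dict:
    """Group EMMs at the covariate mean for one channel, their contrast
    t-test, and Cohen's d from observed per-group slope SDs."""
    if channel not in result.channels:
        raise ValueError(f"channel {channel!r} not in fitted model")
    ref, coded = result.spec.group_levels
    beta, V = result._params, result._cov
    out = {"channel": channel}
    xs = {}
    for label, g in ((ref, 0.0), (coded, 1.0)):
        x = _design_row(result, channel, g)
        xs[label] = x
        out[f"emm_{label}"] = float(x @ beta)
        out[f"se_{label}"] = float(np.sqrt(x @ V @ x))

    c = xs[ref] - xs[coded]          # reference minus coded group
    est = float(c @ beta)
    se = float(np.sqrt(c @ V @ c))
    dfree = float(result.coefficient("group01")["df"])
    t = est / se
    p = 2 * sps.t.sf(abs(t), dfree)

    obs = result._data[result._data["channel"] == channel]
    g_ref = obs.loc[obs["group01"] == 0.0, "slope"].to_numpy()
    g_cod = obs.loc[obs["group01"] == 1.0, "slope"].to_numpy()
    if len(g_ref) == 0 or len(g_cod) == 0:
        raise ValueError("empty group at this channel")
    d = cohens_d(g_ref, g_cod)
    out.update({"contrast": est, "se_contrast": se, "t": t, "df": dfree,
                "p": p, "d": d,
                f"mean_{ref}": float(g_ref.mean()),
                f"mean_{coded}": float(g_cod.mean())})
    return out


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled observed SD: (mean_a - mean_b) / s_pooled."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                 / (na + nb - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def correlate(x: np.ndarray, y: np.ndarray, bonferroni_m: int = 1,
              alpha: float = 0.05) -> dict:
    """Pearson correlation with Bonferroni-adjusted significance flag."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(x)),
            "alpha_corrected": alpha / bonferroni_m,
            "significant": bool(p < alpha / bonferroni_m)}


def partial_correlation(x: np.ndarray, y: np.ndarray, control: np.ndarray
                        ) -> tuple[float, float]:
    """Correlation of x and y after removing the control variable from both
    (residuals of OLS on the control); p uses n - 3 df."""
    x, y, z = (np.asarray(v, float) for v in (x, y, control))
    mask = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[mask], y[mask], z[mask]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete triples")
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if rx.std() < 1e-12 or ry.std() < 1e-12:
        raise ValueError("variable collinear with control; partial "
                         "correlation degenerate")
    r = float(np.corrcoef(rx, ry)[0, 1])
    t = r * np.sqrt((n - 3) / (1 - r ** 2))
    p = float(2 * sps.t.sf(abs(t), n - 3))
    return r, p


def bdi_dichotomize_compare(table: pd.DataFrame, cutoff: int = 10,
                            component: str = "N1P2") -> pd.DataFrame:
    """Split subjects at a self-report depression cutoff (total >= cutoff is
    the symptomatic group) and Welch-t-test the N1P2 slope per channel."""
    df = table[table["component"] == component].dropna(
        subset=["slope", "bdi_total"])
    if df.empty:
        raise ValueError("no rows with depression scores")
    rows = []
    for ch, sub in df.groupby("channel"):
        hi = sub.loc[sub["bdi_total"] >= cutoff, "slope"].to_numpy()
        lo = sub.loc[sub["bdi_total"] < cutoff, "slope"].to_numpy()
        if len(hi) == 0 or len(lo) == 0:
            raise ValueError(f"empty group at cutoff {cutoff} ({ch})")
        t, p = sps.ttest_ind(hi, lo, equal_var=False)
        rows.append({"channel": ch, "n_above": len(hi), "n_below": len(lo),
                     "proportion_above": len(hi) / (len(hi) + len(lo)),
                     "mean_above": float(hi.mean()),
                     "mean_below": float(lo.mean()),
                     "t": float(t), "p": float(p),
                     "d": cohens_d(hi, lo)})
    return pd.DataFrame(rows)
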