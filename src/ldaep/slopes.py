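"""The LDAEP statistic: slope of component amplitude against tone intensity.

The loudness dependence is the ordinary-least-squares slope of the per-level
component amplitude (uV) regressed on stimulus intensity in dB. Following
field convention the coefficient is reported under a "uV/10 dB" label even
though it is numerically the per-dB coefficient; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

COMPONENTS = ("N1", "P2", "N1P2")
CHANNELS = ("Fz", "FCz", "Cz")


def ldaep_slope(amplitudes: Sequence[float],
                intensities: Sequence[float]) -> float:
    """OLS slope of amplitude on intensity: sum((x-x̄)(y-ȳ)) / sum((x-x̄)²)."""
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if x.shape != y.shape:
        raise ValueError("amplitudes and intensities must align")
    if len(np.unique(x)) < len(x):
        raise ValueError("intensities must be distinct")
    if len(x) < 3:
        raise ValueError("need at least 3 intensity levels")
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def _fit(amplitudes: np.ndarray, intensities: np.ndarray
         ) -> tuple[float, float]:
    """Slope and R² of the per-level regression."""
    slope = ldaep_slope(amplitudes, intensities)
    y = np.asarray(amplitudes, dtype=float)
    x = np.asarray(intensities, dtype=float)
    yhat = y.mean() + slope * (x - x.mean())
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum((y - yhat) ** 2) / ss_tot
    return slope, float(r2)


@dataclass
class LdaepResult:
    """Per subject x session: 9 slopes (N1/P2/N1P2 x Fz/FCz/Cz), uV/dB."""

    subject_id: str
    session: int
    slope: dict = field(default_factory=dict)      # (component, channel) -> slope
    r_squared: dict = field(default_factory=dict)  # (component, channel) -> R²
    n_levels: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"subject_id": self.subject_id, "session": self.session,
                 "component": comp, "channel": ch, "slope": s,
                 "r_squared": self.r_squared.get((comp, ch), np.nan),
                 "n_levels": self.n_levels}
                for (comp, ch), s in self.slope.items()]
        return pd.DataFrame(rows)


def subject_ldaep(peak_table: pd.DataFrame, subject_id: str = "",
                  session: int = 1) -> LdaepResult:
    """Compute the 9 LDAEP slopes from a per-channel x intensity peak table."""
    result = LdaepResult(subject_id, session)
    for ch in CHANNELS:
        sub = peak_table[peak_table["channel"] == ch].sort_values(
            "intensity_db")
        if sub.empty:
            raise ValueError(f"peak table missing channel {ch}")
        x = sub["intensity_db"].to_numpy()
        for comp, col in (("N1", "n1_amplitude"), ("P2", "p2_amplitude"),
                          ("N1P2", "n1p2")):
            if sub[col].isna().any():
                raise ValueError(f"missing {comp} amplitude at {ch}")
            slope, r2 = _fit(sub[col].to_numpy(), x)
            result.slope[(comp, ch)] = slope
            result.r_squared[(comp, ch)] = r2
    result.n_levels = len(x)
    return result


def build_cohort_table(results: Sequence[LdaepResult],
                       covariates: pd.DataFrame) -> pd.DataFrame:
    """Join per-subject slopes with covariates into a tidy long table.

    One row per subject x session x channel x component; the covariate table
    must have exactly one row per subject x session present in the results.
    """
    if covariates.duplicated(["subject_id", "session"]).any():
        raise ValueError("duplicate subject/session rows in covariates")
    slopes = pd.concat([r.to_frame() for r in results], ignore_index=True)
    missing = (set(zip(slopes["subject_id"], slopes["session"]))
               - set(zip(covariates["subject_id"], covariates["session"])))
    if missing:
        raise ValueError(f"covariates missing for {sorted(missing)[:5]}")
    table = slopes.merge(covariates, on=["subject_id", "session"],
                         how="left", validate="many_to_one")
    if table.duplicated(["subject_id", "session", "channel",
                         "component"]).any():
        raise ValueError("cohort table rows are not unique")
    return table
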