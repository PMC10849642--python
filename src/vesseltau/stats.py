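"""Association statistics: within-subject ANOVA and immunoassay lane tests.

The headline association — does the fraction of NFT-bearing neurons near
a vessel rise with the vessel's surface-tau decile? — is tested with a
one-way repeated-measures ANOVA across donors (subjects) × deciles
(within-subject conditions). The effect size reported as R² is
SS_effect / (SS_effect + SS_error), i.e. partial eta-squared; note this
is one of several quantities called "R²" in the literature.

Capillary immunoassay (WES) lane intensities are normalized to the mean
of the control lanes per antibody and compared with a one-tailed
two-sample t-test (equal-variance by default, Welch available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RMAnovaResult", "rm_anova", "wes_normalize", "one_tailed_t"]

log = logging.getLogger(__name__)


@dataclass
class RMAnovaResult:
    """One-way within-subject ANOVA result."""

    f_statistic: float
    df_effect: int
    df_error: int
    p_value: float
    r_squared: float  # SS_effect / (SS_effect + SS_error), partial eta²
    n_subjects: int
    n_conditions: int
    ss_subject: float
    ss_effect: float
    ss_error: float
    gg_epsilon: float | None = None  # set when Greenhouse–Geisser applied
    p_value_gg: float | None = None

    def summary(self) -> str:
        lines = [
            "Repeated-measures ANOVA (one-way, within-subject)",
            f"  subjects: {self.n_subjects}   conditions: {self.n_conditions}",
            f"  F({self.df_effect}, {self.df_error}) = {self.f_statistic:.4g}",
            f"  p = {self.p_value:.4g}",
            f"  R^2 (partial eta^2) = {self.r_squared:.4g}",
        ]
        if self.gg_epsilon is not None:
            lines.append(
                f"  Greenhouse-Geisser eps = {self.gg_epsilon:.4g}, "
                f"corrected p = {self.p_value_gg:.4g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "F": self.f_statistic,
            "df_effect": self.df_effect,
            "df_error": self.df_error,
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "n_subjects": self.n_subjects,
            "n_conditions": self.n_conditions,
        }


def rm_anova(
    table: pd.DataFrame | np.ndarray,
    greenhouse_geisser: bool = False,
) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a subjects × conditions table.

    Missing-cell handling is complete-case: subjects (rows) with any
    missing condition are dropped (logged); at least 2 complete subjects
    and 2 conditions are required. The total sum of squares is
    partitioned into subject, condition (effect) and residual (error)
    components; F = MS_effect / MS_error with (k−1) and (n−1)(k−1)
    degrees of freedom. Sphericity is not corrected by default;
    ``greenhouse_geisser=True`` adds an epsilon-corrected p-value.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("need a 2D subjects × conditions table")
    complete = ~np.isnan(arr).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("rm_anova: dropped %d subject(s) with missing conditions", n_dropped)
    arr = arr[complete]
    n, k = arr.shape
    if n < 2:
        raise ValueError(f"need >= 2 complete subjects, have {n}")
    if k < 2:
        raise ValueError(f"need >= 2 conditions, have {k}")

    grand = arr.mean()
    ss_total = float(((arr - grand) ** 2).sum())
    ss_subject = float(k * ((arr.mean(axis=1) - grand) ** 2).sum())
    ss_effect = float(n * ((arr.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_effect
    ss_error = max(ss_error, 0.0)

    df_effect = k - 1
    df_error = (n - 1) * (k - 1)
    ms_effect = ss_effect / df_effect
    ms_error = ss_error / df_error
    if ms_error == 0:
        f = 0.0 if ms_effect == 0 else np.inf
    else:
        f = ms_effect / ms_error
    p = float(sps.f.sf(f, df_effect, df_error)) if np.isfinite(f) else 0.0
    denom = ss_effect + ss_error
    r2 = ss_effect / denom if denom > 0 else 0.0

    result = RMAnovaResult(
        f_statistic=float(f),
        df_effect=df_effect,
        df_error=df_error,
        p_value=p,
        r_squared=float(r2),
        n_subjects=n,
        n_conditions=k,
        ss_subject=ss_subject,
        ss_effect=ss_effect,
        ss_error=ss_error,
    )
    if greenhouse_geisser:
        eps = _gg_epsilon(arr)
        result.gg_epsilon = eps
        result.p_value_gg = float(sps.f.sf(f, eps * df_effect, eps * df_error))
    return result


def _gg_epsilon(arr: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the double-centered covariance."""
    k = arr.shape[1]
    cov = np.cov(arr, rowvar=False, ddof=1)
    cov_c = cov - cov.mean(axis=0) - cov.mean(axis=1)[:, None] + cov.mean()
    num = np.trace(cov_c) ** 2
    den = (k - 1) * (cov_c**2).sum()
    eps = num / den if den > 0 else 1.0
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def wes_normalize(lanes: pd.DataFrame) -> pd.DataFrame:
    """Normalize lane intensities to the control-group mean per antibody.

    Expects columns ``sample``, ``group`` (``AD`` / ``control``),
    ``antibody``, ``lane_intensity``; adds ``normalized``. Control
    normalized values average to 1 within each antibody by construction.
    """
    required = {"sample", "group", "antibody", "lane_intensity"}
    missing = required - set(lanes.columns)
    if missing:
        raise ValueError(f"lane table missing columns: {sorted(missing)}")
    out = lanes.copy()
    out["normalized"] = np.nan
    for ab, grp in out.groupby("antibody"):
        ctrl = grp.loc[grp["group"] == "control", "lane_intensity"]
        if len(ctrl) < 1:
            raise ValueError(f"antibody {ab!r} has no control lanes")
        mean_ctrl = ctrl.mean()
        if mean_ctrl <= 0:
            raise ValueError(f"antibody {ab!r} control mean is not positive")
        out.loc[grp.index, "normalized"] = grp["lane_intensity"] / mean_ctrl
    return out


def one_tailed_t(
    ad, control, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t-test of the one-sided hypothesis AD > control.

    Returns (t, upper-tail p). Equal-variance (pooled) by default;
    ``equal_var=False`` switches to Welch.
    """
    ad = np.asarray(ad, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(ad) < 2 or len(control) < 2:
        raise ValueError("need >= 2 observations per group")
    res = sps.ttest_ind(ad, control, equal_var=equal_var, alternative="greater")
    return float(res.statistic), float(res.pvalue)
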