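"""Moderation analysis: myelin as a moderator of hemodynamics-fALFF coupling.

Fits the canonical interaction model

    fALFF = β0 + β1·X + β2·M + β3·X·M + e

where X is a hemodynamic predictor (e.g. relative CBV), M the moderator
(myelin water fraction), and all variables are z-scored before fitting.
The interaction regressor is the *product of the z-scored main effects*
and is not itself re-standardized, which keeps the moderation threshold
−β1/β3 interpretable on the moderator's z-scale; the raw-scale threshold
is recovered via the moderator's sample moments.  The conditional
("simple") slope of the response on the predictor at moderator level m is
β1 + β3·m_z, and it crosses zero exactly at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModerationFit",
    "fit_moderation",
    "threshold",
    "threshold_from_coefficients",
    "pooled_moments",
    "simple_slopes",
]

#: |β3| below this is treated as "no interaction": threshold undefined
BETA3_TOL = 1e-10


@dataclass
class ModerationFit:
    """Coefficients and thresholds of a fitted moderation model."""

    beta: np.ndarray  # (β0, β1, β2, β3)
    p_values: np.ndarray
    threshold_z: float | None
    threshold_raw: float | None
    moderator_mean: float
    moderator_sd: float
    r_squared: float
    n: int
    beta3_significant: bool = True
    threshold_reason: str | None = None

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def beta1(self) -> float:
        return float(self.beta[1])

    @property
    def beta2(self) -> float:
        return float(self.beta[2])

    @property
    def beta3(self) -> float:
        return float(self.beta[3])

    def to_dict(self) -> dict:
        return {
            "beta": [float(b) for b in self.beta],
            "p_values": [float(p) for p in self.p_values],
            "threshold_z": self.threshold_z,
            "threshold_raw": self.threshold_raw,
            "moderator_mean": self.moderator_mean,
            "moderator_sd": self.moderator_sd,
            "r_squared": self.r_squared,
            "n": self.n,
            "beta3_significant": self.beta3_significant,
            "threshold_reason": self.threshold_reason,
        }


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant column")
    return (x - x.mean()) / sd


def fit_moderation(
    table: pd.DataFrame,
    response: str = "falff",
    predictor: str = "predictor",
    moderator: str = "mwf",
    z_score: bool = True,
    alpha: float = 0.05,
    beta3_tol: float = BETA3_TOL,
) -> ModerationFit:
    """Fit the interaction model by OLS with an intercept.

    With ``z_score=True`` (the default, for raw-scale tables) the
    response, predictor and moderator are standardized first; the raw
    moderator moments are retained so the threshold can be reported on
    the original scale.  With ``z_score=False`` the columns are used
    as-is — appropriate when the table was generated directly on the
    z-scale, as the synthetic moderation generator does.
    """
    import statsmodels.api as sm

    for col in (response, predictor, moderator):
        if col not in table.columns:
            raise KeyError(f"column '{col}' not in table")
    y = table[response].to_numpy(dtype=float)
    x = table[predictor].to_numpy(dtype=float)
    m = table[moderator].to_numpy(dtype=float)
    n = y.size
    if n < 5:
        raise ValueError(f"need at least 5 rows, got {n}")
    if not np.all(np.isfinite(np.c_[y, x, m])):
        raise ValueError("non-finite values in the moderation table")
    for name, col in ((response, y), (predictor, x), (moderator, m)):
        if np.ptp(col) == 0:
            raise ValueError(f"column '{name}' is constant")
    mod_mean, mod_sd = float(m.mean()), float(m.std(ddof=1))
    if z_score:
        y, x, m = _zscore(y), _zscore(x), _zscore(m)
    design = sm.add_constant(np.column_stack([x, m, x * m]))
    res = sm.OLS(y, design).fit()
    beta = np.asarray(res.params)
    pvals = np.asarray(res.pvalues)
    fit = ModerationFit(
        beta=beta,
        p_values=pvals,
        threshold_z=None,
        threshold_raw=None,
        moderator_mean=mod_mean,
        moderator_sd=mod_sd,
        r_squared=float(res.rsquared),
        n=int(n),
        beta3_significant=bool(pvals[3] < alpha),
    )
    tz, traw = threshold(fit, beta3_tol=beta3_tol)
    fit.threshold_z, fit.threshold_raw = tz, traw
    return fit


def threshold(
    fit: ModerationFit, beta3_tol: float = BETA3_TOL
) -> tuple[float | None, float | None]:
    """Moderation threshold −β1/β3 on the z and raw moderator scales.

    The raw-scale value is ``moderator_mean + threshold_z * moderator_sd``
    using the moderator's sample moments.  When |β3| is numerically zero
    the predictor's slope never crosses zero and the threshold is
    undefined (returned as None, with the reason recorded on the fit).
    """
    if abs(fit.beta3) <= beta3_tol:
        fit.threshold_reason = "interaction coefficient is numerically zero"
        return None, None
    tz = -fit.beta1 / fit.beta3
    traw = fit.moderator_mean + tz * fit.moderator_sd
    return float(tz), float(traw)


def threshold_from_coefficients(
    beta1: float,
    beta3: float,
    moderator_mean: float = 0.0,
    moderator_sd: float = 1.0,
    beta3_tol: float = BETA3_TOL,
) -> tuple[float | None, float | None]:
    """Threshold −β1/β3 from given z-scale coefficients, optionally
    converted to the moderator's raw scale."""
    if abs(beta3) <= beta3_tol:
        return None, None
    tz = -beta1 / beta3
    return float(tz), float(moderator_mean + tz * moderator_sd)


def pooled_moments(
    sizes: np.ndarray, means: np.ndarray, sds: np.ndarray
) -> tuple[float, float]:
    """Mean and SD of a mixture described by per-group size, mean and SD.

    The pooled variance is the within-group part plus the between-group
    part (sample convention, n−1 denominator).  Used to back-convert a
    z-scale moderation threshold to raw moderator units from printed
    group statistics, e.g. 120 association bundles at MWF 0.09±0.01 and
    40 projection bundles at 0.12±0.02.
    """
    sizes = np.asarray(sizes, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if np.any(sizes <= 0) or np.any(sds < 0):
        raise ValueError("sizes must be positive and SDs non-negative")
    n = sizes.sum()
    grand = float((sizes * means).sum() / n)
    within = ((sizes - 1) * sds**2).sum()
    between = (sizes * (means - grand) ** 2).sum()
    var = (within + between) / (n - 1)
    return grand, float(np.sqrt(var))


def simple_slopes(
    fit: ModerationFit, moderator_levels: np.ndarray
) -> np.ndarray:
    """Conditional slope β1 + β3·m_z at raw-scale moderator levels.

    At the raw-scale threshold the slope is exactly zero.
    """
    levels = np.asarray(moderator_levels, dtype=float)
    m_z = (levels - fit.moderator_mean) / fit.moderator_sd
    return fit.beta1 + fit.beta3 * m_z
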