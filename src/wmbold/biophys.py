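"""Biophysical model linking BOLD fluctuations to hemodynamics.

The BOLD signal decays with the deoxyhemoglobin-induced increment δR2* to
the transverse relaxation rate: for δR2*·TE ≪ 1,

    S(t) ≈ S̄ · (1 − TE · δR2*(t)),

so δR2* can be read off the fractional signal deviation from baseline.
To first order δR2* tracks the deoxygenated blood content,

    δR2*(t) = β · OEF(t) · CBV(t),

with β a constant susceptibility coefficient, which under independent
fluctuations gives the supply-side variance

    σ²_δR2* = β² (CBV² σ²_OEF + OEF² σ²_CBV).

Substituting the identities CMRO2 = α·OEF·CBF and CBF = CBV/MTT gives the
demand-side form δR2* = (β/α)·CMRO2·MTT and

    σ²_δR2* = (β²/α²) (MTT² σ²_CMRO2 + CMRO2² σ²_MTT),

which reduces to (β²/α²)·MTT²·σ²_CMRO2 when transit-time fluctuations are
negligible.  The two regression models fitted here decompose bundle-wise
fALFF into these squared hemodynamic terms:

    Model 1:  fALFF = γ1·CBV² + γ2·OEF²  + e1
    Model 2:  fALFF = γ3·MTT² + γ4·CMRO2² + e2

with all variables z-scored before fitting, so the magnitudes of the γ
coefficients are comparable and each regressor's percent contribution is
|γi| / Σ|γj| · 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import BoldSeries

__all__ = [
    "HemoFeatures",
    "VarianceComponents",
    "ModelFit",
    "delta_r2star_from_signal",
    "predict_var_supply",
    "predict_var_demand",
    "fit_supply_model",
    "fit_demand_model",
    "hemo_consistency",
    "zscore",
]


@dataclass
class HemoFeatures:
    """Per-bundle hemodynamic/metabolic state obeying the coupling identities.

    ``cbf = cbv / mtt`` and ``cmro2 = alpha * oef * cbf`` hold to float
    precision whenever the object is built by :meth:`from_components`.
    """

    cbv: float
    cbf: float
    oef: float
    cmro2: float
    mtt: float
    alpha: float = 1.0

    @classmethod
    def from_components(
        cls, cbv: float, mtt: float, oef: float, alpha: float = 1.0
    ) -> "HemoFeatures":
        if cbv <= 0 or mtt <= 0 or alpha <= 0:
            raise ValueError("cbv, mtt and alpha must be positive")
        if not (0 < oef < 1):
            raise ValueError("oef must lie in (0, 1)")
        cbf = cbv / mtt
        return cls(cbv=cbv, cbf=cbf, oef=oef, cmro2=alpha * oef * cbf,
                   mtt=mtt, alpha=alpha)


@dataclass
class VarianceComponents:
    """Fluctuation variances entering the δR2* variance predictions."""

    var_oef: float = 0.0
    var_cbv: float = 0.0
    var_cmro2: float = 0.0
    var_mtt: float = 0.0
    var_dr2: float = 0.0
    beta_suscept: float = 1.0

    def __post_init__(self) -> None:
        for name in ("var_oef", "var_cbv", "var_cmro2", "var_mtt", "var_dr2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ModelFit:
    """OLS fit of fALFF on two squared, z-scored hemodynamic regressors."""

    gammas: np.ndarray
    p_values: np.ndarray
    contributions_pct: np.ndarray
    r_squared: float
    residual_label: str
    regressor_names: tuple[str, str]
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "gammas": [float(g) for g in self.gammas],
            "p_values": [float(p) for p in self.p_values],
            "contributions_pct": [float(c) for c in self.contributions_pct],
            "r_squared": float(self.r_squared),
            "residual": self.residual_label,
            "regressors": list(self.regressor_names),
            "n": self.n,
        }


def zscore(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize to zero mean, unit (sample) standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot z-score a constant column")
    return (x - x.mean()) / sd


def delta_r2star_from_signal(
    series: BoldSeries,
    baseline: float | None = None,
    sign: str = "dip_positive",
) -> np.ndarray:
    """δR2* time course (1/s) from a BOLD series.

    Under the small-perturbation linearization the fractional signal
    deviation from baseline is −TE·δR2*, so

        δR2*(t) = (S̄ − S(t)) / (TE · S̄)

    with the documented convention that δR2* is *positive when the signal
    drops below baseline* (more deoxyhemoglobin).  Pass
    ``sign="signal_positive"`` for the opposite convention.  The baseline
    defaults to the stored S̄ of the series, falling back to the series
    mean (in which case the output is mean-zero).
    """
    s_bar = series.baseline_value() if baseline is None else float(baseline)
    if s_bar <= 0:
        raise ValueError("baseline S̄ must be positive")
    frac = (series.values - s_bar) / s_bar
    dr2 = -frac / series.te_s
    if sign == "signal_positive":
        dr2 = -dr2
    elif sign != "dip_positive":
        raise ValueError("sign must be 'dip_positive' or 'signal_positive'")
    return dr2


def predict_var_supply(
    mean_oef: float,
    mean_cbv: float,
    var_oef: float,
    var_cbv: float,
    beta_suscept: float,
) -> float:
    """Supply-side δR2* variance: β² (CBV² σ²_OEF + OEF² σ²_CBV).

    First-order propagation through δR2* = β·OEF·CBV for independent
    fluctuations; accurate for small coefficients of variation.
    """
    if var_oef < 0 or var_cbv < 0:
        raise ValueError("variances must be non-negative")
    return beta_suscept**2 * (mean_cbv**2 * var_oef + mean_oef**2 * var_cbv)


def predict_var_demand(
    mean_cmro2: float,
    mean_mtt: float,
    var_cmro2: float,
    var_mtt: float,
    beta_suscept: float,
    alpha: float,
) -> float:
    """Demand-side δR2* variance: (β²/α²)(MTT² σ²_CMRO2 + CMRO2² σ²_MTT).

    With ``var_mtt=0`` this reduces to the constant-transit-time limit
    (β²/α²)·MTT²·σ²_CMRO2.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if var_cmro2 < 0 or var_mtt < 0:
        raise ValueError("variances must be non-negative")
    return (beta_suscept / alpha) ** 2 * (
        mean_mtt**2 * var_cmro2 + mean_cmro2**2 * var_mtt
    )


def _fit_two_term(
    y: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    names: tuple[str, str],
    residual_label: str,
    intercept: bool,
) -> ModelFit:
    import statsmodels.api as sm

    if y.size < 3:
        raise ValueError("need at least 3 rows to fit")
    if not np.all(np.isfinite(np.c_[y, x1, x2])):
        raise ValueError("non-finite values in the model table")
    yz = zscore(y)
    x1z, x2z = zscore(x1), zscore(x2)
    X = np.column_stack([x1z, x2z])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError(
            f"rank-deficient design: columns {names[0]} and {names[1]} are collinear"
        )
    design = sm.add_constant(X) if intercept else X
    res = sm.OLS(yz, design).fit()
    off = 1 if intercept else 0
    gammas = np.asarray(res.params[off : off + 2])
    pvals = np.asarray(res.pvalues[off : off + 2])
    total = np.abs(gammas).sum()
    contrib = (
        100.0 * np.abs(gammas) / total if total > 0 else np.full(2, 50.0)
    )
    return ModelFit(
        gammas=gammas,
        p_values=pvals,
        contributions_pct=contrib,
        r_squared=float(res.rsquared),
        residual_label=residual_label,
        regressor_names=names,
        n=int(y.size),
    )


def fit_supply_model(
    table: pd.DataFrame,
    falff_col: str = "falff",
    cbv_col: str = "cbv",
    oef_col: str = "oef",
    intercept: bool = False,
) -> ModelFit:
    """Model 1: z(fALFF) = γ1·z(CBV²) + γ2·z(OEF²) + e1.

    Raw predictors are squared first and the squared quantities are
    z-scored, making γ1 and γ2 directly comparable; the percent
    contribution of each term is |γi|/Σ|γj|·100.
    """
    return _fit_two_term(
        table[falff_col].to_numpy(dtype=float),
        table[cbv_col].to_numpy(dtype=float) ** 2,
        table[oef_col].to_numpy(dtype=float) ** 2,
        names=("cbv_sq", "oef_sq"),
        residual_label="e1",
        intercept=intercept,
    )


def fit_demand_model(
    table: pd.DataFrame,
    falff_col: str = "falff",
    mtt_col: str = "mtt",
    cmro2_col: str = "cmro2",
    intercept: bool = False,
) -> ModelFit:
    """Model 2: z(fALFF) = γ3·z(MTT²) + γ4·z(CMRO2²) + e2."""
    return _fit_two_term(
        table[falff_col].to_numpy(dtype=float),
        table[mtt_col].to_numpy(dtype=float) ** 2,
        table[cmro2_col].to_numpy(dtype=float) ** 2,
        names=("mtt_sq", "cmro2_sq"),
        residual_label="e2",
        intercept=intercept,
    )


def hemo_consistency(features: HemoFeatures) -> dict[str, float]:
    """Residuals of the coupling identities CBF = CBV/MTT and
    CMRO2 = α·OEF·CBF, absolute and relative.

    Large residuals flag externally supplied tables with inconsistent
    units; no exception is raised.
    """
    flow = features.cbv / features.mtt
    metab = features.alpha * features.oef * features.cbf
    abs_flow = abs(features.cbf - flow)
    abs_metab = abs(features.cmro2 - metab)
    return {
        "abs_cbf_residual": abs_flow,
        "rel_cbf_residual": abs_flow / abs(flow) if flow else np.inf,
        "abs_cmro2_residual": abs_metab,
        "rel_cmro2_residual": abs_metab / abs(metab) if metab else np.inf,
    }
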