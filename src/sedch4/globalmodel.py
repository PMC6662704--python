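"""Global prediction model of sediment CH4 formation from age and TN.

Pooling all slice-occasion CH4 formation rates (dry-weight basis) across
reservoirs, the ln rate is modelled by ordinary least squares as

    ln(rate) = b1 * ln(age) + b2 * TN + b3 * ln(age) * TN + b0

with age in years and TN in mass %.  Back-transforming ln-scale predictions
underestimates the mean of the lognormal response, so point predictions are
bias-corrected with the residual variance s²:

    rate_corr = exp(ln_mean + s²/2),
    var_corr  = rate_corr² * (exp(s²) - 1).

The coefficient set published for three tropical reservoirs
(b1=-0.59, b2=6.46, b3=-0.99, b0=-3.12, s²=0.28, R²=0.81, n=764) is available
as :data:`PUBLISHED_MODEL` for prediction without refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GlobalModel:
    beta_lnage: float        # per ln-year
    beta_tn: float           # per mass % TN
    beta_interaction: float  # per (ln-year · mass %)
    intercept: float         # ln(µmol g(dw)^-1 d^-1)
    s2: float                # ln-scale residual variance
    r2: float
    n: int

    def __post_init__(self):
        if self.s2 < 0:
            raise ValueError("residual variance must be >= 0")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("R^2 must be in [0, 1]")

    def ln_mean(self, age_years, tn_pct):
        ln_age = np.log(np.asarray(age_years, dtype=float))
        tn = np.asarray(tn_pct, dtype=float)
        return (self.beta_lnage * ln_age + self.beta_tn * tn
                + self.beta_interaction * ln_age * tn + self.intercept)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GlobalModel":
        return cls(**{k: d[k] for k in
                      ("beta_lnage", "beta_tn", "beta_interaction",
                       "intercept", "s2", "r2", "n")})


#: Published coefficient set for the three-reservoir dataset.
PUBLISHED_MODEL = GlobalModel(beta_lnage=-0.59, beta_tn=6.46, beta_interaction=-0.99,
                          intercept=-3.12, s2=0.28, r2=0.81, n=764)


@dataclass
class Prediction:
    ln_mean: float
    rate_naive: float   # exp(ln_mean), biased low as a mean predictor
    rate_corr: float    # lognormal-mean corrected
    var_corr: float


def fit_global(df: pd.DataFrame, rate_col: str = "rate_dw",
               age_col: str = "age_years", tn_col: str = "tn_interp") -> GlobalModel:
    """OLS fit of ln(rate) ~ ln(age) + TN + ln(age):TN.

    Non-positive net rates cannot be ln-transformed; they are dropped with a
    logged count.  Refuses n < 10 and degenerate (collinear) designs.
    """
    sub = df[[rate_col, age_col, tn_col]].dropna()
    n_nonpos = int((sub[rate_col] <= 0).sum())
    if n_nonpos:
        logger.info("fit_global: dropping %d non-positive net rates", n_nonpos)
        sub = sub[sub[rate_col] > 0]
    if (sub[age_col] <= 0).any():
        raise ValueError("ages must be > 0 for ln transform")
    n = len(sub)
    if n < 10:
        raise ValueError(f"refusing to fit with n={n} < 10")
    ln_age = np.log(sub[age_col].to_numpy())
    tn = sub[tn_col].to_numpy()
    X = sm.add_constant(np.column_stack([ln_age, tn, ln_age * tn]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design (constant ln(age) or TN?)")
    y = np.log(sub[rate_col].to_numpy())
    res = sm.OLS(y, X).fit()
    b0, b1, b2, b3 = res.params
    return GlobalModel(beta_lnage=float(b1), beta_tn=float(b2),
                       beta_interaction=float(b3), intercept=float(b0),
                       s2=float(res.mse_resid), r2=float(res.rsquared), n=n)


def predict(model: GlobalModel, age_years: float, tn_pct: float) -> Prediction:
    """Predicted CH4 formation rate (µmol g(dw)^-1 d^-1) with bias correction."""
    if np.any(np.asarray(age_years, dtype=float) <= 0):
        raise ValueError("age must be > 0")
    ln_mean = model.ln_mean(age_years, tn_pct)
    rate_naive = np.exp(ln_mean)
    rate_corr = np.exp(ln_mean + 0.5 * model.s2)
    var_corr = rate_corr ** 2 * (np.exp(model.s2) - 1.0)
    if np.ndim(ln_mean) == 0:
        return Prediction(float(ln_mean), float(rate_naive), float(rate_corr),
                          float(var_corr))
    return Prediction(ln_mean, rate_naive, rate_corr, var_corr)


def tn_from_tc(tc_pct, tn_pct):
    """Ancillary least-squares line of TN on TC -> (slope, intercept, r2).

    TN tracks TC closely across reservoir sediments because both reflect the
    bulk organic-matter content.
    """
    tc = np.asarray(tc_pct, dtype=float)
    tn = np.asarray(tn_pct, dtype=float)
    if len(tc) != len(tn):
        raise ValueError("inputs must have equal length")
    if len(tc) < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(tc) == 0:
        raise ValueError("zero variance in TC")
    res = stats.linregress(tc, tn)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
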