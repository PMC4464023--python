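"""Multiple linear regression of equilibrium SSI on network topology.

The model is

    SSI_i = b0 + b1*SFFI_i + b2*APL_i + b3*DIAMETER_i + b4*ACC_i
            + b5*TRANSITIVITY_i + b6*MODULARITY_i + e_i

fitted by ordinary least squares over one observation per simulated network
(realized metrics, not generator targets).  Redundant predictors are removed
by backward elimination: each pass drops the single least significant term
whose partial F-test p-value exceeds ``alpha`` and refits, until every
retained term is significant.  For a single coefficient the partial F equals
the squared t statistic of that coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["PREDICTORS", "RegressionResult", "correlation_matrix",
           "fit_ssi_model"]

PREDICTORS = ["sffi", "apl", "diameter", "acc", "transitivity", "modularity"]
RESPONSE = "ssi"


def correlation_matrix(observations: pd.DataFrame,
                       columns: list[str] | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between all metric/response pairs.

    Returns the square correlation matrix and a long-format table
    (``var_a``, ``var_b``, ``r``) convenient for scatter-matrix plotting.
    Constant columns yield NaN correlations and are flagged with a warning.
    """
    if columns is None:
        columns = [c for c in PREDICTORS + [RESPONSE]
                   if c in observations.columns]
    if len(observations) < 3:
        raise ValueError("need at least 3 observations")
    sub = observations[columns].astype(float)
    constant = [c for c in columns if sub[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant columns, correlation undefined: {constant}")
    corr = sub.corr()
    long = (corr.stack().rename_axis(["var_a", "var_b"])
            .reset_index(name="r"))
    return corr, long


@dataclass
class RegressionResult:
    """Final backward-eliminated OLS fit plus the elimination trail."""

    params: pd.Series                 # coefficients incl. intercept
    bse: pd.Series                    # standard errors
    fvalues: pd.Series                # per-term partial F (= t^2)
    pvalues: pd.Series                # per-term partial-F p-values
    adj_r2: float
    r2: float
    retained: list[str]
    eliminated: list[str] = field(default_factory=list)
    correlations: pd.DataFrame | None = None
    nobs: int = 0

    def summary(self) -> str:
        lines = [f"OLS of {RESPONSE} on {', '.join(self.retained) or '(intercept)'}",
                 f"n = {self.nobs}, R^2 = {self.r2:.4f}, "
                 f"adjusted R^2 = {self.adj_r2:.4f}"]
        for name in self.params.index:
            p = self.pvalues.get(name, float("nan"))
            lines.append(f"  {name:>14s}  beta = {self.params[name]: .4g}  "
                         f"(se {self.bse[name]:.3g}, p = {p:.3g})")
        if self.eliminated:
            lines.append("eliminated (in order): " + ", ".join(self.eliminated))
        return "\n".join(lines)


def _fit(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def fit_ssi_model(observations: pd.DataFrame, alpha: float = 0.05,
                  predictors: list[str] | None = None) -> RegressionResult:
    """OLS on all predictors, then backward elimination at level ``alpha``.

    ``observations`` needs one row per network with the predictor columns
    and an ``ssi`` response column.  Aliased (perfectly collinear or
    constant) columns are dropped with a warning before fitting.  A term is
    never removed while its partial-F p-value is below ``alpha``; removal
    order is largest p-value first, one term per pass, refitting each pass.
    """
    cols = [c for c in (predictors or PREDICTORS) if c in observations.columns]
    if RESPONSE not in observations.columns:
        raise ValueError(f"observations must contain a {RESPONSE!r} column")
    n = len(observations)
    if n <= len(cols) + 1:
        raise ValueError(f"{n} observations cannot support {len(cols)} "
                         "predictors plus an intercept")
    y = observations[RESPONSE].to_numpy(dtype=float)
    X = observations[cols].astype(float)

    # drop constant or aliased columns until the design has full rank
    dropped_aliased: list[str] = []
    for c in list(X.columns):
        if X[c].nunique() <= 1:
            X = X.drop(columns=c)
            dropped_aliased.append(c)
    while X.shape[1] > 0:
        design = np.column_stack([np.ones(n), X.to_numpy()])
        if np.linalg.matrix_rank(design) == design.shape[1]:
            break
        c = X.columns[-1]
        X = X.drop(columns=c)
        dropped_aliased.append(c)
    if dropped_aliased:
        warnings.warn(f"dropped aliased/constant predictors: {dropped_aliased}")

    eliminated: list[str] = []
    fit = _fit(y, X)
    while X.shape[1] > 0:
        pvals = fit.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] <= alpha:
            break
        X = X.drop(columns=worst)
        eliminated.append(worst)
        fit = _fit(y, X)

    retained = list(X.columns)
    tvals = fit.tvalues
    pv = fit.pvalues
    corr = observations[cols + [RESPONSE]].astype(float).corr() \
        if len(cols) > 0 else None
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        fvalues=(tvals.drop("const") ** 2) if retained else pd.Series(dtype=float),
        pvalues=pv,
        adj_r2=float(fit.rsquared_adj),
        r2=float(fit.rsquared),
        retained=retained,
        eliminated=dropped_aliased + eliminated,
        correlations=corr,
        nobs=n,
    )
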