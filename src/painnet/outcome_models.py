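"""Stepwise multifactorial regression of pain outcomes.

Pain and residual pain are modelled from the five component scores plus
demographic/clinical covariates (age, gender, education, BMI, pain duration,
radiographic grade).  Predictors enter by forward selection at p < 0.05 and
leave by backward elimination at p > 0.10, alternating until stable; cases
with a studentized deleted residual beyond +-3 SD are pruned (at most three,
largest first) and the model refit.  Predictor sets selected on the knee arm
can be re-tested on the hip arm with a plain multiple regression (no
selection), reporting the same table columns (b, SE, beta, t, p, adjusted
R^2, F).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .cohort_model import AnalysisConfig

logger = logging.getLogger("painnet")


@dataclass
class RegressionFit:
    outcome: str
    predictors: list[str]
    b: dict                      # unstandardized coefficients
    se: dict
    beta: dict                   # standardized coefficients b * sd(x)/sd(y)
    t: dict
    p: dict
    intercept: float
    r2: float
    adj_r2: float
    fvalue: float
    f_pvalue: float
    df_model: float
    df_resid: float
    n: int
    removed_outliers: list = field(default_factory=list)

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)

    def table(self) -> pd.DataFrame:
        """Per-predictor table mirroring the published model layout."""
        return pd.DataFrame({
            "b": self.b, "SE": self.se, "beta": self.beta,
            "t": self.t, "p": self.p,
        }).loc[self.predictors]


def _ols(X: pd.DataFrame, y: pd.Series, predictors: list[str]):
    exog = sm.add_constant(X[predictors], has_constant="add") if predictors \
        else pd.DataFrame({"const": np.ones(len(y))}, index=y.index)
    return sm.OLS(np.asarray(y, float), np.asarray(exog, float)).fit(), exog


def _fit_result(outcome: str, X: pd.DataFrame, y: pd.Series,
                predictors: list[str], removed: list) -> RegressionFit:
    res, exog = _ols(X, y, predictors)
    sy = float(np.std(y, ddof=1))
    b, se, beta, t, p = {}, {}, {}, {}, {}
    for j, name in enumerate(predictors, start=1):
        b[name] = float(res.params[j])
        se[name] = float(res.bse[j])
        t[name] = float(res.tvalues[j])
        p[name] = float(res.pvalues[j])
        beta[name] = float(res.params[j] * np.std(X[name], ddof=1) / sy) if sy > 0 else np.nan
    return RegressionFit(
        outcome=outcome, predictors=list(predictors),
        b=b, se=se, beta=beta, t=t, p=p,
        intercept=float(res.params[0]),
        r2=float(res.rsquared) if predictors else 0.0,
        adj_r2=float(res.rsquared_adj) if predictors else 0.0,
        fvalue=float(res.fvalue) if predictors else float("nan"),
        f_pvalue=float(res.f_pvalue) if predictors else float("nan"),
        df_model=float(res.df_model), df_resid=float(res.df_resid),
        n=int(res.nobs), removed_outliers=list(removed),
    )


def stepwise_fit(X: pd.DataFrame, y: pd.Series,
                 config: AnalysisConfig | None = None,
                 outcome: str = "outcome") -> RegressionFit:
    """Alternating forward entry / backward removal until stable.

    Entry and removal are judged by the predictor's partial t-test p-value
    (equivalent to the partial F for a single variable).  Ties in p-values
    are broken by candidate column order, making the procedure deterministic.
    """
    config = config or AnalysisConfig()
    X = X.copy()
    keep = []
    for c in X.columns:
        if np.std(X[c], ddof=1) == 0:
            warnings.warn(f"dropping zero-variance candidate {c!r}")
        else:
            keep.append(c)
    X = X[keep]
    candidates = list(X.columns)
    if len(y) <= len(candidates) + 2:
        warnings.warn("n is small relative to the candidate count")

    selected: list[str] = []
    max_steps = 2 * max(len(candidates), 1)
    for _ in range(max_steps):
        changed = False
        # forward: best (smallest-p) candidate below alpha_enter
        best_name, best_p = None, None
        for name in candidates:
            if name in selected:
                continue
            res, _ = _ols(X, y, selected + [name])
            p_new = float(res.pvalues[len(selected) + 1])
            if p_new < config.alpha_enter and (best_p is None or p_new < best_p):
                best_name, best_p = name, p_new
        if best_name is not None:
            selected.append(best_name)
            changed = True
        # backward: worst (largest-p) selected predictor above alpha_remove
        if selected:
            res, _ = _ols(X, y, selected)
            pvals = {name: float(res.pvalues[j]) for j, name in enumerate(selected, 1)}
            worst = max(selected, key=lambda nm: pvals[nm])
            if pvals[worst] > config.alpha_remove:
                selected.remove(worst)
                changed = True
        if not changed:
            break
    else:
        raise RuntimeError("stepwise selection cycled without converging")
    return _fit_result(outcome, X, y, selected, removed=[])


def remove_outliers(X: pd.DataFrame, y: pd.Series, predictors: list[str],
                    config: AnalysisConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.Series, list]:
    """Prune cases with |studentized deleted residual| > the +-3 SD cut.

    At most ``outlier_cap`` cases are removed (the study removed no more than
    three), the most extreme first, refitting after each removal.
    """
    config = config or AnalysisConfig()
    Xw, yw = X.copy(), y.copy()
    removed: list = []
    if not predictors:
        return Xw, yw, removed
    while len(removed) < config.outlier_cap:
        if len(yw) <= len(predictors) + 2:
            raise ValueError("outlier removal would leave too few cases to fit")
        res, _ = _ols(Xw, yw, predictors)
        stud = OLSInfluence(res).resid_studentized_external
        worst = int(np.argmax(np.abs(stud)))
        if abs(stud[worst]) <= config.outlier_sd:
            break
        sid = yw.index[worst]
        removed.append(sid)
        Xw = Xw.drop(index=sid)
        yw = yw.drop(index=sid)
    if removed:
        logger.info("removed %d outlier case(s): %s", len(removed), removed)
    return Xw, yw, removed


def stepwise_with_outliers(X: pd.DataFrame, y: pd.Series,
                           config: AnalysisConfig | None = None,
                           outcome: str = "outcome",
                           outliers_first: bool = False) -> RegressionFit:
    """Stepwise selection with one studentized-residual pruning pass.

    Default order: select, prune on the selected model, re-select once on the
    pruned data.  ``outliers_first=True`` instead prunes on the full candidate
    model before any selection.
    """
    config = config or AnalysisConfig()
    if outliers_first:
        Xp, yp, removed = remove_outliers(X, y, list(X.columns), config)
        fit = stepwise_fit(Xp, yp, config, outcome)
        fit.removed_outliers = removed
        return fit
    first = stepwise_fit(X, y, config, outcome)
    if not first.predictors:
        return first
    Xp, yp, removed = remove_outliers(X, y, first.predictors, config)
    if not removed:
        return first
    fit = stepwise_fit(Xp, yp, config, outcome)
    fit.removed_outliers = removed
    return fit


def apply_model(predictors: list[str], X: pd.DataFrame, y: pd.Series,
                outcome: str = "outcome") -> RegressionFit:
    """Plain multiple regression of a fixed predictor set (no selection).

    Used to re-test the knee-arm predictor sets on the hip arm.
    """
    missing = [p for p in predictors if p not in X.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    if len(y) <= len(predictors) + 2:
        raise ValueError("too few cases for this predictor set")
    return _fit_result(outcome, X, y, list(predictors), removed=[])
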