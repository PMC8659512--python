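"""The CDH and CDH+ABI breathiness indices and the regression machinery
to re-derive such indices from a feature table.

CDH is a linear combination of CPPS, the DECOM open quotient (DOQ) and
the Howard open quotient (HOQ) fitted against perceptual breathiness
ratings; CDH+ABI adds the Acoustic Breathiness Index as a fourth
regressor.  Both printed models have no intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import SignalError

CDH_COEFFS = {"cpps": -0.20688984, "doq": -3.21878076, "hoq": 9.56627174}
CDH_ABI_COEFFS = {"cpps": -0.06959419, "doq": -3.26429585,
                  "hoq": 8.27435347, "abi": 0.2633933}


def cdh(cpps: float, doq: float, hoq: float) -> float:
    """CDH index: exact evaluation of the published coefficients, no
    intercept."""
    c = CDH_COEFFS
    return c["cpps"] * cpps + c["doq"] * doq + c["hoq"] * hoq


def cdh_abi(cpps: float, doq: float, hoq: float, abi: float) -> float:
    """CDH+ABI index: the four-regressor published model, no intercept."""
    c = CDH_ABI_COEFFS
    return c["cpps"] * cpps + c["doq"] * doq + c["hoq"] * hoq + c["abi"] * abi


@dataclass
class IndexModel:
    """A fitted linear breathiness index."""

    coefficients: dict[str, float]
    intercept: float = 0.0
    std_errors: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    fitted_on: str = ""

    def predict(self, rows) -> np.ndarray:
        """Sum of coefficient * feature (+ intercept), exactly."""
        n = len(next(iter(rows.values()))) if isinstance(rows, dict) else len(rows)
        out = np.full(n, self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            out += coef * np.asarray(rows[name], dtype=float)
        return out


def fit_index(rows, features: list[str], target, intercept: bool = False,
              fitted_on: str = "") -> IndexModel:
    """Ordinary-least-squares index fit.

    `rows` is any mapping from feature name to a numeric column (a pandas
    DataFrame works).  The intercept is suppressed by default to mirror the
    published no-constant index form.  Classical OLS standard errors and
    t-test p-values are reported per coefficient.
    """
    y = np.asarray(target, dtype=float)
    cols = [np.asarray(rows[f], dtype=float) for f in features]
    X = np.column_stack(cols)
    names = list(features)
    if intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names
    n, k = X.shape
    if n < k:
        raise SignalError(f"need at least {k} rows to fit {k} coefficients")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise SignalError("fit_index requires finite feature and target values")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the collinear columns by testing each one's marginal rank
        collinear = [
            names[j] for j in range(k)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise SignalError(f"rank-deficient design; collinear features: {collinear}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof if dof > 0 else float("nan")
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof) if dof > 0 else np.full(k, np.nan)

    coef = dict(zip(names, beta))
    inter = coef.pop("intercept", 0.0)
    return IndexModel(
        coefficients=coef,
        intercept=float(inter),
        std_errors=dict(zip(names, se)),
        p_values=dict(zip(names, pvals)),
        fitted_on=fitted_on,
    )
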