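"""Likelihood-ratio test of the incompatibility effect (Step 2).

The disease outcome is modelled by logistic regression

    logit P(Y = 1 | Gm, Go) = b0 + bm*Gm + bo*Go + bic*Gic (+ covariates)

with Gm/Go the maternal/offspring additive minor-allele counts and Gic the
binary incompatibility indicator coded under the analysis model from Step 1.
The incompatibility effect is tested by a likelihood-ratio test of
H0: bic = 0 against the reduced model dropping only Gic, with the statistic
referred to a chi-square distribution on 1 degree of freedom.  Covariates
enter both the full and the reduced fits so the test isolates bic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .entropy_selection import SelectionConfig, SelectionResult, permutation_select
from .genotype_models import MFGIModel, code_incompatibility, get_model

__all__ = [
    "LogisticSpec",
    "LogisticFit",
    "MFGITestResult",
    "fit_logistic",
    "lrt_incompatibility",
    "two_step_test",
]

_Z975 = 1.959963984540054  # standard-normal 97.5% quantile for the Wald CI


@dataclass(frozen=True)
class LogisticSpec:
    """Design of one incompatibility regression.

    All columns share length; ``response`` is the 0/1 phenotype, ``g_m`` and
    ``g_o`` the additive genotype terms, ``g_ic`` the binary incompatibility
    indicator, and ``covariates`` an optional (n, k) numeric array.
    """

    response: np.ndarray
    g_m: np.ndarray
    g_o: np.ndarray
    g_ic: np.ndarray
    covariates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        y = np.asarray(self.response)
        n = y.size
        for name in ("g_m", "g_o", "g_ic"):
            if np.asarray(getattr(self, name)).shape != (n,):
                raise ValueError(f"{name} must have the same length as response")
        if not set(np.unique(y)).issubset({0, 1}):
            raise ValueError("response must be binary 0/1")
        if self.covariates is not None and np.asarray(self.covariates).shape[0] != n:
            raise ValueError("covariates must have one row per family")

    def design(self, include_ic: bool = True) -> np.ndarray:
        """Design matrix: intercept, Gm, Go, covariates, then Gic if asked."""
        cols = [np.ones(len(self.response)), self.g_m, self.g_o]
        if self.covariates is not None:
            cov = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
            if cov.shape[0] != len(self.response):
                cov = cov.T
            cols.extend(cov.T)
        if include_ic:
            cols.append(self.g_ic)
        return np.column_stack(cols).astype(np.float64)


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit: coefficients, SEs, log-likelihood."""

    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool


@dataclass(frozen=True)
class MFGITestResult:
    """LRT of the incompatibility term, with OR and 95% Wald CI."""

    beta_ic: float
    se_ic: float
    lrt_stat: float
    df: int
    p_value: float  # NaN when either fit failed
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    converged: bool
    selected_model_id: Optional[int] = None


def _fit(y: np.ndarray, x: np.ndarray) -> LogisticFit:
    """Newton ML fit (lbfgs fallback), never raising.

    Under complete or quasi-complete separation the coefficient estimates
    drift to the boundary and the Wald standard errors explode; such fits
    are returned with ``converged=False``.
    """
    k = x.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, x).fit(disp=0, method="newton", maxiter=100)
        except Exception:
            try:
                res = sm.Logit(y, x).fit(disp=0, method="lbfgs", maxiter=500)
            except Exception:
                return LogisticFit(np.full(k, np.nan), np.full(k, np.nan), np.nan, False)
        bse = np.asarray(res.bse, dtype=np.float64)
    converged = bool(res.mle_retvals.get("converged", False))
    # exploding estimates/SEs mark a boundary fit even if the optimizer
    # reported convergence by its own tolerance
    if not np.all(np.isfinite(bse)) or np.any(np.abs(res.params) > 50):
        converged = False
    llf = float(res.llf)
    return LogisticFit(np.asarray(res.params, float), bse,
                       llf if np.isfinite(llf) else np.nan, converged)


def fit_logistic(spec: LogisticSpec, include_ic: bool = True) -> LogisticFit:
    """Fit the incompatibility regression (or the reduced model without Gic).

    The response must contain both classes; a constant Gic column with
    ``include_ic=True`` is refused because the coefficient is unidentifiable
    next to the intercept.
    """
    y = np.asarray(spec.response, dtype=np.float64)
    if y.min() == y.max():
        raise ValueError("response has a single class; the model is not identifiable")
    if include_ic and np.ptp(np.asarray(spec.g_ic)) == 0:
        raise ValueError("g_ic is constant; fit the reduced model instead")
    return _fit(y, spec.design(include_ic=include_ic))


def lrt_incompatibility(spec: LogisticSpec,
                        selected_model_id: Optional[int] = None) -> MFGITestResult:
    """Likelihood-ratio test of H0: bic = 0.

    The statistic is twice the log-likelihood difference between the full
    fit and the reduced fit dropping only Gic, referred to chi-square(1).
    A constant Gic column carries no information: the result is returned
    with statistic 0 and p-value 1.

    Complete or quasi-complete separation, or a failed optimization, in
    either fit yields ``converged=False`` with a missing (NaN) p-value
    rather than a fabricated one; the boundary log-likelihoods are still
    recorded on the result for diagnostic use.
    """
    y = np.asarray(spec.response, dtype=np.float64)
    if y.min() == y.max():
        raise ValueError("response has a single class; the test is undefined")

    x_full = spec.design(include_ic=True)
    x_red = spec.design(include_ic=False)
    # Gic inside the reduced column span (constant, or duplicating a
    # covariate) adds no information: the LRT is identically zero
    if np.linalg.matrix_rank(x_full) == np.linalg.matrix_rank(x_red):
        red = _fit(y, x_red)
        return MFGITestResult(0.0, np.nan, 0.0, 1, 1.0, 1.0, np.nan, np.nan,
                              red.converged, selected_model_id)

    full = _fit(y, x_full)
    reduced = _fit(y, x_red)
    ok = (full.converged and reduced.converged
          and np.isfinite(full.llf) and np.isfinite(reduced.llf))

    beta_ic = full.params[-1]
    se_ic = full.bse[-1]
    lrt = max(0.0, 2.0 * (full.llf - reduced.llf)) if ok else np.nan
    p = float(stats.chi2.sf(lrt, df=1)) if ok else np.nan
    with np.errstate(over="ignore"):
        or_ = float(np.exp(beta_ic))
        lo = float(np.exp(beta_ic - _Z975 * se_ic))
        hi = float(np.exp(beta_ic + _Z975 * se_ic))
    return MFGITestResult(float(beta_ic), float(se_ic), float(lrt) if ok else np.nan,
                          1, p, or_, lo, hi, ok, selected_model_id)


def two_step_test(
    y,
    classifications,
    g_m,
    g_o,
    covariates=None,
    config: Optional[SelectionConfig] = None,
    select: bool = True,
) -> tuple[Optional[SelectionResult], MFGITestResult]:
    """Run Step 1 selection then the Step 2 LRT under the selected model.

    With ``select=False`` the selection step is skipped and Model 11 is used
    throughout — the "full model" baseline against which the two-step
    procedure is compared.
    """
    y = np.asarray(y, dtype=np.int64)
    if select:
        cfg = config if config is not None else SelectionConfig()
        sel: Optional[SelectionResult] = permutation_select(y, classifications, cfg)
        model: MFGIModel = get_model(sel.final_model_id)
    else:
        sel = None
        model = get_model(11)
    g_ic = code_incompatibility(model, classifications)
    spec = LogisticSpec(y, np.asarray(g_m), np.asarray(g_o), g_ic, covariates)
    return sel, lrt_incompatibility(spec, selected_model_id=model.model_id)
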