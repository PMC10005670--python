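"""Covariate-adjusted models of the TG response.

The central object is :class:`ResponseModel`, a logistic model of the
responder/nonresponder outcome given clinical covariates (age, sex,
BMI, baseline TG) and a genetic risk score; its :meth:`~ResponseModel.fit`
returns a :class:`ResponseModelResults` carrying coefficient estimates,
log-likelihoods, McFadden's pseudo-R2 and fitted probabilities, with a
``summary()`` table.  Around it sit the supporting statistics used in
the analysis: the explained-variance contribution of a GRS in a linear
model (delta R2), Welch's two-sample t-test for group comparisons, and
the per-SNP genotype-by-visit interaction test implemented through its
change-score equivalent (for a balanced two-visit design with a random
subject intercept, the interaction contrast is exactly the genotype
coefficient of the regression of the TG change on genotype and
covariates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import ttest_ind

from .cohort import Cohort, Sex

__all__ = [
    "ResponseModel",
    "ResponseModelResults",
    "fit_logistic",
    "mcfadden_r2",
    "delta_r2",
    "group_ttest",
    "snp_visit_interaction",
    "SeparationWarning",
]

DEFAULT_COVARIATES = ("age", "sex", "bmi", "tg_baseline")


class SeparationWarning(UserWarning):
    """Perfect or quasi-perfect separation detected during a logistic fit."""


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns until the design is full rank (pivoted QR order)."""
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return X
    from scipy.linalg import qr

    _, _, piv = qr(arr, pivoting=True, mode="economic")
    keep = sorted(piv[:rank])
    dropped = [X.columns[j] for j in range(arr.shape[1]) if j not in keep]
    warnings.warn(f"dropping collinear columns: {dropped}", stacklevel=3)
    return X.iloc[:, keep]


def _bernoulli_llf(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _penalized_irls(y, X, alpha=1e-6, maxiter=200, gtol=1e-8):
    """Ridge-penalized IRLS fallback for separated logistic fits."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(maxiter):
        p = expit(X @ beta)
        grad = X.T @ (y - p) - alpha * beta
        W = p * (1 - p)
        H = (X.T * W) @ X + alpha * np.eye(k)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.linalg.norm(grad) < gtol:
            break
    p = expit(X @ beta)
    cov = np.linalg.inv((X.T * (p * (1 - p))) @ X + alpha * np.eye(k))
    return beta, cov, p


@dataclass
class ResponseModelResults:
    """Fitted logistic response model: estimates, likelihoods, diagnostics."""

    params: pd.Series
    bse: pd.Series
    llf: float
    llnull: float
    fittedvalues: pd.Series  # fitted probabilities of the positive class
    nobs: int
    converged: bool
    separation: bool
    exog_columns: list

    @property
    def mcfadden(self) -> float:
        return mcfadden_r2(self)

    def predict(self, design: pd.DataFrame) -> pd.Series:
        X = sm.add_constant(design[[c for c in self.exog_columns if c != "const"]],
                            has_constant="add")
        X = X[self.params.index]
        return pd.Series(expit(X.to_numpy(dtype=float) @ self.params.to_numpy()),
                         index=design.index)

    def summary(self) -> str:
        lines = [
            "Logistic response model",
            f"  n = {self.nobs}, converged = {self.converged}, separation = {self.separation}",
            f"  log-likelihood = {self.llf:.4f} (null {self.llnull:.4f})",
            f"  McFadden pseudo-R2 = {self.mcfadden:.4f}",
            "",
            f"  {'term':<14}{'coef':>12}{'std err':>12}",
        ]
        for term in self.params.index:
            lines.append(f"  {term:<14}{self.params[term]:>12.4f}{self.bse[term]:>12.4f}")
        return "\n".join(lines)


class ResponseModel:
    """Logistic model of the probability of responding to supplementation.

    Parameters
    ----------
    outcome
        Binary vector (1 = positive class, responder by default).
    design
        Covariate matrix (no intercept; one is added).  Collinear
        columns are dropped with a warning.
    """

    def __init__(self, outcome, design: pd.DataFrame):
        outcome = pd.Series(outcome).astype(float)
        if not set(outcome.unique()) <= {0.0, 1.0}:
            raise ValueError("outcome must be binary (0/1)")
        if outcome.nunique() < 2:
            raise ValueError("outcome has a single class; logistic fit undefined")
        if isinstance(design, pd.DataFrame):
            design = design.astype(float)
        else:
            design = pd.DataFrame(np.asarray(design, dtype=float))
        if len(design) != len(outcome):
            raise ValueError("outcome and design lengths differ")
        self.outcome = outcome
        self.design = design

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        grs: pd.Series | None = None,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        positive: str = "responder",
    ) -> "ResponseModel":
        """Build the model from a labelled cohort.

        ``grs`` is a per-subject score series (e.g. one column of
        :func:`trigrs.scoring.grs_profiles`); ``covariates`` draws from
        the phenotype table (sex is coded 0 = female, 1 = male).
        """
        pheno = cohort.phenotype_frame()
        ids = [i for i in cohort.labelled_ids() if grs is None or i in grs.index]
        pheno = pheno.loc[ids]
        y = (pheno["response"] == positive).astype(float)
        design = pd.DataFrame(index=pheno.index)
        for cov in covariates:
            if cov == "sex":
                design["sex"] = (pheno["sex"] == Sex.male.value).astype(float)
            else:
                design[cov] = pheno[cov].astype(float)
        if grs is not None:
            design["grs"] = grs.loc[ids].astype(float)
        return cls(y, design)

    def fit(self, maxiter: int = 100, gtol: float = 1e-8) -> ResponseModelResults:
        """Maximum-likelihood fit (Newton IRLS; ridge 1e-6 under separation)."""
        y = self.outcome.to_numpy()
        X = _drop_collinear(sm.add_constant(self.design, has_constant="add"))
        columns = list(X.columns)
        arr = X.to_numpy(dtype=float)

        from statsmodels.tools.sm_exceptions import (
            PerfectSeparationError,
            PerfectSeparationWarning,
        )

        separation = False
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(y, arr).fit(disp=0, maxiter=maxiter, tol=gtol,
                                           method="newton")
            params, cov = res.params, res.cov_params()
            probs = expit(arr @ params)
            converged = bool(res.mle_retvals.get("converged", True))
            if np.abs(params).max() > 50 or not converged:
                separation = True
        except (PerfectSeparationError, PerfectSeparationWarning,
                np.linalg.LinAlgError):
            separation = True
        if separation:
            warnings.warn(
                "separation detected; refitting with ridge penalty 1e-6",
                SeparationWarning,
                stacklevel=2,
            )
            params, cov, probs = _penalized_irls(y, arr, gtol=gtol)
            converged = True

        pbar = y.mean()
        llnull = _bernoulli_llf(y, np.full_like(y, pbar))
        return ResponseModelResults(
            params=pd.Series(params, index=columns),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=columns),
            llf=_bernoulli_llf(y, probs),
            llnull=llnull,
            fittedvalues=pd.Series(probs, index=self.design.index),
            nobs=len(y),
            converged=converged,
            separation=separation,
            exog_columns=columns,
        )


def fit_logistic(outcome, design) -> ResponseModelResults:
    """Functional wrapper: fit a logistic model and return its results."""
    return ResponseModel(outcome, pd.DataFrame(design)).fit()


def mcfadden_r2(fit: ResponseModelResults) -> float:
    """McFadden's pseudo-R2, ``1 - llf / llnull``."""
    if fit.llnull == 0:
        raise ValueError("null log-likelihood is zero; pseudo-R2 undefined")
    return 1.0 - fit.llf / fit.llnull


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R2 of a least-squares fit with intercept (rank-deficiency tolerant)."""
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient design in R2 computation; dropped implicitly",
                      stacklevel=3)
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    return 1.0 - float(np.sum(resid ** 2)) / tss


def delta_r2(outcome, covariates, grs) -> float:
    """Explained-variance contribution of the GRS beyond covariates.

    ``R2(covariates + GRS) - R2(covariates)`` from nested least-squares
    fits; non-negative by construction (tiny negative rounding is
    clipped).  Returned as a proportion; multiply by 100 to report in
    percent.
    """
    y = np.asarray(outcome, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov.reshape(-1, 1) if cov.size else np.empty((len(y), 0))
    g = np.asarray(grs, dtype=float).reshape(-1, 1)
    if len(y) <= cov.shape[1] + 2:
        raise ValueError("too few observations for the nested comparison")
    full = _ols_r2(y, np.hstack([cov, g]))
    reduced = _ols_r2(y, cov)
    return max(full - reduced, 0.0)


def group_ttest(values_a, values_b) -> tuple:
    """Two-sided Welch (unequal-variance) t-test between two groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    stat, p = ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)


def snp_visit_interaction(tg_baseline, tg_post, dosage, covariates=None,
                          return_details: bool = False):
    """Genotype-by-visit interaction p-value for paired TG measurements.

    Fits the change-score regression ``(tg_post - tg_baseline) ~ dosage
    + covariates`` and tests the genotype coefficient; in a balanced
    two-visit random-intercept model this is exactly the visit-by-
    genotype interaction contrast.
    """
    delta = np.asarray(tg_post, dtype=float) - np.asarray(tg_baseline, dtype=float)
    g = np.asarray(dosage, dtype=float)
    if np.nanvar(g) == 0:
        raise ValueError("monomorphic dosage: interaction test undefined")
    parts = [g.reshape(-1, 1)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov.reshape(-1, 1)
        parts.append(cov)
    X = sm.add_constant(np.hstack(parts), has_constant="add")
    res = sm.OLS(delta, X).fit()
    p = float(res.pvalues[1])  # column 1 is the dosage term
    if return_details:
        return p, {"coef": float(res.params[1]), "se": float(res.bse[1]),
                   "t": float(res.tvalues[1]), "df_resid": float(res.df_resid)}
    return p
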