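"""Efficient score tests of genotypic scores under a logistic null model.

One covariate-only logistic regression (disease ~ sex + 20 genotypic
PCs) is fitted per cohort and reused across thousands of scores.  Each
score s is then tested with the efficient score test — gradient and
information of the log-likelihood evaluated at the null fit:

    U = s' (y - mu)
    V = s'Ws - s'WX (X'WX)^{-1} X'Ws,   W = diag(mu (1 - mu))

V is the efficient information after projecting s out of the covariate
space; U^2/V is chi-square with 1 df under the null.  Reported log odds
ratios use the one-step estimator U/V, multiplied by the SD of the score
so the coefficient is the log odds ratio per one-SD increase of the
score.  A full maximum-likelihood refit including the score is available
behind ``refit=True`` for validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .scoring import GateScore, LocusScore

logger = logging.getLogger(__name__)

__all__ = [
    "NullModel",
    "AssociationResult",
    "fit_null",
    "efficient_score_test",
    "standardized_log_or",
    "measured_level_association",
    "association_table",
]


@dataclass
class NullModel:
    """Fitted covariate-only logistic null, shared across all score tests."""

    outcome: np.ndarray
    X: np.ndarray                 # design with intercept
    fitted_probabilities: np.ndarray
    weight_diagonal: np.ndarray   # mu (1 - mu)
    xtwx_inv: np.ndarray
    convergence_flag: bool

    @property
    def residuals(self) -> np.ndarray:
        return self.outcome - self.fitted_probabilities

    @property
    def n_cases(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_noncases(self) -> int:
        return int(len(self.outcome) - self.outcome.sum())


def fit_null(outcome: np.ndarray, covariates: pd.DataFrame | np.ndarray | None) -> NullModel:
    """Fit the covariate-only logistic null model by maximum likelihood.

    An intercept is always added.  Raises on non-binary or single-class
    outcomes, rank-deficient covariates, and (quasi-)separation.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    if covariates is None:
        X = np.ones((len(y), 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(len(y)), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient (after intercept)")

    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    mu = np.asarray(res.fittedvalues)
    eta = X @ res.params
    if np.any(np.abs(eta) > 30) or np.any(mu <= 1e-12) or np.any(mu >= 1 - 1e-12):
        raise ValueError(
            "separation detected (unbounded linear predictor); "
            "consider a penalized (Firth) fit"
        )
    grad = X.T @ (y - mu)
    if np.max(np.abs(grad)) > 1e-6 * max(1.0, len(y) / 1e4):
        raise RuntimeError("null model gradient not at optimum")
    w = mu * (1 - mu)
    xtwx_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    return NullModel(
        outcome=y,
        X=X,
        fitted_probabilities=mu,
        weight_diagonal=w,
        xtwx_inv=xtwx_inv,
        convergence_flag=bool(res.converged),
    )


@dataclass
class AssociationResult:
    gene_id: str
    score_type: str  # trans | cis | measured_protein | cell_phenotype
    U: float
    V: float
    chi2: float
    pvalue: float
    log_or_std: float
    n_cases: int
    n_noncases: int
    effective_n: float | None = None
    n_loci: int | None = None
    study: str = ""


def standardized_log_or(U: float, V: float, score_sd: float) -> float:
    """One-step log OR per score unit (U/V), rescaled to per-SD units."""
    if V <= 0:
        raise ValueError("V must be positive")
    return (U / V) * score_sd


def efficient_score_test(
    null: NullModel,
    score_values: np.ndarray,
    gene_id: str = "",
    score_type: str = "trans",
    study: str = "",
    effective_n: float | None = None,
    n_loci: int | None = None,
    refit: bool = False,
) -> AssociationResult:
    """Test one score against the fitted null (1-df chi-square U^2/V)."""
    s = np.asarray(score_values, dtype=float)
    if len(s) != len(null.outcome):
        raise ValueError("score not aligned with cohort")
    sd = float(s.std(ddof=1))
    if sd == 0:
        raise ValueError("constant score cannot be tested")
    U = float(s @ null.residuals)
    ws = null.weight_diagonal * s
    a = null.X.T @ ws
    sWs = float(s @ ws)
    V = float(sWs - a @ null.xtwx_inv @ a)
    if V <= 1e-10 * sWs:
        raise ValueError("non-positive efficient information (collinear with covariates)")
    chi2 = U * U / V
    pvalue = float(stats.chi2.sf(chi2, df=1))
    if refit:
        full = sm.GLM(
            null.outcome, np.column_stack([null.X, s]), family=sm.families.Binomial()
        ).fit()
        beta = float(full.params[-1])
        log_or = beta * sd
    else:
        log_or = standardized_log_or(U, V, sd)
    return AssociationResult(
        gene_id=gene_id,
        score_type=score_type,
        U=U,
        V=V,
        chi2=chi2,
        pvalue=max(pvalue, np.finfo(float).tiny),
        log_or_std=log_or,
        n_cases=null.n_cases,
        n_noncases=null.n_noncases,
        effective_n=effective_n,
        n_loci=n_loci,
        study=study,
    )


def test_gate_score(
    null: NullModel, gs: GateScore, exclude: np.ndarray | None = None
) -> AssociationResult:
    """Score-test a GateScore; ``exclude`` masks individuals (e.g. the
    proteomics subset when testing scores derived from that study)."""
    values = gs.values
    if exclude is not None:
        raise ValueError("pass a pre-subset null model for exclusions")
    return efficient_score_test(
        null,
        values,
        gene_id=gs.gene_id,
        score_type="trans",
        study=gs.study,
        effective_n=gs.effective_n,
        n_loci=gs.n_loci,
    )


def test_cis_score(null: NullModel, cs: LocusScore, study: str = "") -> AssociationResult:
    return efficient_score_test(
        null, cs.values, gene_id=cs.gene_id, score_type="cis", study=study
    )


def measured_level_association(
    outcome: np.ndarray,
    measured_values: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    gene_id: str = "",
    subset: np.ndarray | None = None,
    score_type: str = "measured_protein",
) -> AssociationResult:
    """Association of disease with a measured level (e.g. plasma protein).

    The same efficient-score machinery applied to a measured predictor
    standardized to unit SD; ``subset`` restricts the analysis (e.g. to
    incident cases plus noncases).  Covariates for measured levels
    typically include age, sex and ancestry rather than genotypic PCs.
    """
    y = np.asarray(outcome, dtype=float)
    v = np.asarray(measured_values, dtype=float)
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        y = y[subset]
        v = v[subset]
        if covariates is not None:
            covariates = np.asarray(covariates, dtype=float)[subset]
    v = (v - v.mean()) / v.std(ddof=1)
    null = fit_null(y, covariates)
    return efficient_score_test(null, v, gene_id=gene_id, score_type=score_type)


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten results to the reporting table (Tables 1-3 column shape)."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "study": [r.study for r in results],
            "score_type": [r.score_type for r in results],
            "n_loci": [r.n_loci for r in results],
            "effective_n": [r.effective_n for r in results],
            "log_or_std": [r.log_or_std for r in results],
            "pvalue": [r.pvalue for r in results],
            "n_cases": [r.n_cases for r in results],
            "n_noncases": [r.n_noncases for r in results],
        }
    )
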