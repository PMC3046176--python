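"""Null-model residual scores.

GMDR replaces the case/control counts that MDR accumulates in multilocus
cells with per-subject residuals from a null logistic regression,

    s_i = y_i - pihat_i,

where pihat_i is the fitted probability of disease from the model containing
the intercept and any covariates but no genotype terms (the null hypothesis
of no genotypic effect). Affected subjects always score positive, unaffected
negative, and the scores sum to zero by the logistic score equations.
Without covariates pihat is the sample prevalence and GMDR reduces to MDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .data_io import GenotypeDataset

__all__ = ["NullModelFit", "ScoreVector", "ScoringError", "fit_null_model", "residual_scores"]

MAX_ITER = 100
#: coefficient magnitude beyond which we declare (quasi-)separation
SEPARATION_BOUND = 30.0


class ScoringError(RuntimeError):
    """Raised when the null logistic fit fails (non-convergence, separation)."""


@dataclass(frozen=True)
class NullModelFit:
    """MLE of the intercept(+covariates) logistic model under H0: no genotype effect."""

    beta0_hat: float
    betaE_hat: np.ndarray  # (c,) covariate coefficients; empty if unadjusted
    fitted_prob: np.ndarray  # (n,) per-subject pihat in (0,1)
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class ScoreVector:
    """Per-subject residual scores s_i = y_i - pihat_i."""

    scores: np.ndarray


def fit_null_model(dataset: GenotypeDataset, adjust: bool = True) -> NullModelFit:
    """Fit the covariate-only (or intercept-only) logistic null model by IRLS.

    With ``adjust=False`` (or no covariates) the MLE is closed-form: the
    fitted probability is the sample prevalence for every subject.
    """
    y = dataset.phenotype.astype(float)
    n_case = int(y.sum())
    if n_case == 0 or n_case == len(y):
        raise ScoringError("phenotype must contain both cases and controls")
    if adjust and dataset.n_covariates == 0:
        raise ScoringError("adjust=True requires at least one covariate column")

    if not adjust or dataset.n_covariates == 0:
        p = n_case / len(y)
        return NullModelFit(
            beta0_hat=float(np.log(p / (1 - p))),
            betaE_hat=np.empty(0),
            fitted_prob=np.full(len(y), p),
            converged=True,
            n_iter=0,
        )

    X = sm.add_constant(dataset.covariates, has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(maxiter=MAX_ITER, tol=1e-10)
    except Exception as exc:  # statsmodels raises PerfectSeparation{Error,Warning}
        raise ScoringError(f"null logistic fit failed: {exc}") from exc
    if not res.converged:
        raise ScoringError(f"null logistic fit did not converge in {MAX_ITER} iterations")
    if np.any(np.abs(res.params) > SEPARATION_BOUND):
        raise ScoringError(
            "diverging coefficients suggest (quasi-)separation of the phenotype "
            f"by the covariates: {res.params}"
        )
    return NullModelFit(
        beta0_hat=float(res.params[0]),
        betaE_hat=np.asarray(res.params[1:]),
        fitted_prob=np.asarray(res.fittedvalues),
        converged=True,
        n_iter=int(res.fit_history["iteration"]),
    )


def residual_scores(fit: NullModelFit, dataset: GenotypeDataset) -> ScoreVector:
    """Residual score s_i = y_i - pihat_i for every subject."""
    if fit.fitted_prob.shape[0] != dataset.n_subjects:
        raise ValueError(
            f"fit covers {fit.fitted_prob.shape[0]} subjects, dataset has {dataset.n_subjects}"
        )
    if not fit.converged:
        raise ScoringError("refusing to score from a non-converged fit")
    return ScoreVector(scores=dataset.phenotype - fit.fitted_prob)
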