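"""Closed-form theory of classification accuracy for epistasis models.

The generative law is a logistic penetrance over a high/low-risk partition of
multilocus genotypes plus one normally distributed covariate:

    P(affected | g, e) = expit(beta0 + betaG * x_G(g) + betaE * e),
    e ~ Normal(0, sigma_E**2),

with genotype priors given by Hardy-Weinberg and linkage equilibrium. From
this law we obtain, without simulation:

* the covariate-integrated (expected) penetrance of each genotype group
  (Gauss-Hermite quadrature);
* the population prevalence K and, via Bayes, the genotype distribution
  conditional on case/control status in an ascertained sample;
* the expected residual-score masses per cell, both unadjusted (scores are
  +/-(1-p), -p with p the sample case fraction) and covariate-adjusted
  (scores integrate the population-limit null logistic fit over the Bayes
  posterior of the covariate given status and genotype);
* theoretical classification accuracy (and sensitivity/specificity/balanced
  accuracy) under majority labeling — the large-sample limit of MDR/GMDR
  testing accuracy;
* Culverhouse-style heritability, the genotype-attributable variance
  fraction sum_g P(g) (pen_g - K)^2 / (K (1 - K)).

Three epistasis patterns are built in: the digenic checkerboard (high risk =
exactly one heterozygous locus), and the tri/tetragenic "uppercase-letter"
models 3ULM/4ULM (high risk = exactly 3 of 6, resp. 4 of 8, major alleles).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit

from .data_io import VALID_MODELS

__all__ = [
    "PenetranceModel",
    "GenotypePrior",
    "ConditionalDistribution",
    "ExpectedScoreTable",
    "TheoreticalMetrics",
    "genotype_prior",
    "high_risk_fraction",
    "is_high_risk",
    "expected_penetrance",
    "calibrate_covariate_sd",
    "conditional_distribution",
    "theoretical_accuracy_genotype",
    "ascertained_null_fit",
    "expected_score_table",
    "theoretical_accuracy_score",
    "heritability",
    "accuracy_heritability_grid",
]

GH_NODES = 128
N_FUNCTIONAL = {"checkerboard": 2, "3ULM": 3, "4ULM": 4}


@lru_cache(maxsize=4)
def _gh(n: int = GH_NODES) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(n)
    return x, w / np.sqrt(np.pi)


def _nodes(sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/weights for integrating against Normal(0, sd^2)."""
    x, w = _gh()
    return np.sqrt(2.0) * sd * x, w


def is_high_risk(model_name: str, genotype: Sequence[int]) -> bool:
    """High-risk predicate on a multilocus genotype (minor-allele counts)."""
    if model_name == "checkerboard":
        return sum(1 for c in genotype if c == 1) == 1
    if model_name == "3ULM":
        return sum(2 - c for c in genotype) == 3
    if model_name == "4ULM":
        return sum(2 - c for c in genotype) == 4
    raise ValueError(f"unknown model {model_name!r}; expected one of {VALID_MODELS}")


@dataclass(frozen=True)
class PenetranceModel:
    """Logistic penetrance with a genotype-group indicator and one covariate."""

    beta0: float
    betaG: float
    betaE: float
    covariate_sd: float
    model_name: str

    def __post_init__(self) -> None:
        if self.model_name not in VALID_MODELS:
            raise ValueError(f"unknown model {self.model_name!r}")
        if self.covariate_sd < 0:
            raise ValueError("covariate_sd must be nonnegative")

    @property
    def n_loci(self) -> int:
        return N_FUNCTIONAL[self.model_name]

    def x_g(self, genotype: Sequence[int]) -> int:
        return int(is_high_risk(self.model_name, genotype))

    def penetrance(self, x_g: int, e: np.ndarray | float) -> np.ndarray:
        """P(affected | group, covariate value)."""
        return expit(self.beta0 + self.betaG * x_g + self.betaE * np.asarray(e, dtype=float))


@dataclass(frozen=True)
class GenotypePrior:
    """HWE x LE prior over multilocus genotype cells."""

    cells: Mapping[tuple[int, ...], float]

    def total(self) -> float:
        return float(sum(self.cells.values()))


@dataclass(frozen=True)
class ConditionalDistribution:
    """P(genotype | case) and P(genotype | control) with prevalence K."""

    p_case: Mapping[tuple[int, ...], float]
    p_control: Mapping[tuple[int, ...], float]
    prevalence_K: float


@dataclass(frozen=True)
class ScoreCell:
    pos_mass: float  # expected sum of (positive) case scores in the cell
    neg_mass: float  # expected sum of |negative| control scores

    @property
    def score_sum(self) -> float:
        return self.pos_mass - self.neg_mass


@dataclass(frozen=True)
class ExpectedScoreTable:
    cells: Mapping[tuple[int, ...], ScoreCell]
    counts: Mapping[tuple[int, ...], float]  # expected subjects per cell
    n_case: float
    n_control: float
    adjusted: bool


@dataclass(frozen=True)
class TheoreticalMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    labeling: Mapping[tuple[int, ...], str]


def _maf_vector(mafs: float | Sequence[float], loci: int) -> np.ndarray:
    v = np.atleast_1d(np.asarray(mafs, dtype=float))
    if v.size == 1:
        v = np.repeat(v, loci)
    if v.size != loci:
        raise ValueError(f"need {loci} MAFs, got {v.size}")
    if np.any((v <= 0) | (v > 0.5)):
        raise ValueError(f"MAF must lie in (0, 0.5], got {v}")
    return v


def genotype_prior(mafs: float | Sequence[float], loci: int) -> GenotypePrior:
    """Product of per-locus HWE triples; genotype codes are minor-allele counts."""
    v = _maf_vector(mafs, loci)
    per_locus = [np.array([(1 - m) ** 2, 2 * m * (1 - m), m**2]) for m in v]
    cells = {
        g: float(np.prod([per_locus[j][c] for j, c in enumerate(g)]))
        for g in product(range(3), repeat=loci)
    }
    return GenotypePrior(cells=cells)


def high_risk_fraction(model_name: str, mafs: float | Sequence[float]) -> float:
    """Prior probability mass of the model's high-risk genotype set."""
    if model_name not in N_FUNCTIONAL:
        raise ValueError(f"unknown penetrance model {model_name!r}")
    loci = N_FUNCTIONAL[model_name]
    prior = genotype_prior(mafs, loci)
    return float(sum(p for g, p in prior.cells.items() if is_high_risk(model_name, g)))


def expected_penetrance(model: PenetranceModel, x_g: int) -> float:
    """Covariate-integrated penetrance of a genotype group (Eq.-5-style integral)."""
    if model.covariate_sd == 0:
        return float(expit(model.beta0 + model.betaG * x_g))
    e, w = _nodes(model.covariate_sd)
    val = float(np.sum(w * model.penetrance(x_g, e)))
    if not np.isfinite(val):
        raise FloatingPointError("quadrature produced a non-finite penetrance")
    return val


class CalibrationError(RuntimeError):
    """No covariate SD reproduces the target group penetrances."""


def calibrate_covariate_sd(
    beta0: float,
    betaG: float,
    betaE: float,
    target_low: float,
    target_high: float,
    model_name: str = "checkerboard",
    max_sd: float = 20.0,
) -> float:
    """Covariate SD minimizing squared deviation of the two covariate-integrated
    group penetrances from their targets; errors out if the residual exceeds 1e-3.
    """
    if not (0 < target_low < 1 and 0 < target_high < 1):
        raise ValueError("targets must lie in (0, 1)")

    def objective(sd: float) -> float:
        m = PenetranceModel(beta0, betaG, betaE, sd, model_name)
        return (expected_penetrance(m, 0) - target_low) ** 2 + (
            expected_penetrance(m, 1) - target_high
        ) ** 2

    res = minimize_scalar(objective, bounds=(0.0, max_sd), method="bounded",
                          options={"xatol": 1e-8})
    sd = float(res.x)
    m = PenetranceModel(beta0, betaG, betaE, sd, model_name)
    resid = max(
        abs(expected_penetrance(m, 0) - target_low),
        abs(expected_penetrance(m, 1) - target_high),
    )
    if resid > 1e-3:
        raise CalibrationError(
            f"no covariate SD in [0, {max_sd}] reaches targets "
            f"({target_low}, {target_high}); best residual {resid:.2e} at sd={sd:.3f}"
        )
    return sd


def _group_penetrances(
    model: PenetranceModel, penetrances: tuple[float, float] | None
) -> tuple[float, float]:
    """(low, high) covariate-integrated penetrances, optionally overridden."""
    if penetrances is not None:
        return float(penetrances[0]), float(penetrances[1])
    return expected_penetrance(model, 0), expected_penetrance(model, 1)


def conditional_distribution(
    model: PenetranceModel,
    prior: GenotypePrior,
    penetrances: tuple[float, float] | None = None,
) -> ConditionalDistribution:
    """Bayes inversion: P(g | case) ∝ pen(g) P(g), P(g | control) ∝ (1-pen(g)) P(g).

    ``penetrances`` fixes the (low, high) group penetrances explicitly, e.g.
    to values printed at 3 decimals, instead of integrating the model.
    """
    if abs(prior.total() - 1) > 1e-8:
        raise ValueError("prior does not sum to 1")
    pen_lo, pen_hi = _group_penetrances(model, penetrances)
    pen = {g: (pen_hi if is_high_risk(model.model_name, g) else pen_lo) for g in prior.cells}
    K = sum(prior.cells[g] * pen[g] for g in prior.cells)
    if K <= 0 or K >= 1:
        raise ValueError(f"degenerate prevalence K={K}")
    p_case = {g: prior.cells[g] * pen[g] / K for g in prior.cells}
    p_control = {g: prior.cells[g] * (1 - pen[g]) / (1 - K) for g in prior.cells}
    return ConditionalDistribution(p_case=p_case, p_control=p_control, prevalence_K=float(K))


def theoretical_accuracy_genotype(
    dist: ConditionalDistribution, case_fraction: float = 0.5
) -> TheoreticalMetrics:
    """Accuracy of the optimal (majority) cell labeling in the ascertained sample.

    A cell is high-risk when its expected case mass is at least its expected
    control mass: case_fraction * P(g|case) >= (1-case_fraction) * P(g|control).
    """
    cf = case_fraction
    labeling = {
        g: ("high" if cf * dist.p_case[g] >= (1 - cf) * dist.p_control[g] else "low")
        for g in dist.p_case
    }
    sens = sum(dist.p_case[g] for g, lab in labeling.items() if lab == "high")
    spec = sum(dist.p_control[g] for g, lab in labeling.items() if lab == "low")
    return TheoreticalMetrics(
        accuracy=float(cf * sens + (1 - cf) * spec),
        sensitivity=float(sens),
        specificity=float(spec),
        balanced_accuracy=float(0.5 * (sens + spec)),
        labeling=labeling,
    )


def ascertained_null_fit(
    model: PenetranceModel,
    high_fraction: float,
    case_fraction: float = 0.5,
) -> tuple[float, float]:
    """Population limit of the null (intercept + covariate) logistic MLE.

    Maximizes the expected log-likelihood of the covariate-only model over a
    balanced (or ``case_fraction``-weighted) ascertained sample, whose
    covariate densities f(e | status) follow from the generative law by Bayes.
    """
    h = high_fraction
    e, w = _nodes(model.covariate_sd)
    mix = h * model.penetrance(1, e) + (1 - h) * model.penetrance(0, e)
    K = float(np.sum(w * mix))
    f_case = w * mix / K
    f_ctrl = w * (1 - mix) / (1 - K)
    cf = case_fraction

    def negll(b: np.ndarray) -> float:
        z = b[0] + b[1] * e
        # log expit(z) = z - log(1+e^z); log(1-expit(z)) = -log(1+e^z)
        lse = np.logaddexp(0.0, z)
        return -(cf * np.sum(f_case * (z - lse)) + (1 - cf) * np.sum(f_ctrl * (-lse)))

    def grad(b: np.ndarray) -> np.ndarray:
        pi = expit(b[0] + b[1] * e)
        gc = cf * (1 - pi) * f_case
        gu = (1 - cf) * pi * f_ctrl
        return -np.array([np.sum(gc) - np.sum(gu), np.sum(gc * e) - np.sum(gu * e)])

    res = minimize(negll, x0=np.array([0.0, 0.5]), jac=grad, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 500})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError("population-limit null fit did not converge")
    return float(res.x[0]), float(res.x[1])


def expected_score_table(
    model: PenetranceModel,
    prior: GenotypePrior,
    adjust: bool,
    n_case: float = 1000.0,
    n_control: float = 1000.0,
    penetrances: tuple[float, float] | None = None,
) -> ExpectedScoreTable:
    """Expected residual-score masses per cell in an ascertained sample.

    Unadjusted: every case scores 1-p and every control -p with p the sample
    case fraction. Adjusted: the null-fit probability pihat(e) from
    :func:`ascertained_null_fit` is integrated over the Bayes posterior of
    the covariate given status and genotype group.
    """
    dist = conditional_distribution(model, prior, penetrances)
    cf = n_case / (n_case + n_control)
    name = model.model_name
    if not adjust:
        e_case = {0: 1 - cf, 1: 1 - cf}
        e_ctrl = {0: cf, 1: cf}
    else:
        hf = sum(prior.cells[g] for g in prior.cells if is_high_risk(name, g))
        b0, b1 = ascertained_null_fit(model, hf, cf)
        e, w = _nodes(model.covariate_sd)
        pihat = expit(b0 + b1 * e)
        e_case, e_ctrl = {}, {}
        for xg in (0, 1):
            # covariate profile always comes from the model itself; a
            # `penetrances` override only repins the cell masses above
            pen_e = model.penetrance(xg, e)
            e_case[xg] = float(np.sum(w * pen_e * (1 - pihat)) / np.sum(w * pen_e))
            e_ctrl[xg] = float(np.sum(w * (1 - pen_e) * pihat) / np.sum(w * (1 - pen_e)))

    cells: dict[tuple[int, ...], ScoreCell] = {}
    counts: dict[tuple[int, ...], float] = {}
    for g in prior.cells:
        xg = int(is_high_risk(name, g))
        pos = n_case * dist.p_case[g] * e_case[xg]
        neg = n_control * dist.p_control[g] * e_ctrl[xg]
        cells[g] = ScoreCell(pos_mass=float(pos), neg_mass=float(neg))
        counts[g] = float(n_case * dist.p_case[g] + n_control * dist.p_control[g])
    return ExpectedScoreTable(
        cells=cells, counts=counts, n_case=n_case, n_control=n_control, adjusted=adjust
    )


def theoretical_accuracy_score(table: ExpectedScoreTable, T: float = 0.0) -> TheoreticalMetrics:
    """Accuracy of the score-mass labeling: cell high iff mean expected score >= T."""
    labeling = {
        g: ("high" if c.score_sum >= T * table.counts[g] else "low")
        for g, c in table.cells.items()
    }
    tp = sum(c.pos_mass for g, c in table.cells.items() if labeling[g] == "high")
    fp = sum(c.neg_mass for g, c in table.cells.items() if labeling[g] == "high")
    fn = sum(c.pos_mass for g, c in table.cells.items() if labeling[g] == "low")
    tn = sum(c.neg_mass for g, c in table.cells.items() if labeling[g] == "low")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return TheoreticalMetrics(
        accuracy=float((tp + tn) / (tp + tn + fp + fn)),
        sensitivity=float(sens),
        specificity=float(spec),
        balanced_accuracy=float(0.5 * (sens + spec)),
        labeling=labeling,
    )


def heritability(
    model: PenetranceModel,
    prior: GenotypePrior,
    penetrances: tuple[float, float] | None = None,
) -> float:
    """Genotype-attributable variance fraction sum_g P(g)(pen_g - K)^2 / (K(1-K))."""
    pen_lo, pen_hi = _group_penetrances(model, penetrances)
    pen = {g: (pen_hi if is_high_risk(model.model_name, g) else pen_lo) for g in prior.cells}
    K = sum(prior.cells[g] * pen[g] for g in prior.cells)
    if K <= 0 or K >= 1:
        raise ValueError(f"degenerate prevalence K={K}")
    var_g = sum(prior.cells[g] * (pen[g] - K) ** 2 for g in prior.cells)
    return float(var_g / (K * (1 - K)))


def accuracy_heritability_grid(
    model_names: Iterable[str],
    mafs: Iterable[float],
    beta_gs: Iterable[float],
    covariate_sd: float,
    beta0: float = -5.30,
    betaE: float = 1.0,
    min_accuracy: float | None = None,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Theoretical (accuracy, heritability) over a scenario grid with per-model
    Pearson correlation and least-squares fit of heritability on accuracy.

    ``min_accuracy`` drops scenarios below that accuracy before correlating.
    """
    rows = []
    for name in model_names:
        for maf in mafs:
            for bg in beta_gs:
                m = PenetranceModel(beta0, bg, betaE, covariate_sd, name)
                prior = genotype_prior(maf, m.n_loci)
                dist = conditional_distribution(m, prior)
                acc = theoretical_accuracy_genotype(dist).accuracy
                rows.append(
                    {
                        "model": name,
                        "maf": maf,
                        "beta_g": bg,
                        "accuracy": acc,
                        "heritability": heritability(m, prior),
                        "prevalence": dist.prevalence_K,
                    }
                )
    df = pd.DataFrame(rows)
    fits: dict[str, dict[str, float]] = {}
    for name, sub in df.groupby("model"):
        if min_accuracy is not None:
            sub = sub[sub["accuracy"] >= min_accuracy]
        if len(sub) < 3:
            raise ValueError(f"model {name}: fewer than 3 grid points to correlate")
        a = sub["accuracy"].to_numpy()
        h = sub["heritability"].to_numpy()
        if a.std() == 0 or h.std() == 0:
            raise ValueError(f"model {name}: zero variance, correlation undefined")
        r = float(np.corrcoef(a, h)[0, 1])
        slope, intercept = np.polyfit(a, h, 1)
        fits[name] = {"r": r, "slope": float(slope), "intercept": float(intercept),
                      "n": float(len(sub))}
    return df, fits
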