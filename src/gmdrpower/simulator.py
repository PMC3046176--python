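"""Balanced case-control simulator under the logistic penetrance models.

Subjects are drawn from the population law — genotypes at all markers from
HWE/LE, covariate from Normal(0, sigma_E^2), disease status from the
logistic penetrance of the functional loci — and accepted by rejection
sampling until both arms (n_total/2 cases, n_total/2 controls) are filled.
Functional loci are, by convention, the first k of the marker panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_io import GenotypeDataset, ScenarioSpec
from .scoring import ScoreVector

__all__ = ["SimulatedDataset", "simulate_case_control", "shuffle_null"]

DRAW_BUDGET = 10_000_000


@dataclass
class SimulatedDataset:
    """A GenotypeDataset plus simulation provenance."""

    dataset: GenotypeDataset
    spec: ScenarioSpec
    functional_indices: tuple[int, ...]
    realized_prevalence: float  # case fraction among all population draws


def _high_risk_rows(model_name: str, g: np.ndarray) -> np.ndarray:
    """Vectorized high-risk indicator over rows of functional-locus genotypes."""
    if model_name == "checkerboard":
        return ((g == 1).sum(axis=1) == 1).astype(np.int64)
    k = {"3ULM": 3, "4ULM": 4}[model_name]
    return ((2 * g.shape[1] - g.sum(axis=1)) == k).astype(np.int64)


def simulate_case_control(spec: ScenarioSpec, rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Draw a balanced case-control dataset under the scenario's generative law."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    k = spec.n_functional
    n_arm = spec.n_total // 2
    cases_g, cases_e = [], []
    ctrls_g, ctrls_e = [], []
    n_drawn = n_affected = 0
    batch = max(4 * spec.n_total, 10_000)
    while (len(cases_g) < n_arm or len(ctrls_g) < n_arm) and n_drawn < DRAW_BUDGET:
        g = rng.binomial(2, spec.maf, size=(batch, spec.n_markers)).astype(np.int8)
        e = rng.normal(0.0, spec.covariate_sd, size=batch)
        xg = _high_risk_rows(spec.model_name, g[:, :k])
        pi = expit(spec.beta_0 + spec.beta_g * xg + spec.beta_e * e)
        y = rng.random(batch) < pi
        n_drawn += batch
        n_affected += int(y.sum())
        need_case = n_arm - len(cases_g)
        need_ctrl = n_arm - len(ctrls_g)
        if need_case:
            idx = np.flatnonzero(y)[:need_case]
            cases_g.extend(g[idx])
            cases_e.extend(e[idx])
        if need_ctrl:
            idx = np.flatnonzero(~y)[:need_ctrl]
            ctrls_g.extend(g[idx])
            ctrls_e.extend(e[idx])
    if len(cases_g) < n_arm or len(ctrls_g) < n_arm:
        raise RuntimeError(
            f"could not fill both arms within {DRAW_BUDGET} draws "
            f"({len(cases_g)}/{n_arm} cases, {len(ctrls_g)}/{n_arm} controls); "
            "the scenario's prevalence is too extreme"
        )
    genotypes = np.vstack([np.array(cases_g), np.array(ctrls_g)])
    covar = np.concatenate([cases_e, ctrls_e])[:, None]
    phenotype = np.concatenate([np.ones(n_arm, dtype=np.int64), np.zeros(n_arm, dtype=np.int64)])
    order = rng.permutation(spec.n_total)  # interleave arms
    dataset = GenotypeDataset(
        subject_ids=[f"S{i + 1:05d}" for i in range(spec.n_total)],
        phenotype=phenotype[order],
        covariates=covar[order],
        genotypes=genotypes[order],
        marker_names=[f"M{j + 1}" for j in range(spec.n_markers)],
    )
    return SimulatedDataset(
        dataset=dataset,
        spec=spec,
        functional_indices=tuple(range(k)),
        realized_prevalence=n_affected / n_drawn,
    )


def shuffle_null(
    dataset: GenotypeDataset,
    what: str,
    seed: int | np.random.Generator,
    scores: ScoreVector | np.ndarray | None = None,
):
    """Break the genotype-outcome association by permutation.

    ``what='scores'`` permutes a residual-score vector (GMDR null protocol)
    and returns the permuted array; ``what='phenotype'`` returns a copy of
    the dataset with the phenotype vector permuted (MDR null protocol).
    Genotypes are never touched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(dataset.n_subjects)
    if what == "scores":
        if scores is None:
            raise ValueError("what='scores' requires a scores argument")
        s = scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores)
        return s[perm]
    if what == "phenotype":
        return GenotypeDataset(
            subject_ids=list(dataset.subject_ids),
            phenotype=dataset.phenotype[perm],
            covariates=dataset.covariates.copy(),
            genotypes=dataset.genotypes,
            marker_names=list(dataset.marker_names),
        )
    raise ValueError("what must be 'scores' or 'phenotype'")
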