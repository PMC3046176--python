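"""The MDR/GMDR data-reduction engine.

The algorithm, per cross-validation fold and interaction order k:

1. split subjects into stratified folds (one testing, rest training);
2. enumerate every combination of k of the m markers;
3. allocate training subjects to the 3**k multilocus cells of a combination
   and sum their residual scores per cell;
4. label a non-empty cell high-risk when its average score is >= a threshold
   T (default 0), low-risk otherwise, pooling cells into a 1-D classifier;
5. keep the combination with the highest training classification accuracy,
   where accuracy is measured on positive/negative score mass:
   TP = high-cell positive mass, TN = low-cell negative mass, etc.;
6. evaluate that combination's testing accuracy (TA) on the held-out fold.

Across folds the modal winner is the order's final model and the number of
folds electing it is the cross-validation consistency (CVC). Across orders
the model maximizing mean TA and CVC is selected; when the two statistics
disagree the more parsimonious (lower-order) model wins.

For balanced designs without covariates the residual scores are +/-0.5 and
the whole procedure is exactly count-based MDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_io import GenotypeDataset
from .scoring import ScoreVector, fit_null_model, residual_scores

__all__ = [
    "FactorCombination",
    "CellStats",
    "CellTable",
    "RiskLabeling",
    "ConfusionSummary",
    "OrderResult",
    "ModelSearchResult",
    "partition_cv",
    "tabulate_cells",
    "label_cells",
    "confusion",
    "search_best_model",
    "cross_validate",
]

FactorCombination = tuple[int, ...]


@dataclass(frozen=True)
class CellStats:
    score_sum: float
    pos_mass: float
    neg_mass: float
    n_case: int
    n_control: int

    @property
    def count(self) -> int:
        return self.n_case + self.n_control


@dataclass
class CellTable:
    """Per-multilocus-cell score masses for one factor combination."""

    combo: FactorCombination
    cells: dict[tuple[int, ...], CellStats]

    @property
    def total_mass(self) -> float:
        return sum(c.pos_mass + c.neg_mass for c in self.cells.values())


@dataclass
class RiskLabeling:
    labels: dict[tuple[int, ...], str]  # 'high' | 'low'
    threshold_T: float


@dataclass(frozen=True)
class ConfusionSummary:
    """Score-mass confusion: TP/FP from high-risk cells, FN/TN from low-risk."""

    TP: float
    TN: float
    FP: float
    FN: float

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / (self.TP + self.TN + self.FP + self.FN)

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP)

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)


@dataclass
class OrderResult:
    """Search outcome for one interaction order."""

    order: int
    fold_winners: list[FactorCombination]
    fold_tas: list[float]
    mean_ta: float
    cvc: int
    final_model: FactorCombination


@dataclass
class ModelSearchResult:
    per_order: dict[int, OrderResult]
    selected_order: int

    @property
    def selected(self) -> OrderResult:
        return self.per_order[self.selected_order]

    @property
    def final_model(self) -> FactorCombination:
        return self.selected.final_model

    @property
    def final_mean_ta(self) -> float:
        return self.selected.mean_ta


def partition_cv(
    n: int, folds: int, phenotype: np.ndarray, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified K-fold partition: list of (train_idx, test_idx) pairs.

    Subjects of each phenotype class are shuffled and dealt round-robin so
    every fold carries a near-equal share of cases and of controls.
    Deterministic given the seed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"folds={folds} exceeds n={n}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(np.asarray(phenotype) == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % folds
    out = []
    all_idx = np.arange(n)
    for f in range(folds):
        test = all_idx[fold_of == f]
        train = all_idx[fold_of != f]
        out.append((train, test))
    return out


def _as_scores(scores: ScoreVector | np.ndarray) -> np.ndarray:
    return scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores, dtype=float)


def tabulate_cells(
    scores: ScoreVector | np.ndarray,
    dataset: GenotypeDataset,
    combo: FactorCombination,
    subject_subset: np.ndarray | None = None,
) -> CellTable:
    """Allocate subjects to multilocus cells and sum their scores."""
    s = _as_scores(scores)
    idx = np.arange(dataset.n_subjects) if subject_subset is None else np.asarray(subject_subset)
    if idx.size == 0:
        raise ValueError("empty subject subset")
    if any(j < 0 or j >= dataset.n_markers for j in combo):
        raise IndexError(f"combination {combo} outside 0..{dataset.n_markers - 1}")
    cells: dict[tuple[int, ...], list] = {}
    g = dataset.genotypes[np.ix_(idx, list(combo))]
    y = dataset.phenotype[idx]
    si = s[idx]
    for row, yi, sc in zip(g, y, si):
        key = tuple(int(v) for v in row)
        acc = cells.setdefault(key, [0.0, 0.0, 0.0, 0, 0])
        acc[0] += sc
        if sc > 0:
            acc[1] += sc
        elif sc < 0:
            acc[2] -= sc
        if yi == 1:
            acc[3] += 1
        else:
            acc[4] += 1
    return CellTable(
        combo=tuple(combo),
        cells={k: CellStats(v[0], v[1], v[2], v[3], v[4]) for k, v in cells.items()},
    )


def label_cells(table: CellTable, T: float = 0.0) -> RiskLabeling:
    """High-risk iff the cell's average score is not less than T (ties high)."""
    if not table.cells:
        raise ValueError("cannot label an empty cell table")
    labels = {
        k: ("high" if c.score_sum / c.count >= T else "low") for k, c in table.cells.items()
    }
    return RiskLabeling(labels=labels, threshold_T=T)


def confusion(table: CellTable, labeling: RiskLabeling) -> ConfusionSummary:
    """Score-mass confusion of a labeling applied to a (possibly new) table.

    Cells absent from the labeling (unseen in training) are treated as
    low-risk, contributing to FN/TN.
    """
    tp = tn = fp = fn = 0.0
    for k, c in table.cells.items():
        if labeling.labels.get(k, "low") == "high":
            tp += c.pos_mass
            fp += c.neg_mass
        else:
            fn += c.pos_mass
            tn += c.neg_mass
    return ConfusionSummary(TP=tp, TN=tn, FP=fp, FN=fn)


def search_best_model(
    scores: ScoreVector | np.ndarray,
    dataset: GenotypeDataset,
    k: int,
    T: float = 0.0,
    subject_subset: np.ndarray | None = None,
) -> tuple[FactorCombination, float]:
    """Exhaustive scan of all C(m, k) combinations; returns the one with the
    highest training classification accuracy (ties: lexicographically first).
    """
    if k > dataset.n_markers:
        raise ValueError(f"order {k} exceeds {dataset.n_markers} markers")
    best: tuple[FactorCombination, float] | None = None
    for combo in combinations(range(dataset.n_markers), k):
        table = tabulate_cells(scores, dataset, combo, subject_subset)
        acc = confusion(table, label_cells(table, T)).accuracy
        if best is None or acc > best[1]:
            best = (combo, acc)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Vectorized search used by cross_validate and the power pipeline. Cell
# indices per combination are precomputed once per dataset so that permutation
# replicates only pay for weighted bincounts.
# ---------------------------------------------------------------------------


class InteractionSearch:
    """Precomputed exhaustive-search structure over one genotype matrix."""

    def __init__(self, genotypes: np.ndarray, orders: Sequence[int]):
        genotypes = np.asarray(genotypes)
        m = genotypes.shape[1]
        self.orders = list(orders)
        self.combos: dict[int, list[FactorCombination]] = {}
        self.cell_idx: dict[int, np.ndarray] = {}
        self.n_cells: dict[int, int] = {}
        for k in self.orders:
            combos = list(combinations(range(m), k))
            pow3 = 3 ** np.arange(k)
            ci = np.empty((genotypes.shape[0], len(combos)), dtype=np.int64)
            for c, combo in enumerate(combos):
                ci[:, c] = genotypes[:, list(combo)] @ pow3
            self.combos[k] = combos
            self.cell_idx[k] = ci
            self.n_cells[k] = 3**k

    def fold_best(
        self,
        scores: np.ndarray,
        train_idx: np.ndarray,
        test_idx: np.ndarray,
        k: int,
        T: float = 0.0,
    ) -> tuple[int, float, float]:
        """Best combination on the training subset and its TA on the test subset.

        Returns (combo position, training accuracy, testing accuracy).
        """
        ci = self.cell_idx[k]
        nc = self.n_cells[k]
        ncombo = ci.shape[1]
        pos = np.where(scores > 0, scores, 0.0)
        neg = np.where(scores < 0, -scores, 0.0)
        cit = ci[train_idx]
        flat = (cit + np.arange(ncombo, dtype=np.int64) * nc).ravel()
        shape = (len(train_idx), ncombo)
        posc = np.bincount(
            flat, weights=np.broadcast_to(pos[train_idx][:, None], shape).ravel(),
            minlength=ncombo * nc,
        ).reshape(ncombo, nc)
        negc = np.bincount(
            flat, weights=np.broadcast_to(neg[train_idx][:, None], shape).ravel(),
            minlength=ncombo * nc,
        ).reshape(ncombo, nc)
        cnt = np.bincount(flat, minlength=ncombo * nc).reshape(ncombo, nc)
        # high-risk iff mean score >= T on non-empty cells
        high = ((posc - negc) >= T * cnt) & (cnt > 0)
        total = posc[0].sum() + negc[0].sum()
        train_acc = np.where(high, posc, negc).sum(axis=1) / total
        best = int(np.argmax(train_acc))  # first max = lexicographically smallest
        # testing accuracy of the winner under the training labeling
        cib = ci[test_idx, best]
        post = np.bincount(cib, weights=pos[test_idx], minlength=nc)
        negt = np.bincount(cib, weights=neg[test_idx], minlength=nc)
        hb = high[best]
        ta = (post[hb].sum() + negt[~hb].sum()) / (post.sum() + negt.sum())
        return best, float(train_acc[best]), float(ta)


def _summarize_order(
    k: int, winners: list[FactorCombination], tas: list[float]
) -> OrderResult:
    counts: dict[FactorCombination, int] = {}
    for w in winners:
        counts[w] = counts.get(w, 0) + 1
    cvc = max(counts.values())
    tied = [w for w, c in counts.items() if c == cvc]
    if len(tied) > 1:
        # tie: highest mean TA over the folds each candidate won, then lexicographic
        def key(w: FactorCombination):
            won = [ta for ww, ta in zip(winners, tas) if ww == w]
            return (-float(np.mean(won)), w)

        tied.sort(key=key)
    final = tied[0]
    return OrderResult(
        order=k,
        fold_winners=winners,
        fold_tas=tas,
        mean_ta=float(np.mean(tas)),
        cvc=cvc,
        final_model=final,
    )


def cross_validate(
    dataset: GenotypeDataset,
    orders: Sequence[int],
    folds: int = 10,
    T: float = 0.0,
    adjust: bool = True,
    seed: int = 0,
    search: InteractionSearch | None = None,
    partition: list[tuple[np.ndarray, np.ndarray]] | None = None,
    scores: np.ndarray | None = None,
) -> ModelSearchResult:
    """Run the full cross-validated search over the given interaction orders.

    ``search``, ``partition`` and ``scores`` may be supplied to reuse
    precomputed state (the permutation pipeline does); otherwise they are
    built from the dataset and seed.
    """
    if not orders:
        raise ValueError("orders must be nonempty")
    if scores is None:
        fit = fit_null_model(dataset, adjust=adjust and dataset.n_covariates > 0)
        scores = residual_scores(fit, dataset).scores
    if partition is None:
        partition = partition_cv(dataset.n_subjects, folds, dataset.phenotype, seed)
    if search is None:
        search = InteractionSearch(dataset.genotypes, orders)

    per_order: dict[int, OrderResult] = {}
    for k in orders:
        winners, tas = [], []
        for train_idx, test_idx in partition:
            b, _, ta = search.fold_best(scores, train_idx, test_idx, k, T)
            winners.append(search.combos[k][b])
            tas.append(ta)
        per_order[k] = _summarize_order(k, winners, tas)

    ks = sorted(per_order)
    best_ta_k = min(ks, key=lambda k: (-per_order[k].mean_ta, k))
    best_cvc_k = min(ks, key=lambda k: (-per_order[k].cvc, k))
    # parsimony: when mean TA and CVC point to different orders, keep the simpler
    selected = best_ta_k if best_ta_k == best_cvc_k else min(best_ta_k, best_cvc_k)
    return ModelSearchResult(per_order=per_order, selected_order=selected)
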