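"""Engine tests, including an independent count-based MDR oracle.

The oracle re-implements classic MDR from scratch on case/control counts
(no scores): a cell is high-risk when cases >= controls, and accuracy is
count-based. For balanced designs without covariates the score-based engine
must agree exactly (scores are +/-0.5, so every mass is a count scaled by 0.5).
"""

from itertools import combinations

import numpy as np
import pytest

from gmdrpower.data_io import GenotypeDataset, ScenarioSpec
from gmdrpower.mdr_engine import (
    InteractionSearch,
    confusion,
    cross_validate,
    label_cells,
    partition_cv,
    search_best_model,
    tabulate_cells,
)
from gmdrpower.scoring import fit_null_model, residual_scores
from gmdrpower.simulator import simulate_case_control


def _balanced_dataset(rng, n=200, m=4):
    n2 = n // 2
    return GenotypeDataset(
        subject_ids=[f"s{i}" for i in range(n)],
        phenotype=np.array([1] * n2 + [0] * n2),
        covariates=np.empty((n, 0)),
        genotypes=rng.integers(0, 3, size=(n, m)).astype(np.int8),
        marker_names=[f"M{j}" for j in range(m)],
    )


def _scores(ds):
    return residual_scores(fit_null_model(ds, adjust=False), ds).scores


# ------------------------------------------------------------------ oracle
def count_mdr_best(ds, k, subset=None):
    """Brute-force count-MDR: best k-marker combo by count accuracy."""
    idx = np.arange(ds.n_subjects) if subset is None else subset
    best = None
    for combo in combinations(range(ds.n_markers), k):
        cells = {}
        for i in idx:
            key = tuple(ds.genotypes[i, list(combo)])
            ca, co = cells.get(key, (0, 0))
            if ds.phenotype[i] == 1:
                cells[key] = (ca + 1, co)
            else:
                cells[key] = (ca, co + 1)
        correct = sum(ca if ca >= co else co for ca, co in cells.values())
        acc = correct / len(idx)
        if best is None or acc > best[1]:
            best = (combo, acc)
    return best


# ------------------------------------------------------------- partitions
def test_partition_stratified_balanced():
    phen = np.array([1] * 50 + [0] * 50)
    parts = partition_cv(100, 10, phen, seed=0)
    tests = [t for _, t in parts]
    assert sorted(np.concatenate(tests)) == list(range(100))
    for tr, te in parts:
        assert len(te) == 10
        assert phen[te].sum() == 5
        assert set(tr) | set(te) == set(range(100))
        assert not set(tr) & set(te)


def test_partition_seed_determinism():
    phen = np.array([1, 0] * 50)
    a = partition_cv(100, 10, phen, seed=5)
    b = partition_cv(100, 10, phen, seed=5)
    c = partition_cv(100, 10, phen, seed=6)
    assert all(np.array_equal(x[1], y[1]) for x, y in zip(a, b))
    assert any(not np.array_equal(x[1], y[1]) for x, y in zip(a, c))


def test_partition_errors():
    with pytest.raises(ValueError):
        partition_cv(5, 10, np.array([1, 0, 1, 0, 1]), seed=0)


# ------------------------------------------------------------ cell tables
def test_single_cell_table(toy_dataset):
    ds = toy_dataset
    ds.genotypes[:] = 0
    t = tabulate_cells(_scores(ds), ds, (0, 1))
    assert list(t.cells) == [(0, 0)]
    c = t.cells[(0, 0)]
    assert c.n_case == 2 and c.n_control == 2
    assert c.score_sum == pytest.approx(0.0)


def test_cell_score_sum_three_cases_one_control():
    ds = GenotypeDataset(
        subject_ids=list("abcdefgh"),
        phenotype=np.array([1, 1, 1, 0, 1, 0, 0, 0]),
        covariates=np.empty((8, 0)),
        genotypes=np.array([[0], [0], [0], [0], [1], [1], [1], [1]]),
        marker_names=["M1"],
    )
    t = tabulate_cells(_scores(ds), ds, (0,))
    assert t.cells[(0,)].score_sum == pytest.approx(3 * 0.5 - 0.5)  # = 1.0
    assert t.cells[(0,)].pos_mass == pytest.approx(1.5)
    total_cases = sum(c.n_case for c in t.cells.values())
    assert total_cases == 4


def test_label_tie_goes_high(toy_dataset):
    t = tabulate_cells(np.array([0.5, -0.5, -0.5, 0.5]), toy_dataset, (0,))
    lab = label_cells(t, T=0.0)
    # both cells sum to zero -> boundary inclusive -> high
    assert all(v == "high" for v in lab.labels.values())


def test_all_negative_cells_low():
    ds = GenotypeDataset(
        subject_ids=["a", "b"],
        phenotype=np.array([1, 0]),
        covariates=np.empty((2, 0)),
        genotypes=np.array([[0], [1]]),
        marker_names=["M1"],
    )
    t = tabulate_cells(np.array([-0.1, -0.2]), ds, (0,))
    lab = label_cells(t, T=0.0)
    assert set(lab.labels.values()) == {"low"}


def test_confusion_arithmetic(toy_dataset):
    from gmdrpower.mdr_engine import ConfusionSummary

    c = ConfusionSummary(TP=30, TN=25, FP=10, FN=15)
    assert c.accuracy == pytest.approx(0.6875)
    assert c.sensitivity == pytest.approx(30 / 45)
    assert c.specificity == pytest.approx(25 / 35)
    assert c.balanced_accuracy == pytest.approx(0.5 * (30 / 45 + 25 / 35))


def test_unseen_cells_count_as_low(toy_dataset):
    s = _scores(toy_dataset)
    train = np.array([0, 2])
    test = np.array([1, 3])
    t_train = tabulate_cells(s, toy_dataset, (1,), train)
    lab = label_cells(t_train)
    t_test = tabulate_cells(s, toy_dataset, (1,), test)
    cm = confusion(t_test, lab)
    # subject 'd' has genotype 2 at marker 1, unseen in training -> low -> TN
    assert cm.TN >= 0.5


# ----------------------------------------------------------------- search
def test_combination_count_is_exhaustive():
    rng = np.random.default_rng(0)
    ds = _balanced_dataset(rng, n=60, m=10)
    search = InteractionSearch(ds.genotypes, [2])
    assert len(search.combos[2]) == 45


def test_single_marker_search():
    rng = np.random.default_rng(1)
    ds = _balanced_dataset(rng, n=40, m=1)
    combo, _ = search_best_model(_scores(ds), ds, 1)
    assert combo == (0,)


def test_count_mdr_equivalence_oracle():
    """Balanced, no covariates: score engine == independent count-MDR."""
    for seed in range(5):
        rng = np.random.default_rng(seed)
        ds = _balanced_dataset(rng, n=150 + 2 * seed, m=5)
        s = _scores(ds)
        for k in (1, 2):
            combo, acc = search_best_model(s, ds, k)
            o_combo, o_acc = count_mdr_best(ds, k)
            assert combo == o_combo
            assert acc == pytest.approx(o_acc)
            # score-mass confusion equals 0.5 * count confusion
            t = tabulate_cells(s, ds, combo)
            cm = confusion(t, label_cells(t))
            assert cm.TP + cm.TN == pytest.approx(0.5 * o_acc * ds.n_subjects)


def test_fast_path_matches_reference():
    """Vectorized fold search agrees with the op-by-op composition."""
    rng = np.random.default_rng(42)
    ds = _balanced_dataset(rng, n=120, m=5)
    s = _scores(ds)
    search = InteractionSearch(ds.genotypes, [2])
    parts = partition_cv(ds.n_subjects, 5, ds.phenotype, seed=9)
    for train, test in parts:
        b, train_acc, ta = search.fold_best(s, train, test, 2)
        ref_combo, ref_acc = search_best_model(s, ds, 2, subject_subset=train)
        assert search.combos[2][b] == ref_combo
        assert train_acc == pytest.approx(ref_acc)
        t_train = tabulate_cells(s, ds, ref_combo, train)
        lab = label_cells(t_train)
        t_test = tabulate_cells(s, ds, ref_combo, test)
        assert ta == pytest.approx(confusion(t_test, lab).accuracy)


def test_mass_conservation():
    rng = np.random.default_rng(11)
    ds = _balanced_dataset(rng, n=100, m=3)
    s = rng.normal(0, 1, 100)
    t = tabulate_cells(s, ds, (0, 2))
    cm = confusion(t, label_cells(t))
    assert cm.TP + cm.TN + cm.FP + cm.FN == pytest.approx(np.abs(s).sum())


def test_accuracy_invariant_to_marker_order_in_combo():
    rng = np.random.default_rng(13)
    ds = _balanced_dataset(rng, n=80, m=3)
    s = _scores(ds)
    t1 = tabulate_cells(s, ds, (0, 2))
    ds_swapped = GenotypeDataset(
        subject_ids=ds.subject_ids,
        phenotype=ds.phenotype,
        covariates=ds.covariates,
        genotypes=ds.genotypes[:, [2, 1, 0]],
        marker_names=["M2", "M1", "M0"],
    )
    t2 = tabulate_cells(s, ds_swapped, (0, 2))
    a1 = confusion(t1, label_cells(t1)).accuracy
    a2 = confusion(t2, label_cells(t2)).accuracy
    assert a1 == pytest.approx(a2)


# --------------------------------------------------------- cross-validate
def test_cross_validate_determinism(fig1_dataset):
    ds = fig1_dataset.dataset
    r1 = cross_validate(ds, orders=[2], seed=4)
    r2 = cross_validate(ds, orders=[2], seed=4)
    assert r1.final_model == r2.final_model
    assert r1.per_order[2].fold_tas == r2.per_order[2].fold_tas


def test_training_accuracy_at_least_half():
    rng = np.random.default_rng(21)
    ds = _balanced_dataset(rng, n=100, m=4)
    s = _scores(ds)
    search = InteractionSearch(ds.genotypes, [2])
    parts = partition_cv(100, 5, ds.phenotype, seed=2)
    for train, test in parts:
        _, train_acc, _ = search.fold_best(s, train, test, 2)
        assert train_acc >= 0.5


def test_cvc_definition():
    from gmdrpower.mdr_engine import _summarize_order

    winners = [(0, 1)] * 8 + [(0, 2)] * 2
    tas = [0.6] * 10
    o = _summarize_order(2, winners, tas)
    assert o.cvc == 8
    assert o.final_model == (0, 1)


def test_planted_signal_recovered(calibrated_sd):
    """Strong two-locus interaction is found by the exhaustive CV search."""
    hits = 0
    for seed in range(5):
        spec = ScenarioSpec(
            "checkerboard", maf=0.5, beta_g=2.5, covariate_sd=calibrated_sd,
            n_total=2000, seed=100 + seed,
        )
        sim = simulate_case_control(spec)
        res = cross_validate(sim.dataset, orders=[2], seed=seed)
        hits += res.final_model == sim.functional_indices
    assert hits == 5
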