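"""Tests of partitioning, bootstrap orchestration, filtering, retention and t-tests."""

import math

import numpy as np
import pytest
from scipy import stats

from glvnet import (
    ActiveSet,
    CandidateModel,
    GLVParameters,
    ModelEnsemble,
    aggregate_and_test,
    filter_models,
    generate,
    partition,
    preset_two_taxon,
    run_bagging,
    select_best,
)
from glvnet.bagging import _one_sample_t


def _series(T=20, n=2, seed=0):
    spec = preset_two_taxon(sigma=0.05, n_times=T, seed=seed)
    return generate(spec)[0]


def _candidate(taxa, bic, A=None, select=(), bootstrap_id=0, r=None, K=1e11):
    n = len(taxa)
    params = GLVParameters(
        taxa,
        np.full(n, 0.5) if r is None else np.asarray(r, float),
        np.zeros((n, n)) if A is None else np.asarray(A, float),
        K,
    )
    return CandidateModel(
        select_set=ActiveSet(frozenset(select)),
        params=params,
        rss_full=1.0,
        bic_full=bic,
        U=20,
        V=n + len(select),
        train_indices=(0, 1),
        bootstrap_id=bootstrap_id,
    )


class TestPartition:
    def test_eighty_percent_of_twenty_is_sixteen(self):
        series = _series(T=20)
        train, test, idx = partition(series, 0.8, np.random.default_rng(0))
        assert train.n_times == 16
        assert test.n_times == 4

    def test_first_time_point_always_included(self):
        series = _series(T=12)
        for s in range(20):
            train, _, idx = partition(series, 0.5, np.random.default_rng(s))
            assert idx[0] == 0
            assert train.times[0] == series.times[0]

    def test_full_fraction_keeps_everything(self):
        series = _series(T=10)
        train, test, idx = partition(series, 1.0, np.random.default_rng(0))
        assert train.n_times == 10
        assert test is None

    def test_same_seed_same_partition(self):
        series = _series(T=15)
        _, _, a = partition(series, 0.8, np.random.default_rng(42))
        _, _, b = partition(series, 0.8, np.random.default_rng(42))
        _, _, c = partition(series, 0.8, np.random.default_rng(43))
        assert a == b
        assert a != c

    def test_train_in_temporal_order_and_disjoint(self):
        series = _series(T=15)
        train, test, idx = partition(series, 0.6, np.random.default_rng(1))
        assert np.all(np.diff(train.times) > 0)
        assert set(train.times).isdisjoint(test.times)
        assert len(set(train.times) | set(test.times)) == 15

    def test_too_few_points_rejected(self):
        series = _series(T=20).subset([0, 1])
        with pytest.raises(ValueError):
            partition(series, 0.8, np.random.default_rng(0))


class TestRunBagging:
    def test_single_bootstrap(self, config):
        series = _series()
        ens = run_bagging(series, config, n_bootstraps=1)
        assert ens.n_requested == 1
        assert len(ens) + ens.n_failed == 1

    def test_fixed_master_seed_reproducible(self, config):
        series = _series()
        a = run_bagging(series, config, n_bootstraps=4)
        b = run_bagging(series, config, n_bootstraps=4)
        assert [m.select_set for m in a.models] == [m.select_set for m in b.models]
        for ma, mb in zip(a.models, b.models):
            np.testing.assert_array_equal(ma.params.A, mb.params.A)
            np.testing.assert_array_equal(ma.params.r, mb.params.r)

    def test_thread_count_does_not_change_results(self, config):
        series = _series()
        a = run_bagging(series, config, n_bootstraps=4, threads=1)
        b = run_bagging(series, config, n_bootstraps=4, threads=3)
        for ma, mb in zip(a.models, b.models):
            assert ma.select_set == mb.select_set
            np.testing.assert_array_equal(ma.params.A, mb.params.A)

    def test_true_interaction_selected_more_often_than_false(self, config):
        from glvnet import preset_three_taxon

        series, _ = generate(preset_three_taxon(seed=2))
        ens = run_bagging(series, config, n_bootstraps=20)
        freq_true = np.mean([(0, 1) in m.select_set for m in ens.models])
        freq_false = np.mean([(1, 2) in m.select_set for m in ens.models])
        assert freq_true > freq_false


class TestFilterModels:
    def test_zero_constraints_identity(self, config, simple_series):
        ens = ModelEnsemble(models=(_candidate(("A", "B"), -10.0),), n_requested=1)
        out = filter_models(ens, config, simple_series)
        assert out is ens

    def test_extinction_violating_model_removed(self, config):
        series = _series()
        # strong mutual inhibition drives taxon 2 to extinction quickly
        bad = _candidate(
            ("T1", "T2"), -5.0, A=[[0.0, 0.0], [-30.0, 0.0]], r=[1.0, 0.1]
        )
        good = _candidate(("T1", "T2"), -4.0, r=[0.5, 0.5])
        ens = ModelEnsemble(models=(bad, good), n_requested=2)
        cfg = config.replace(min_species_abundance=1e6)
        out = filter_models(ens, cfg, series)
        assert len(out) == 1
        assert out.models[0] is good
        assert len(out.filter_log) == 1
        assert "below min abundance" in out.filter_log[0][1]

    def test_idempotent(self, config):
        series = _series()
        bad = _candidate(("T1", "T2"), -5.0, A=[[0.0, 0.0], [-30.0, 0.0]], r=[1.0, 0.1])
        good = _candidate(("T1", "T2"), -4.0, r=[0.5, 0.5])
        ens = ModelEnsemble(models=(bad, good), n_requested=2)
        cfg = config.replace(min_species_abundance=1e6)
        once = filter_models(ens, cfg, series)
        twice = filter_models(once, cfg, series)
        assert twice.models == once.models


class TestSelectBest:
    def test_hand_example_negative_bics(self):
        taxa = ("A", "B")
        ens = ModelEnsemble(
            models=tuple(_candidate(taxa, b) for b in (-100.0, -95.0, -50.0)),
            n_requested=3,
        )
        kept = select_best(ens, allowance=0.10)
        assert sorted(m.bic_full for m in kept.models) == [-100.0, -95.0]

    def test_all_equal_bics_all_kept(self):
        taxa = ("A", "B")
        ens = ModelEnsemble(
            models=tuple(_candidate(taxa, -42.0) for _ in range(5)), n_requested=5
        )
        assert len(select_best(ens, 0.10)) == 5

    def test_zero_allowance_keeps_only_minimum(self):
        taxa = ("A", "B")
        ens = ModelEnsemble(
            models=tuple(_candidate(taxa, b) for b in (-100.0, -99.999, -50.0)),
            n_requested=3,
        )
        kept = select_best(ens, allowance=0.0)
        assert [m.bic_full for m in kept.models] == [-100.0]

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError, match="no models"):
            select_best(ModelEnsemble(models=(), n_requested=5), 0.1)


class TestAggregateAndTest:
    def test_textbook_t_test(self):
        sample = np.array([0.5, 0.6, 0.4, 0.0, 0.5])
        t, p = _one_sample_t(sample)
        t_ref, p_ref = stats.ttest_1samp(sample, 0.0)
        assert t == pytest.approx(float(t_ref), rel=1e-12)
        assert p == pytest.approx(float(p_ref), rel=1e-12)
        # and the explicit formula
        assert t == pytest.approx(
            sample.mean() / (sample.std(ddof=1) / math.sqrt(5)), rel=1e-12
        )

    def test_never_selected_pair_not_significant(self):
        taxa = ("A", "B")
        ens = ModelEnsemble(
            models=tuple(_candidate(taxa, -10.0) for _ in range(4)), n_requested=4
        )
        coefs, growth = aggregate_and_test(ens, 0.95)
        assert all(not c.significant for c in coefs)
        assert all(c.p_value == 1.0 for c in coefs)

    def test_constant_nonzero_sample_significant(self):
        taxa = ("A", "B")
        models = tuple(
            _candidate(taxa, -10.0, A=[[0.0, 0.7], [0.0, 0.0]], select=[(0, 1)])
            for _ in range(3)
        )
        ens = ModelEnsemble(models=models, n_requested=3)
        coefs, _ = aggregate_and_test(ens, 0.95)
        c01 = next(c for c in coefs if c.pair == (0, 1))
        assert c01.significant and c01.p_value == 0.0
        assert c01.mean == pytest.approx(0.7)
        assert c01.selection_frequency == 1.0

    def test_zeros_included_by_default_but_excludable(self):
        taxa = ("A", "B")
        vals = [0.5, 0.6, 0.0, 0.0]
        models = tuple(
            _candidate(
                taxa,
                -10.0,
                A=[[0.0, v], [0.0, 0.0]],
                select=[(0, 1)] if v != 0 else [],
                bootstrap_id=i,
            )
            for i, v in enumerate(vals)
        )
        ens = ModelEnsemble(models=models, n_requested=4)
        with_zeros, _ = aggregate_and_test(ens, 0.95, include_unselected_zeros=True)
        without, _ = aggregate_and_test(ens, 0.95, include_unselected_zeros=False)
        c_w = next(c for c in with_zeros if c.pair == (0, 1))
        c_wo = next(c for c in without if c.pair == (0, 1))
        assert c_w.mean == pytest.approx(np.mean(vals))
        assert c_wo.mean == pytest.approx(0.55)
        assert c_w.selection_frequency == c_wo.selection_frequency == 0.5

    def test_growth_rates_mean_and_se(self):
        taxa = ("A", "B")
        rs = [[0.4, 1.0], [0.6, 1.2]]
        models = tuple(_candidate(taxa, -10.0, r=r) for r in rs)
        ens = ModelEnsemble(models=models, n_requested=2)
        _, growth = aggregate_and_test(ens, 0.95)
        assert growth["A"][0] == pytest.approx(0.5)
        assert growth["A"][1] == pytest.approx(np.std([0.4, 0.6], ddof=1) / math.sqrt(2))

    def test_raising_confidence_never_adds_edges(self):
        rng = np.random.default_rng(0)
        taxa = ("A", "B", "C")
        models = []
        for i in range(12):
            A = np.zeros((3, 3))
            sel = []
            if rng.random() < 0.7:
                A[0, 1] = 0.5 + 0.05 * rng.normal()
                sel.append((0, 1))
            if rng.random() < 0.3:
                A[2, 0] = rng.normal() * 0.2
                sel.append((2, 0))
            models.append(_candidate(taxa, -10.0, A=A, select=sel, bootstrap_id=i))
        ens = ModelEnsemble(models=tuple(models), n_requested=12)
        sig95 = {c.pair for c in aggregate_and_test(ens, 0.95)[0] if c.significant}
        sig99 = {c.pair for c in aggregate_and_test(ens, 0.99)[0] if c.significant}
        assert sig99 <= sig95

    def test_single_model_flagged_undefined(self):
        taxa = ("A", "B")
        ens = ModelEnsemble(
            models=(_candidate(taxa, -10.0, A=[[0, 0.5], [0, 0]], select=[(0, 1)]),),
            n_requested=1,
        )
        coefs, _ = aggregate_and_test(ens, 0.95)
        c01 = next(c for c in coefs if c.pair == (0, 1))
        assert math.isnan(c01.p_value)
        assert not c01.significant
        assert c01.mean == pytest.approx(0.5)
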