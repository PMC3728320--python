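import math

import numpy as np
import pytest

from plastid_delim import gmyc
from plastid_delim.errors import NumericalError, TreeError
from plastid_delim.gmyc import (
    GMYCFit,
    GMYCParams,
    aicc,
    branching_intervals,
    candidate_single_threshold_fits,
    entities_at_probability,
    entity_confidence_interval,
    fit_multiple_threshold,
    fit_null,
    fit_single_threshold,
    loglik,
    lr_test,
    ltt,
    multimodel_average,
)
from plastid_delim.io_formats import read_tree
from plastid_delim.synthetic_data import recovery_fixture, simulate_yule

from oracles import gmyc_grid_loglik


def scale_tree(tree, c):
    t = tree.copy()
    for n in t.root.preorder():
        n.age *= c
    return t


class TestBranchingIntervals:
    def test_hand_example(self, balanced_tree):
        tab = branching_intervals(balanced_tree)
        assert tab.ages.tolist() == [2.0, 1.0]
        assert tab.x.tolist() == [1.0, 1.0]
        assert tab.lineages.tolist() == [2, 3]
        assert tab.x.sum() == pytest.approx(balanced_tree.root_age)

    def test_n_minus_one_ages(self):
        t = simulate_yule(12, 1.0, seed=3)
        assert len(branching_intervals(t).ages) == 11

    def test_ladder_tree_unit_intervals(self):
        t = read_tree(None, data="(((a:1,b:1):1,c:2):1,d:3);")
        assert branching_intervals(t).x.tolist() == [1.0, 1.0, 1.0]

    def test_too_few_tips(self):
        t = read_tree(None, data="(a:1,b:1);")
        with pytest.raises(TreeError, match="3 tips"):
            branching_intervals(t)

    def test_tied_ages_perturbed(self):
        t = read_tree(None, data="((a:1,b:1):1,(c:1,d:1):1);")
        tab = branching_intervals(t)
        assert tab.perturbed
        assert len(set(tab.ages.tolist())) == 3


class TestLoglik:
    def test_all_coalescent_hand_sum(self, balanced_tree):
        p = GMYCParams(0.0, 0.5, 1.0, 1.0)
        expect = (math.log(1.0) - 1.0) + (math.log(3.0) - 3.0)
        assert loglik(balanced_tree, p) == pytest.approx(expect)

    def test_zero_rate_gives_minus_inf_not_raise(self, balanced_tree):
        p = GMYCParams(0.0, 0.0, 1.0, 1.0)
        assert loglik(balanced_tree, p) == -math.inf

    def test_time_rescaling_shifts_loglik_by_events_log_c(self):
        t = simulate_yule(8, 1.0, seed=1)
        p = GMYCParams(0.0, 0.7, 1.0, 1.3)
        base = loglik(t, p)
        c = 3.7
        p_scaled = GMYCParams(0.0, 0.7 / c, 1.0, 1.3)
        n_events = t.n_tips - 1
        assert loglik(scale_tree(t, c), p_scaled) == pytest.approx(
            base - n_events * math.log(c)
        )

    def test_exponent_convention_switch(self, balanced_tree):
        # default: exponent on n(n-1); alternative: n * (n-1)^p2.  They
        # agree at p2 = 1 and differ otherwise.
        p = GMYCParams(0.0, 0.5, 1.0, 1.0)
        p_frac = GMYCParams(0.0, 0.5, 1.0, 0.5)
        base = loglik(balanced_tree, p)
        base_frac = loglik(balanced_tree, p_frac)
        try:
            gmyc.EXPONENT_ON_PRODUCT = False
            assert loglik(balanced_tree, p) == pytest.approx(base)
            assert loglik(balanced_tree, p_frac) != pytest.approx(base_frac)
        finally:
            gmyc.EXPONENT_ON_PRODUCT = True

    def test_threshold_changes_assignment_and_likelihood(self):
        # the two processes see different lineage-count functions, so the
        # likelihood genuinely depends on where the threshold is placed
        t = simulate_yule(7, 1.0, seed=2)
        p = GMYCParams(0.8, 0.8, 1.0, 1.0)
        vals = {
            round(loglik(t, p, coalescent_ages_below=T), 9)
            for T in [0.0, t.root_age / 2, math.inf]
        }
        assert len(vals) > 1
        assert all(math.isfinite(v) for v in vals)


class TestFitNull:
    def test_two_tip_closed_form(self):
        t = read_tree(None, data="(a:1,b:1);")
        f = fit_null(t, fix_p=1.0)
        assert f.params.lambda2 == pytest.approx(0.5, rel=1e-4)
        assert f.logL == pytest.approx(-1.0, abs=1e-6)
        assert f.k == 2 and f.entities == 1

    def test_rate_scales_inversely_with_depth(self):
        t = simulate_yule(10, 1.0, seed=4)
        f1 = fit_null(t, n_starts=4)
        f2 = fit_null(scale_tree(t, 10.0), n_starts=4)
        assert f2.params.lambda2 == pytest.approx(f1.params.lambda2 / 10.0, rel=1e-2)


class TestNestingAndOracle:
    def test_nesting_inequality_on_random_trees(self):
        for seed in range(6):
            _, gt, _ = recovery_fixture(S=4, samples_per_species=2, seed=seed)
            null = fit_null(gt, n_starts=3)
            single = fit_single_threshold(gt, n_starts=3)
            multiple = fit_multiple_threshold(gt, seed=seed, start=single)
            assert null.logL <= single.logL + 1e-9
            assert single.logL <= multiple.logL + 1e-9

    def test_optimizer_beats_exhaustive_grid(self):
        for seed in (0, 1):
            t = simulate_yule(7, 1.0, seed=seed)
            single = fit_single_threshold(t, n_starts=6)
            null = fit_null(t, n_starts=6)
            opt = max(single.logL, null.logL)
            grid = gmyc_grid_loglik(t)
            assert opt >= grid - 0.05

    def test_multiple_threshold_fixed_point_keeps_loglik(self):
        _, gt, _ = recovery_fixture(S=5, samples_per_species=3, seed=11)
        single = fit_single_threshold(gt, n_starts=4)
        mult = fit_multiple_threshold(gt, seed=0, start=single)
        assert mult.logL >= single.logL - 1e-9
        if mult.coalescent_nodes == single.coalescent_nodes:
            assert mult.logL == pytest.approx(single.logL, abs=1e-6)

    def test_multiple_threshold_deterministic_given_seed(self):
        _, gt, _ = recovery_fixture(S=4, samples_per_species=3, seed=2)
        single = fit_single_threshold(gt, n_starts=3)
        a = fit_multiple_threshold(gt, seed=5, start=single)
        b = fit_multiple_threshold(gt, seed=5, start=single)
        assert a.logL == b.logL
        assert a.coalescent_nodes == b.coalescent_nodes


class TestEntities:
    def test_entity_bounds_and_extremes(self):
        t = simulate_yule(9, 1.0, seed=6)
        data = gmyc._TreeData(t)
        cl, si = data.decompose(data.threshold_assignment(0.0))
        assert cl == [] and len(si) == 9  # threshold below every node
        cl, si = data.decompose(data.threshold_assignment(math.inf))
        assert len(cl) == 1 and si == []  # threshold above the root
        f = fit_single_threshold(t, n_starts=3)
        assert 1 <= f.entities <= t.n_tips

    def test_clusters_and_singletons_partition_tips(self):
        _, gt, _ = recovery_fixture(S=5, samples_per_species=3, seed=9)
        f = fit_single_threshold(gt, n_starts=3)
        members = [m for c in f.clusters for m in c] + f.singletons
        assert sorted(members) == sorted(gt.tip_labels())
        assert all(len(c) >= 2 for c in f.clusters)


class TestLRTest:
    def test_printed_p_values(self):
        assert lr_test(0.0, 3.17 / 2)[1] == pytest.approx(0.205, abs=0.005)
        assert lr_test(0.0, 10.08 / 2)[1] == pytest.approx(0.0065, abs=0.0005)

    def test_zero_ratio_p_one(self):
        assert lr_test(5.0, 5.0) == (0.0, 1.0)

    def test_negative_ratio_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            ratio, p = lr_test(5.0, 4.0)
        assert ratio == 0.0 and p == 1.0

    def test_bad_df(self):
        with pytest.raises(ValueError):
            lr_test(0.0, 1.0, df=0)


def fake_fit(tips, clusters, logL, k=5):
    clustered = {m for c in clusters for m in c}
    return GMYCFit(
        params=GMYCParams(1, 1, 1, 1, (1.0,)),
        logL=logL,
        k=k,
        clusters=[list(c) for c in clusters],
        singletons=[t for t in tips if t not in clustered],
        n_tips=len(tips),
        method="single",
    )


class TestMultimodel:
    tips20 = [f"t{i}" for i in range(20)]

    def test_equal_models_average_by_hand(self):
        f2 = fake_fit(self.tips20, [self.tips20[:10], self.tips20[10:]], -50.0)
        f4 = fake_fit(
            self.tips20,
            [self.tips20[i : i + 5] for i in range(0, 20, 5)],
            -50.0,
        )
        mm = multimodel_average([f2, f4], self.tips20, cutoff=7.0)
        assert mm.weights.tolist() == pytest.approx([0.5, 0.5])
        assert mm.mean_clusters == pytest.approx(3.0)
        assert mm.var_clusters == pytest.approx(1.0)

    def test_single_retained_model(self):
        good = fake_fit(self.tips20, [self.tips20[:10], self.tips20[10:]], -10.0)
        bad = fake_fit(self.tips20, [self.tips20], -500.0)
        mm = multimodel_average([good, bad], self.tips20, cutoff=7.0)
        assert len(mm.fits) == 1
        assert mm.mean_clusters == 2.0 and mm.var_clusters == 0.0
        assert mm.pair_probability("t0", "t1") == 1.0
        assert mm.pair_probability("t0", "t19") == 0.0

    def test_weights_sum_to_one_and_probs_in_unit_interval(self):
        rng = np.random.default_rng(8)
        _, gt, _ = recovery_fixture(S=4, samples_per_species=3, seed=21)
        null, singles = candidate_single_threshold_fits(gt, n_starts=3)
        mm = multimodel_average([null] + singles, gt.tip_labels())
        assert mm.weights.sum() == pytest.approx(1.0)
        assert (mm.pair_prob >= 0).all() and (mm.pair_prob <= 1 + 1e-12).all()

    def test_aicc_needs_enough_tips(self):
        with pytest.raises(NumericalError):
            aicc(-10.0, k=5, n=6)


class TestEntitiesAtProbability:
    def test_single_model_reproduces_its_decomposition(self):
        _, gt, _ = recovery_fixture(S=4, samples_per_species=3, seed=3)
        f = fit_single_threshold(gt, n_starts=3)
        mm = multimodel_average([f], gt.tip_labels())
        for thr in (1.0, 0.6, 0.2):
            clusters, singles = entities_at_probability(mm, gt, thr)
            assert len(clusters) + len(singles) == f.entities

    def test_entity_count_monotone_in_threshold(self):
        rng = np.random.default_rng(19)
        for rep in range(10):
            t = simulate_yule(10, 1.0, seed=100 + rep)
            data = gmyc._TreeData(t)
            fits = []
            for T in rng.choice(
                [n.age for n in t.internal_nodes()], size=4, replace=False
            ):
                cl, si = data.decompose(data.threshold_assignment(float(T)))
                fits.append(
                    fake_fit(t.tip_labels(), cl, float(-50 - rng.random() * 3))
                )
            mm = multimodel_average(fits, t.tip_labels(), cutoff=50.0)
            counts = []
            for thr in (1.0, 0.95, 0.8, 0.5, 0.2, 0.05):
                clusters, singles = entities_at_probability(mm, t, thr)
                counts.append(len(clusters) + len(singles))
            assert counts == sorted(counts, reverse=True)


class TestConfidenceInterval:
    def test_two_unit_support_set(self):
        tips = [f"t{i}" for i in range(20)]
        fits = [
            fake_fit(tips, [tips], -10.0),
            fake_fit(tips, [tips[:10], tips[10:]], -11.5),
            fake_fit(tips, [], -20.0),
        ]
        assert entity_confidence_interval(fits, delta=2.0) == (1, 2)


class TestLTT:
    def test_hand_example(self, balanced_tree):
        assert ltt(balanced_tree) == [(2.0, 2), (1.0, 3)]

    def test_final_count_is_tip_number(self):
        t = simulate_yule(15, 1.0, seed=5)
        steps = ltt(t)
        assert steps[-1][1] == 15

    def test_pure_birth_log_lineages_roughly_linear(self):
        rsq = []
        for seed in range(30):
            t = simulate_yule(40, 1.0, seed=seed)
            steps = ltt(t)
            times = np.array([t.root_age - a for a, _ in steps])
            logn = np.log([n for _, n in steps])
            r = np.corrcoef(times, logn)[0, 1]
            rsq.append(r * r)
        assert np.mean(rsq) > 0.9
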