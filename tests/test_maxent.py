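import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollmap import (
    GridSpec,
    auc_presence_background,
    build_features,
    cross_validate,
    fit_maxent,
    generate_landscape,
    generate_virtual_species,
    permutation_importance,
    sample_background,
    sample_occurrences,
)
from pollmap.maxent import (
    null_model_test,
    rank_correlation_bootstrap,
    single_predictor_gain_ranks,
    tgb_bias_test,
)
from pollmap.synthetic import make_effort


class TestFitMaxent:
    """Penalized Gibbs fit against closed-form solutions."""

    # two-cell universe: background features {0, 1}, presence mean f = 0.75
    Fp = np.array([[1.0], [1.0], [1.0], [0.0]])
    Fb = np.array([[0.0], [1.0]])

    def test_two_cell_closed_form(self):
        # solving e^l / (1 + e^l) = 0.75 gives l = ln 3
        m = fit_maxent(self.Fp, self.Fb, reg_beta=0.0)
        assert m.lam[0] == pytest.approx(np.log(3), abs=1e-3)
        q1 = np.exp(m.lam[0] - m.normalizer)
        assert q1 == pytest.approx(0.75, abs=1e-3)
        assert m.converged

    def test_no_signal_gives_uniform_q(self):
        rng = np.random.default_rng(0)
        F = rng.uniform(size=(50, 3))
        m = fit_maxent(F, F, reg_beta=0.0)
        assert np.all(np.abs(m.lam) < 1e-4)
        q = np.exp(F @ m.lam - m.normalizer)
        np.testing.assert_allclose(q, 1 / 50, atol=1e-6)
        assert m.entropy_H == pytest.approx(np.log(50), abs=1e-6)

    def test_l1_penalty_shrinks_weights_monotonically(self):
        lams = [
            abs(fit_maxent(self.Fp, self.Fb, reg_beta=beta).lam[0])
            for beta in (0.0, 0.05, 0.1, 0.2, 0.4)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(lams, lams[1:]))

    def test_gibbs_distribution_sums_to_one_over_background(self):
        rng = np.random.default_rng(1)
        Fb = rng.uniform(size=(80, 4))
        m = fit_maxent(rng.uniform(size=(30, 4)), Fb, reg_beta=0.01)
        q = np.exp(m.eta(Fb))
        assert q.sum() == pytest.approx(1.0, abs=1e-8)
        assert m.entropy_H >= 0

    def test_non_finite_features_rejected(self):
        bad = self.Fp.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_maxent(bad, self.Fb)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            fit_maxent(self.Fp, self.Fb, tau=0.0)


class TestLogisticOutput:
    @pytest.mark.parametrize("tau", [0.1, 0.2, 0.3, 0.4, 0.5])
    def test_typical_site_scores_tau(self, tau):
        m = fit_maxent(TestFitMaxent.Fp, TestFitMaxent.Fb, tau=tau)
        assert m.logistic_from_eta(-m.entropy_H) == pytest.approx(tau, abs=1e-9)

    def test_strictly_increasing_in_eta(self):
        m = fit_maxent(TestFitMaxent.Fp, TestFitMaxent.Fb, tau=0.3)
        etas = np.linspace(-5, 5, 51)
        p = m.logistic_from_eta(etas)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))


class TestBuildFeatures:
    def test_linear_class_preserves_ranking(self, landscape4, uniform_background):
        exp = build_features(landscape4, uniform_background.cells, classes=("linear",), n_presence=20)
        raw = landscape4.matrix(uniform_background.cells)
        F = exp.transform(raw)
        assert F.shape[1] == 4
        assert np.array_equal(np.argsort(F[:, 0]), np.argsort(raw[:, 0]))

    def test_hinge_gives_2k_columns_per_layer(self, landscape4, uniform_background):
        exp = build_features(
            landscape4, uniform_background.cells, classes=("hinge",), n_presence=20, n_hinge_knots=7
        )
        assert exp.n_columns == 4 * 2 * 7

    def test_columns_bounded_in_unit_interval(self, landscape4, uniform_background):
        exp = build_features(
            landscape4,
            uniform_background.cells,
            classes=("linear", "quadratic", "product", "threshold", "hinge"),
            n_presence=20,
            n_hinge_knots=5,
        )
        # transform values well outside the background range: still bounded
        F = exp.transform(np.full((3, 4), 100.0))
        assert np.all((F >= 0) & (F <= 1))

    def test_minimum_sample_size_enforced_at_12(self, landscape4, uniform_background):
        build_features(landscape4, uniform_background.cells, n_presence=12)  # accepted
        with pytest.raises(ValueError, match="11"):
            build_features(
                landscape4, uniform_background.cells, n_presence=11, species_id="Andrena parva"
            )


class TestSampleBackground:
    def test_pool_exhaustion_returns_whole_pool_with_warning(self):
        pool = GridSpec(10, 10).all_cells()
        with pytest.warns(UserWarning, match="whole pool"):
            bg = sample_background(pool, n=5000, seed=0)
        assert len(bg) == 100

    def test_origin_bookkeeping_and_determinism(self):
        pool = GridSpec(30, 30).all_cells()
        a = sample_background(pool, n=50, seed=4, origin="target-group")
        b = sample_background(pool, n=50, seed=4, origin="target-group")
        assert a.origin == "target-group"
        assert np.array_equal(a.cells, b.cells)
        assert len(np.unique(a.cells, axis=0)) == 50  # without replacement

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sample_background(np.empty((0, 2)), n=10)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_presence_background([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_identical_distributions(self):
        assert auc_presence_background([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_pairwise_counting_example(self):
        # 3 of 4 (presence, background) pairs correctly ordered
        assert auc_presence_background([0.8, 0.4], [0.6, 0.2]) == 0.75

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=20),
        st.lists(st.floats(-5, 5), min_size=2, max_size=20),
    )
    def test_invariant_under_strictly_monotone_transform(self, pres, bg):
        base = auc_presence_background(pres, bg)
        # scaling by a power of two is strictly monotone and exact in floats
        transformed = auc_presence_background(8.0 * np.asarray(pres), 8.0 * np.asarray(bg))
        assert transformed == pytest.approx(base, abs=1e-12)

    def test_invariant_under_exponential_transform(self):
        pres, bg = [0.8, 0.4, 0.4], [0.6, 0.2, -1.0]
        assert auc_presence_background(np.exp(pres), np.exp(bg)) == auc_presence_background(pres, bg)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            auc_presence_background([], [0.5])


class TestCrossValidate:
    def test_folds_partition_the_presences(self, strong_grid, landscape4, uniform_background):
        cv = cross_validate(
            strong_grid.cells, landscape4, uniform_background, k=10,
            classes=("hinge",), n_hinge_knots=5, seed=0, with_importance=False,
        )
        sizes = [len(f) for f in cv.fold_indices]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(cv.fold_indices)) == list(range(strong_grid.n_occurrences))

    def test_strong_signal_species_beats_chance_and_generalizes(
        self, strong_grid, landscape4, uniform_background, spec20
    ):
        cv = cross_validate(
            strong_grid.cells, landscape4, uniform_background, k=10,
            classes=("hinge",), n_hinge_knots=10, seed=1,
            background_pool=spec20.all_cells(), with_importance=False,
        )
        assert cv.mean_test_auc > 0.65
        assert abs(cv.mean_test_auc - cv.mean_train_auc) < 0.05

    def test_too_few_presences_rejected(self, landscape4, uniform_background):
        with pytest.raises(ValueError, match="folds"):
            cross_validate(np.array([[0, 0]] * 5), landscape4, uniform_background, k=10)

    def test_hinge_only_matches_all_classes_auc_on_smooth_species(
        self, landscape4, spec20, uniform_background
    ):
        """Hinge-alone and the full feature set give similar test AUC on a
        smooth virtual species, while hinge-alone spreads permutation
        importance at least as widely (averaged over seeds)."""
        sp = generate_virtual_species(
            landscape4, {"env1": {"kind": "gaussian", "center": 0.0, "width": 0.8}}
        )
        diffs, sd_hinge, sd_all = [], [], []
        for seed in (0, 1, 2):
            recs = sample_occurrences(sp, 250, make_effort(spec20), seed=seed, spec=spec20)
            cells = np.unique(
                spec20.point_to_cell(recs["easting"].to_numpy(), recs["northing"].to_numpy()),
                axis=0,
            )
            kwargs = dict(k=5, seed=seed, n_hinge_knots=10, background_pool=spec20.all_cells())
            cv_h = cross_validate(cells, landscape4, uniform_background, classes=("hinge",), **kwargs)
            cv_a = cross_validate(
                cells, landscape4, uniform_background,
                classes=("linear", "quadratic", "product", "threshold", "hinge"), **kwargs
            )
            diffs.append(abs(cv_h.mean_test_auc - cv_a.mean_test_auc))
            sd_hinge.append(cv_h.permutation_importance_sd)
            sd_all.append(cv_a.permutation_importance_sd)
        assert np.mean(diffs) < 0.05
        assert np.mean(sd_hinge) >= np.mean(sd_all) - 2.0


class TestPermutationImportance:
    def test_single_active_predictor_takes_all_importance(self, landscape4, spec20, uniform_background):
        sp = generate_virtual_species(
            landscape4, {"env1": {"kind": "gaussian", "center": 0.8, "width": 0.4}}
        )
        recs = sample_occurrences(sp, 200, make_effort(spec20), seed=3, spec=spec20)
        cells = np.unique(
            spec20.point_to_cell(recs["easting"].to_numpy(), recs["northing"].to_numpy()), axis=0
        )
        exp = build_features(landscape4, uniform_background.cells, ("hinge",), len(cells), n_hinge_knots=10)
        Fp = exp.transform(landscape4.matrix(cells))
        Fb = exp.transform(landscape4.matrix(uniform_background.cells))
        model = fit_maxent(Fp, Fb, reg_beta=0.02, expansion=exp)
        imp, sd = permutation_importance(
            model, landscape4.matrix(cells), landscape4.matrix(uniform_background.cells), seed=0
        )
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-6)
        assert max(imp, key=imp.get) == "env1"
        assert imp["env1"] > 50.0
        assert sd > 0


class TestNullModelTest:
    def test_p_value_floor_at_full_exceedance(self, landscape4, spec20, uniform_background):
        res = null_model_test(
            observed_auc=1.0,
            n_occ=10,
            domain_cells=spec20.all_cells(),
            stack=landscape4,
            background=uniform_background,
            n_null=20,
            k=5,
            classes=("linear",),
            seed=0,
            min_samples=5,
        )
        assert res.p_value == pytest.approx(1 / 21)
        assert res.significant

    def test_small_n_null_warns(self, landscape4, spec20, uniform_background):
        with pytest.warns(UserWarning, match="unresolvable"):
            null_model_test(
                0.9, 10, spec20.all_cells(), landscape4, uniform_background,
                n_null=5, k=5, classes=("linear",), seed=0, min_samples=5,
            )


class TestTgbBiasTest:
    def test_unbiased_tgb_is_not_flagged(self, landscape4, spec20):
        rng = np.random.default_rng(0)
        domain = spec20.all_cells()
        tgb = domain[rng.choice(len(domain), 200, replace=False)]
        res = tgb_bias_test(
            tgb, domain, landscape4, n_points=60, n_tgb_sets=4, n_null=19,
            k=4, classes=("linear",), n_background=150, seed=1, min_samples=5,
        )
        assert not res.biased
        assert "+/-" in res.summary()

    def test_gradient_restricted_tgb_is_flagged(self, landscape4, spec20):
        env1 = landscape4["env1"]
        domain = spec20.all_cells()
        # recorder effort confined to one end of an environmental gradient
        tgb = np.column_stack(np.nonzero(env1 > np.quantile(env1, 0.7)))
        res = tgb_bias_test(
            tgb, domain, landscape4, n_points=60, n_tgb_sets=4, n_null=19,
            k=4, classes=("linear",), n_background=150, seed=1, min_samples=5,
        )
        assert res.biased
        assert res.tgb_mean > res.null_q95


class TestGainRanks:
    def test_true_driver_outranks_noise(self, strong_grid, landscape4, uniform_background):
        ranks = single_predictor_gain_ranks(
            strong_grid.cells, landscape4, uniform_background,
            k=5, seed=0, classes=("hinge",), n_hinge_knots=8,
        )
        assert ranks.loc["env1", "train_rank"] == ranks["train_rank"].max()
        # ranks are a permutation (ties averaged) of 1..P
        assert sorted(ranks["train_rank"]) == [1.0, 2.0, 3.0, 4.0]

    def test_identical_predictors_tie(self, strong_grid, landscape4, uniform_background):
        from pollmap.grids import PredictorStack

        twin = PredictorStack(
            landscape4.spec,
            {"a": landscape4["env1"], "b": landscape4["env1"].copy()},
        )
        ranks = single_predictor_gain_ranks(
            strong_grid.cells, twin, uniform_background, k=5, seed=0,
            classes=("linear",),
        )
        assert ranks["train_rank"].tolist() == [1.5, 1.5]


class TestRankCorrelationBootstrap:
    def test_identical_rankings(self):
        rho, p = rank_correlation_bootstrap([1, 2, 3, 4], [1, 2, 3, 4], n_boot=99, seed=0)
        assert rho == 1.0
        assert p <= 0.1

    def test_reversed_rankings(self):
        rho, _ = rank_correlation_bootstrap([1, 2, 3, 4], [4, 3, 2, 1], n_boot=99, seed=0)
        assert rho == -1.0

    def test_length_four_matches_exhaustive_enumeration(self):
        from itertools import permutations

        from scipy.stats import spearmanr

        a = [1, 2, 3, 4]
        b = [1, 3, 2, 4]
        rho_obs = spearmanr(a, b).statistic
        exact = np.mean(
            [spearmanr(a, perm).statistic >= rho_obs for perm in permutations(b)]
        )
        _, p = rank_correlation_bootstrap(a, b, n_boot=1999, seed=1)
        assert p == pytest.approx(exact, abs=0.05)

    def test_short_lists_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation_bootstrap([1, 2], [2, 1])
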