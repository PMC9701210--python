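"""Tests for splits, preprocessing, grid selection and the full framework."""

import numpy as np
import pandas as pd
import pytest

from latentdim.framework import (
    RunConfig,
    apply_preprocess,
    fit_preprocess,
    grid_search,
    make_split_scheme,
    normalise_brain,
    run_framework,
    select_cell,
)
from tests.conftest import planted_cohort


def singleton_metadata(n):
    return pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "family_id": [f"f{i}" for i in range(n)],
        "age": np.linspace(20, 40, n),
        "gender": np.arange(n) % 2,
        "site": "site0",
        "zygosity": "NT",
        "pair_id": "",
    })


class TestSplitScheme:
    def test_singleton_families_split_exactly_80_20(self):
        meta = singleton_metadata(100)
        scheme = make_split_scheme(meta, n_outer=3, n_inner=2, seed=0)
        for opt, hold in scheme.outer:
            assert len(opt) == 80 and len(hold) == 20
            assert len(np.intersect1d(opt, hold)) == 0
            assert len(np.union1d(opt, hold)) == 100

    def test_families_never_straddle_any_split(self):
        n_fam, fam_size = 30, 4
        meta = pd.DataFrame({
            "id": [f"s{i}" for i in range(n_fam * fam_size)],
            "family_id": [f"f{i // fam_size}" for i in range(n_fam * fam_size)],
        })
        fams = meta.groupby("family_id").indices
        for seed in range(200):
            scheme = make_split_scheme(meta, n_outer=2, n_inner=2, seed=seed)
            for (opt, hold), inners in zip(scheme.outer, scheme.inner):
                hold_set = set(hold.tolist())
                for idx in fams.values():
                    sides = {int(i) in hold_set for i in idx}
                    assert len(sides) == 1
                for tr, te in inners:
                    te_set = set(te.tolist())
                    for idx in fams.values():
                        in_te = {int(i) in te_set for i in np.asarray(idx)
                                 if int(i) in set(tr) | te_set}
                        assert len(in_te) <= 1

    def test_oversized_family_raises_with_guidance(self):
        meta = pd.DataFrame({
            "id": [f"s{i}" for i in range(20)],
            "family_id": ["big"] * 10 + [f"f{i}" for i in range(10)],
        })
        with pytest.raises(ValueError, match="family"):
            make_split_scheme(meta, n_outer=1, n_inner=1, holdout_fraction=0.2)

    def test_single_outer_single_inner_is_valid(self):
        meta = singleton_metadata(50)
        scheme = make_split_scheme(meta, n_outer=1, n_inner=1, seed=1)
        assert len(scheme.outer) == 1 and len(scheme.inner[0]) == 1
        tr, te = scheme.inner[0][0]
        opt, hold = scheme.outer[0]
        assert set(tr) | set(te) == set(opt)

    def test_deterministic_given_seed(self):
        meta = singleton_metadata(60)
        a = make_split_scheme(meta, seed=7)
        b = make_split_scheme(meta, seed=7)
        for (o1, h1), (o2, h2) in zip(a.outer, b.outer):
            assert np.array_equal(o1, o2) and np.array_equal(h1, h2)


class TestPreprocess:
    def test_train_residuals_orthogonal_to_confounds(self, rng):
        meta = singleton_metadata(200)
        feats = rng.standard_normal((200, 6))
        feats[:, 0] += 0.5 * meta["age"].to_numpy()  # planted age slope
        st = fit_preprocess(feats, meta)
        resid = apply_preprocess(st, feats, meta)
        age = meta["age"].to_numpy()
        for j in range(6):
            assert abs(np.corrcoef(resid[:, j], age)[0, 1]) < 1e-10

    def test_leakage_sentinel_train_coefficients_applied_to_test(self, rng):
        meta = singleton_metadata(100)
        feats = rng.standard_normal((100, 3))
        feats[:, 0] += 0.5 * meta["age"].to_numpy()
        train, test = np.arange(60), np.arange(60, 100)
        st = fit_preprocess(feats[train], meta.iloc[train])
        applied = apply_preprocess(st, feats[test], meta.iloc[test])
        refit = apply_preprocess(
            fit_preprocess(feats[test], meta.iloc[test]), feats[test],
            meta.iloc[test],
        )
        # the two procedures must be distinguishable (no silent refitting)
        assert not np.allclose(applied, refit)
        assert abs(np.mean(refit[:, 0])) < 1e-10

    def test_rank_deficient_design_names_collinear_columns(self, rng):
        meta = singleton_metadata(50)
        meta["age2"] = 2 * meta["age"]
        with pytest.raises(ValueError, match="age"):
            fit_preprocess(rng.standard_normal((50, 2)), meta,
                           confounds=("age", "age2"))

    def test_site_dummies_expand(self, rng):
        meta = singleton_metadata(90)
        meta["site"] = [f"site{i % 3}" for i in range(90)]
        st = fit_preprocess(rng.standard_normal((90, 2)), meta,
                            confounds=("age", "gender", "site"))
        assert sum(c.startswith("site") for c in st.columns) == 2


class TestNormaliseBrain:
    def test_division_by_block_total(self):
        X = np.array([[2.0, 3.0, 5.0]])
        totals = pd.DataFrame({"id": ["a"], "tiv": [10.0],
                               "mean_ct": [1.0], "total_sa": [1.0]})
        out = normalise_brain(X, totals, np.array(["GMV"] * 3))
        assert np.allclose(out, [[0.2, 0.3, 0.5]])

    def test_scale_invariance(self, rng):
        X = rng.standard_normal((4, 5)) + 5
        totals = pd.DataFrame({"id": list("abcd"),
                               "tiv": [1.0, 2.0, 1.5, 3.0],
                               "mean_ct": np.ones(4), "total_sa": np.ones(4)})
        blocks = np.array(["GMV"] * 5)
        base = normalise_brain(X, totals, blocks)
        X2 = X.copy()
        X2[1] *= 2
        totals2 = totals.copy()
        totals2.loc[1, "tiv"] *= 2
        assert np.allclose(normalise_brain(X2, totals2, blocks), base)

    def test_nonpositive_total_rejected(self):
        totals = pd.DataFrame({"id": ["a"], "tiv": [0.0],
                               "mean_ct": [1.0], "total_sa": [1.0]})
        with pytest.raises(ValueError, match="tiv"):
            normalise_brain(np.ones((1, 2)), totals, np.array(["GMV", "GMV"]))

    def test_pipeline_order_normalise_then_deconfound(self, rng):
        """The two preprocessing orders differ on confounded data; the
        pipeline fixes normalise-then-deconfound."""
        meta = singleton_metadata(120)
        X = rng.standard_normal((120, 4)) + 10
        X += 0.3 * meta["age"].to_numpy()[:, None]
        totals = pd.DataFrame({
            "id": meta["id"], "tiv": rng.uniform(0.8, 1.2, 120),
            "mean_ct": np.ones(120), "total_sa": np.ones(120),
        })
        blocks = np.array(["GMV"] * 4)
        norm_first = apply_preprocess(
            fit_preprocess(normalise_brain(X, totals, blocks), meta),
            normalise_brain(X, totals, blocks), meta,
        )
        deconf_first = normalise_brain(
            apply_preprocess(fit_preprocess(X, meta), X, meta), totals, blocks
        )
        assert not np.allclose(norm_first, deconf_first)


class TestGridSelection:
    def test_single_cell_grid_selected(self, rng):
        X = rng.standard_normal((60, 5))
        Y = X[:, :2] + 0.5 * rng.standard_normal((60, 2))
        inner = [(np.arange(0, 40), np.arange(40, 60)),
                 (np.arange(20, 60), np.arange(0, 20))]
        res = grid_search(X, Y, inner, [(0.5, 0.5)])
        assert res.selected == (0.5, 0.5)

    def test_dominating_cell_selected(self):
        grid = [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0)]
        corr = np.array([0.1, 0.6, 0.2])
        stab = np.array([0.3, 0.9, 0.5])
        assert select_cell(grid, corr, stab) == (0.5, 0.5)

    def test_tie_broken_toward_more_regularised(self):
        grid = [(0.0, 0.0), (1.0, 1.0)]
        corr = np.array([0.5, 0.5])
        stab = np.array([0.8, 0.8])
        assert select_cell(grid, corr, stab) == (1.0, 1.0)

    def test_conflicting_criteria_use_average_rank(self):
        grid = [(0.0, 0.0), (0.3, 0.3), (0.9, 0.9)]
        corr = np.array([0.7, 0.5, 0.1])   # ranks 1, 2, 3
        stab = np.array([0.2, 0.9, 0.5])   # ranks 3, 1, 2
        assert select_cell(grid, corr, stab) == (0.3, 0.3)

    def test_regularisation_chosen_under_feature_rich_noise(self):
        """With many noise features, the selected c_x is positive in a
        majority of seeds (shrinkage pays off out of sample)."""
        from latentdim.framework import make_split_scheme

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            c = planted_cohort(seed=300 + seed, n=250, rho=0.6,
                               brain_blocks=(("CT", 200),), n_behaviour=8,
                               families="singletons")
            scheme = make_split_scheme(c.metadata, n_outer=1, n_inner=3,
                                       seed=seed)
            opt, _ = scheme.outer[0]
            pos = {int(i): k for k, i in enumerate(opt)}
            inner = [
                (np.array([pos[int(i)] for i in tr]),
                 np.array([pos[int(i)] for i in te]))
                for tr, te in scheme.inner[0]
            ]
            res = grid_search(c.X[opt], c.Y[opt], inner,
                              [(cx, cy) for cx in (0.0, 0.6, 0.99)
                               for cy in (0.0, 0.6, 0.99)])
            wins += res.selected[0] > 0
        assert wins > n_seeds / 2


@pytest.fixture(scope="module")
def fitted():
    cohort = planted_cohort(seed=21, n=300, rho=0.7)
    config = RunConfig(n_permutations=50, seed=5, max_dimensions=1,
                       grid_x=(0.0, 0.9, 1.0), grid_y=(0.0, 0.9, 1.0))
    return cohort, config, run_framework(cohort, config)


class TestRunFramework:
    def test_per_split_table_shape_and_bonferroni(self, fitted):
        _, config, results = fitted
        tab = results[0].per_split
        assert len(tab) == config.n_outer
        assert np.allclose(
            tab["p_corrected"],
            np.minimum(1.0, config.n_outer * tab["p"]),
        )

    def test_holdout_correlations_all_positive_for_planted_dimension(self, fitted):
        _, _, results = fitted
        assert (results[0].per_split["holdout_corr"] > 0).all()

    def test_bitwise_deterministic_rerun(self, fitted):
        cohort, config, results = fitted
        again = run_framework(cohort, config)
        pd.testing.assert_frame_equal(results[0].per_split, again[0].per_split)
        pd.testing.assert_frame_equal(results[0].scores, again[0].scores)
        for a, b in zip(results[0].null_corrs, again[0].null_corrs):
            assert np.array_equal(a, b)

    def test_holdout_poisoning_does_not_change_models(self, fitted):
        """Leakage sentinel: perturbing holdout rows must leave the fitted
        weights of that split unchanged."""
        cohort, config, results = fitted
        scheme = make_split_scheme(
            cohort.metadata, config.n_outer, config.n_inner,
            config.holdout_fraction, config.test_fraction, seed=config.seed,
        )
        poisoned = planted_cohort(seed=21, n=300, rho=0.7)
        _, hold0 = scheme.outer[0]
        poisoned.X[hold0] += 100.0
        res_p = run_framework(poisoned, RunConfig(
            n_permutations=0, seed=5, max_dimensions=1,
            grid_x=(0.0, 0.9, 1.0), grid_y=(0.0, 0.9, 1.0)))
        assert np.allclose(res_p[0].models[0].u, results[0].models[0].u)
        assert np.allclose(res_p[0].models[0].v, results[0].models[0].v)

    def test_second_dimension_not_significant_when_one_planted(self):
        cohort = planted_cohort(seed=33, n=400, rho=0.7)
        config = RunConfig(n_permutations=200, seed=2, max_dimensions=2,
                           grid_x=(0.0, 0.9), grid_y=(0.0, 0.9))
        results = run_framework(cohort, config)
        assert results[0].omnibus is True
        assert len(results) == 2 and results[1].omnibus is False

    def test_models_never_averaged_across_splits(self, fitted):
        _, config, results = fitted
        # one model per split is retained; weights differ across splits
        assert len(results[0].models) == config.n_outer
        u0 = results[0].models[0].u
        assert any(not np.allclose(u0, m.u) for m in results[0].models[1:])
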