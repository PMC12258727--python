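"""Normalization and seasonal differential-abundance statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhizoprot import abundance as ab
from rhizoprot.io_formats import ValidationError
from rhizoprot.synthetic_data import SimulationConfig, gen_abundance_dataset

from conftest import make_matrix, make_meta


class TestNormalizeTotal:
    def test_equal_sums_unchanged(self):
        m = make_matrix([[1, 2], [3, 2]])  # column sums both 4
        out = ab.normalize_total(m)
        np.testing.assert_allclose(out.data.to_numpy(), m.data.to_numpy())

    def test_scale_factors_from_column_sums(self):
        m = make_matrix([[40, 100], [60, 200]])  # sums 100, 300 -> target 200
        out = ab.normalize_total(m)
        np.testing.assert_allclose(out.data.sum(axis=0).to_numpy(), [200.0, 200.0])
        np.testing.assert_allclose(out.data.to_numpy(), [[80, 100 * 2 / 3], [120, 400 / 3]])

    def test_within_sample_ratios_preserved(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.uniform(1, 100, size=(10, 4)))
        out = ab.normalize_total(m)
        ratios_in = m.data.to_numpy() / m.data.to_numpy()[0]
        ratios_out = out.data.to_numpy() / out.data.to_numpy()[0]
        np.testing.assert_allclose(ratios_in, ratios_out)

    def test_zero_total_sample_named(self):
        m = make_matrix([[0, 1], [0, 2]], samples=["dead", "ok"])
        with pytest.raises(ValidationError, match="dead"):
            ab.normalize_total(m)

    def test_missing_entries_stay_missing(self):
        m = make_matrix([[np.nan, 2], [3, 2]])
        out = ab.normalize_total(m)
        assert np.isnan(out.data.iloc[0, 0])


class TestFilterBothSeasons:
    def test_protein_in_one_season_removed(self, four_v_four):
        samples, meta = four_v_four
        vals = np.ones((2, 8))
        vals[0, :4] = np.nan  # p1 only in summer
        m = make_matrix(vals, samples=samples)
        kept = ab.filter_both_seasons(m, meta)
        assert kept.protein_ids == ["p2"]

    def test_two_per_season_retained(self, four_v_four):
        samples, meta = four_v_four
        vals = np.full((1, 8), np.nan)
        vals[0, [0, 1, 4, 5]] = 1.0
        m = make_matrix(vals, samples=samples)
        assert ab.filter_both_seasons(m, meta).shape[0] == 1

    def test_matches_brute_force_recount(self, four_v_four):
        samples, meta = four_v_four
        rng = np.random.default_rng(11)
        vals = rng.uniform(1, 10, size=(60, 8))
        vals[rng.random(vals.shape) < 0.45] = np.nan
        m = make_matrix(vals, samples=samples)
        kept = set(ab.filter_both_seasons(m, meta).protein_ids)
        season = dict(zip(meta["sample_id"], meta["season"]))
        expect = set()
        for i, pid in enumerate(m.protein_ids):
            nw = sum(1 for j, s in enumerate(samples)
                     if season[s] == "winter" and not np.isnan(vals[i, j]))
            ns = sum(1 for j, s in enumerate(samples)
                     if season[s] == "summer" and not np.isnan(vals[i, j]))
            if nw >= 2 and ns >= 2:
                expect.add(pid)
        assert kept == expect


class TestSeasonalTest:
    def test_identical_groups_give_null(self, four_v_four):
        samples, meta = four_v_four
        m = make_matrix([[8.0] * 8], samples=samples)
        res = ab.seasonal_test(m, meta)
        assert res.loc[0, "log2fc"] == 0.0 and res.loc[0, "p_value"] == 1.0

    def test_f_equals_t_squared_across_random_proteins(self, four_v_four):
        """With two seasons the one-way ANOVA F statistic is the square of
        the pooled t statistic, so the omnibus p equals the two-sided t p."""
        samples, meta = four_v_four
        rng = np.random.default_rng(4)
        vals = np.exp2(rng.normal(15, 1, size=(200, 8)))
        m = make_matrix(vals, samples=samples)
        res_contrast = ab.seasonal_test(m, meta, p_source="contrast")
        res_omnibus = ab.seasonal_test(m, meta, p_source="omnibus")
        logv = np.log2(vals)
        for i in range(200):
            t, p_t = stats.ttest_ind(logv[i, :4], logv[i, 4:])
            f, p_f = stats.f_oneway(logv[i, :4], logv[i, 4:])
            assert f == pytest.approx(t * t, rel=1e-9)
            assert res_contrast.loc[i, "p_value"] == pytest.approx(p_t, rel=1e-9)
            assert res_omnibus.loc[i, "p_value"] == pytest.approx(p_f, rel=1e-9)

    def test_tukey_contrast_equals_studentized_range_at_k2(self, four_v_four):
        """The k=2 shortcut (two-sided t) must agree with the explicit
        studentized-range evaluation used for general k."""
        samples, meta = four_v_four
        rng = np.random.default_rng(9)
        for _ in range(20):
            w, s = rng.normal(0, 1, 4), rng.normal(0.5, 1, 4)
            _, p_t = ab._two_group_stats(w, s)
            nw, ns = 4, 4
            mse = (((w - w.mean()) ** 2).sum() + ((s - s.mean()) ** 2).sum()) / (nw + ns - 2)
            q = abs(w.mean() - s.mean()) / np.sqrt(mse * (1 / nw + 1 / ns) / 2)
            p_q = stats.studentized_range.sf(q, 2, nw + ns - 2)
            assert p_t == pytest.approx(p_q, rel=1e-5)

    def test_bh_ladder_hand_computed(self):
        """BH on raw (0.01, 0.02, 0.03) gives (0.03, 0.03, 0.03)."""
        samples = ["w1", "w2", "s1", "s2"]
        meta = make_meta(samples, ["winter", "winter", "summer", "summer"])
        # craft three proteins whose raw two-sided t p-values are arbitrary,
        # then check BH directly through the result columns
        rng = np.random.default_rng(2)
        m = make_matrix(np.exp2(rng.normal(10, 1, (3, 4))), samples=samples)
        res = ab.seasonal_test(m, meta)
        res.loc[:, "p_value"] = [0.01, 0.02, 0.03]
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(res["p_value"], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_bh_bounds_and_monotonicity(self, four_v_four):
        samples, meta = four_v_four
        rng = np.random.default_rng(6)
        m = make_matrix(np.exp2(rng.normal(12, 1, (120, 8))), samples=samples)
        res = ab.seasonal_test(m, meta).sort_values("p_value").reset_index(drop=True)
        mtot = len(res)
        assert (res["p_adj"].diff().dropna() >= -1e-12).all()
        assert (res["p_adj"] >= res["p_value"] - 1e-12).all()
        assert (res["p_adj"] <= np.minimum(1.0, mtot * res["p_value"]) + 1e-12).all()

    def test_too_few_samples_marks_untested(self, four_v_four):
        samples, meta = four_v_four
        vals = np.ones((1, 8))
        vals[0, :3] = np.nan  # one winter value
        res = ab.seasonal_test(make_matrix(vals, samples=samples), meta)
        assert res.loc[0, "call"] == "untested" and np.isnan(res.loc[0, "p_adj"])

    def test_zeros_treated_as_missing(self, four_v_four):
        samples, meta = four_v_four
        vals = np.full((1, 8), 4.0)
        vals[0, :3] = 0.0
        res = ab.seasonal_test(make_matrix(vals, samples=samples), meta)
        assert res.loc[0, "n_winter"] == 1 and res.loc[0, "call"] == "untested"

    def test_result_invariant_to_row_and_column_order(self, four_v_four):
        samples, meta = four_v_four
        rng = np.random.default_rng(14)
        vals = np.exp2(rng.normal(12, 1, (30, 8)))
        m = make_matrix(vals, samples=samples)
        res = ab.seasonal_test(m, meta).set_index("protein_id")
        perm_rows = rng.permutation(30)
        perm_cols = rng.permutation(8)
        m2 = make_matrix(vals[np.ix_(perm_rows, perm_cols)],
                         proteins=[m.protein_ids[i] for i in perm_rows],
                         samples=[samples[j] for j in perm_cols])
        res2 = ab.seasonal_test(m2, meta).set_index("protein_id")
        pd.testing.assert_frame_equal(res.sort_index(), res2.sort_index())

    def test_confounded_batch_design_raises(self):
        samples = ["w1", "w2", "s1", "s2"]
        meta = make_meta(samples, ["winter", "winter", "summer", "summer"],
                         batches=["b1", "b1", "b2", "b2"])
        m = make_matrix(np.full((2, 4), 5.0), samples=samples)
        with pytest.raises(ValidationError, match="batch"):
            ab.seasonal_test(m, meta, adjust_for=("batch",))

    def test_adjusted_model_matches_statsmodels_ols(self):
        """Dual route: the hand-built least-squares season contrast must
        agree with a statsmodels OLS fit of the same additive model."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(21)
        samples = [f"x{i}" for i in range(12)]
        seasons = (["winter"] * 6) + (["summer"] * 6)
        batches = ["b1", "b2", "b3"] * 4
        meta = make_meta(samples, seasons, batches=batches)
        vals = np.exp2(rng.normal(10, 1, (5, 12)))
        m = make_matrix(vals, samples=samples)
        res = ab.seasonal_test(m, meta, adjust_for=("batch",))
        for i in range(5):
            df = pd.DataFrame({"y": np.log2(vals[i]),
                               "winter": [s == "winter" for s in seasons],
                               "batch": batches})
            fit = smf.ols("y ~ C(winter) + C(batch)", df).fit()
            assert res.loc[i, "log2fc"] == pytest.approx(
                fit.params["C(winter)[T.True]"], rel=1e-8)
            assert res.loc[i, "p_value"] == pytest.approx(
                fit.pvalues["C(winter)[T.True]"], rel=1e-6)


class TestCallDaps:
    def test_boundary_semantics(self):
        res = pd.DataFrame({
            "protein_id": ["a", "b", "c"],
            "log2fc": [1.0, 0.99, -1.0],
            "p_value": [0.01, 0.001, 0.01],
            "p_adj": [0.049, 0.001, 0.05],
            "call": ["not_significant"] * 3,
            "n_winter": [4] * 3, "n_summer": [4] * 3,
        })
        out = ab.call_daps(res)
        assert list(out["call"]) == ["up", "not_significant", "not_significant"]

    def test_stricter_thresholds_never_add_daps(self, four_v_four):
        samples, meta = four_v_four
        rng = np.random.default_rng(8)
        base = rng.normal(12, 1, (150, 8))
        base[:40, :4] += rng.uniform(0.5, 2.5, (40, 1))
        m = make_matrix(np.exp2(base), samples=samples)
        res = ab.seasonal_test(m, meta)
        loose = ab.call_daps(res, lfc_min=1.0, alpha=0.05)
        for lfc_min, alpha in [(1.0, 0.01), (1.5, 0.05), (1.5, 0.01)]:
            strict = ab.call_daps(res, lfc_min=lfc_min, alpha=alpha)
            for d in ("up", "down"):
                assert set(strict.loc[strict["call"] == d, "protein_id"]) <= \
                    set(loose.loc[loose["call"] == d, "protein_id"])


class TestParameterRecovery:
    def test_zero_noise_log2fc_exact(self):
        cfg = SimulationConfig(n_species=2, n_orthogroups=60, noise_sd_log2=0.0,
                               batch_sd_log2=0.0, effect_size_log2=2.0, seed=3)
        matrices, meta, _, truth = gen_abundance_dataset(cfg)
        for sp, m in matrices.items():
            res = ab.seasonal_test(m, meta[meta["species"] == sp]).set_index("protein_id")
            for pid, eff in truth.true_effect[sp].items():
                assert res.loc[pid, "log2fc"] == pytest.approx(eff, abs=1e-9)

    def test_batch_adjustment_removes_batch_bias(self):
        """With planted batch offsets, adjust_for=('batch',) recovers the
        planted effects essentially unbiased (mean |error| small)."""
        errs = []
        for seed in range(10):
            cfg = SimulationConfig(n_species=1, n_orthogroups=80, noise_sd_log2=0.0,
                                   batch_sd_log2=1.0, effect_size_log2=2.0, seed=seed)
            matrices, meta, _, truth = gen_abundance_dataset(cfg)
            sp, m = next(iter(matrices.items()))
            res = ab.seasonal_test(m, meta[meta["species"] == sp],
                                   adjust_for=("batch",)).set_index("protein_id")
            for pid, eff in truth.true_effect[sp].items():
                errs.append(res.loc[pid, "log2fc"] - eff)
        assert abs(np.mean(errs)) < 0.01
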