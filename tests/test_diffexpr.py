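import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dualstress import diffexpr, preprocess, simulate
from dualstress.errors import ValidationError


def residuals_from(values: dict) -> pd.DataFrame:
    rows = [(pid, aid, v) for (pid, aid), v in values.items()]
    return pd.DataFrame(rows, columns=["probe_id", "array_id", "residual"])


class TestStage1:
    def test_centered_input_unchanged(self, toy_sheet):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, len(toy_sheet)))
        vals -= vals.mean(axis=0)       # centre per array
        lr = pd.DataFrame({
            "probe_id": np.repeat([f"P{i}" for i in range(5)], len(toy_sheet)),
            "array_id": np.tile(toy_sheet["array_id"], 5),
            "log_ratio": vals.ravel(),
        })
        s1 = diffexpr.fit_stage1(lr, toy_sheet)
        assert np.allclose(s1.residuals["residual"], lr["log_ratio"], atol=1e-12)
        assert np.allclose(s1.array_effects, 0.0, atol=1e-12)

    def test_recovers_planted_offsets(self):
        design = pd.DataFrame({
            "array_id": ["a1", "a2", "a3"], "run": [1, 1, 1],
            "treatment": ["Psyr"] * 3, "time_h": [1, 6, 24],
            "replicate": [1, 1, 1],
        })
        base = {"P1": 0.3, "P2": -0.1, "P3": -0.2}
        offsets = {"a1": 1.0, "a2": -1.0, "a3": 0.5}
        lr = pd.DataFrame([
            (p, a, base[p] + offsets[a]) for p in base for a in offsets
        ], columns=["probe_id", "array_id", "log_ratio"])
        s1 = diffexpr.fit_stage1(lr, design)
        centre = np.mean(list(base.values()))
        for a, off in offsets.items():
            assert s1.array_effects[a] == pytest.approx(off + centre)
        for p in base:
            got = s1.residuals.query("probe_id == @p")["residual"]
            assert np.allclose(got, base[p] - centre)

    def test_single_array(self):
        design = pd.DataFrame({"array_id": ["a1"], "run": [1],
                               "treatment": ["Psyr"], "time_h": [1],
                               "replicate": [1]})
        lr = pd.DataFrame({"probe_id": ["P1", "P2"], "array_id": ["a1", "a1"],
                           "log_ratio": [1.0, 3.0]})
        s1 = diffexpr.fit_stage1(lr, design)
        assert np.allclose(sorted(s1.residuals["residual"]), [-1.0, 1.0])

    def test_unknown_array_rejected(self, toy_sheet):
        lr = pd.DataFrame({"probe_id": ["P1"], "array_id": ["nope"],
                           "log_ratio": [0.1]})
        with pytest.raises(ValidationError, match="nope"):
            diffexpr.fit_stage1(lr, toy_sheet)

    def test_residual_array_means_zero(self, clean_experiment):
        kept, _ = preprocess.filter_spots(clean_experiment.spots)
        lr, _ = preprocess.compute_log_ratios(kept)
        s1 = diffexpr.fit_stage1(lr, clean_experiment.sample_sheet)
        means = s1.residuals.groupby("array_id")["residual"].mean()
        assert np.abs(means).max() < 1e-9


class TestStage2:
    def test_noise_free_construction(self, toy_sheet):
        planted = {("Spod", 1): 2.0, ("Spod", 6): 1.0, ("Spod", 24): 0.0,
                   ("Psyr", 1): 0.0, ("Psyr", 6): 1.0, ("Psyr", 24): 2.0}
        vals = {}
        for _, r in toy_sheet.iterrows():
            vals[("P1", r["array_id"])] = planted[(r["treatment"], r["time_h"])]
        fits = diffexpr.fit_stage2(residuals_from(vals), toy_sheet)
        fit = fits[0]
        for k, cell in enumerate(fit.cells):
            assert fit.cell_means[k] == pytest.approx(planted[cell], abs=1e-12)

    def test_all_zero_residuals(self, toy_sheet):
        vals = {("P1", a): 0.0 for a in toy_sheet["array_id"]}
        fit = diffexpr.fit_stage2(residuals_from(vals), toy_sheet)[0]
        assert np.allclose(fit.cell_means, 0.0)
        p_int = fit.f_tests["trt_time"][3]
        assert not (p_int < 0.05)       # NaN or large: never "significant"

    def test_ols_equivalence_when_no_group_variance(self, toy_sheet):
        rng = np.random.default_rng(3)
        n = len(toy_sheet)
        found = False
        for trial in range(20):
            y = rng.normal(0, 1, n)
            vals = {("P1", a): y[i] for i, a in enumerate(toy_sheet["array_id"])}
            fit = diffexpr.fit_stage2(residuals_from(vals), toy_sheet)[0]
            if not fit.used_ols:
                continue
            found = True
            # OLS oracle: cell means are plain averages
            df = toy_sheet.assign(y=y)
            for k, (t, h) in enumerate(fit.cells):
                ref = df[(df.treatment == t) & (df.time_h == h)]["y"].mean()
                assert fit.cell_means[k] == pytest.approx(ref, abs=1e-8)
        assert found

    def test_mixed_cell_means_equal_ols_when_balanced(self, toy_sheet, rng):
        # balanced random-intercept designs: GLS == OLS for the cell means
        y = rng.normal(0, 1, len(toy_sheet)) + np.repeat(rng.normal(0, 1, 4),
                                                         len(toy_sheet) // 4)
        vals = {("P1", a): y[i] for i, a in enumerate(toy_sheet["array_id"])}
        fit = diffexpr.fit_stage2(residuals_from(vals), toy_sheet)[0]
        df = toy_sheet.assign(y=y)
        for k, (t, h) in enumerate(fit.cells):
            ref = df[(df.treatment == t) & (df.time_h == h)]["y"].mean()
            assert fit.cell_means[k] == pytest.approx(ref, abs=1e-8)

    def test_one_treatment_untestable(self, toy_sheet):
        sub = toy_sheet[toy_sheet["treatment"] == "Psyr"]
        vals = {("P1", a): 0.5 for a in sub["array_id"]}
        residuals = residuals_from(vals)
        fits = diffexpr.fit_stage2(residuals, toy_sheet)
        fit = fits[0]
        assert np.isnan(fit.f_tests["trt"][3])
        assert np.isnan(fit.f_tests["trt_time"][3])
        assert fit.incomplete

    def test_probe_with_single_observation_degenerate(self, toy_sheet):
        vals = {("P1", toy_sheet["array_id"].iloc[0]): 1.5}
        vals.update({("P2", a): 0.1 for a in toy_sheet["array_id"]})
        fits = diffexpr.fit_stage2(residuals_from(vals), toy_sheet)
        f1 = next(f for f in fits if f.probe_id == "P1")
        assert f1.incomplete and f1.n_obs == 1
        assert np.isnan(f1.f_tests["trt_time"][3])


class TestAdjust:
    def _one_fit(self, toy_sheet, rng):
        y = rng.normal(0, 0.5, len(toy_sheet))
        vals = {("P1", a): y[i] for i, a in enumerate(toy_sheet["array_id"])}
        return diffexpr.fit_stage2(residuals_from(vals), toy_sheet)[0]

    def test_adjusted_geq_raw(self, toy_sheet, rng):
        fit = self._one_fit(toy_sheet, rng)
        diffexpr.adjust_pvalues([fit])
        ok = np.isfinite(fit.cell_p)
        assert (fit.cell_p_adj[ok] >= fit.cell_p[ok] - 1e-12).all()

    def test_matches_studentized_range_oracle(self, toy_sheet, rng):
        fit = self._one_fit(toy_sheet, rng)
        diffexpr.adjust_pvalues([fit])
        for k in range(6):
            oracle = stats.studentized_range.sf(
                np.sqrt(2.0) * abs(fit.cell_t[k]), 6, fit.ddf)
            oracle = max(oracle, fit.cell_p[k])
            assert fit.cell_p_adj[k] == pytest.approx(oracle, abs=1e-7)

    def test_single_cell_adjusted_equals_raw(self, toy_sheet):
        sub = toy_sheet[(toy_sheet["treatment"] == "Psyr")
                        & (toy_sheet["time_h"] == 1)]
        rng = np.random.default_rng(0)
        vals = {("P1", a): rng.normal() for a in sub["array_id"]}
        extra = toy_sheet[(toy_sheet["treatment"] == "Psyr")
                          & (toy_sheet["time_h"] == 6)]
        vals.update({("P1", a): rng.normal() for a in extra["array_id"]})
        fit = diffexpr.fit_stage2(residuals_from(vals), toy_sheet)[0]
        # drop one cell's results to leave a single testable cell
        fit.cell_t[1:] = np.nan
        fit.cell_p[1:] = np.nan
        fit.cell_means[1:] = np.nan
        diffexpr.adjust_pvalues([fit])
        assert fit.cell_p_adj[0] == pytest.approx(fit.cell_p[0])

    def test_identical_cells_never_significant_pairwise(self, toy_sheet):
        vals = {("P1", a): 1.0 for a in toy_sheet["array_id"]}
        fit = diffexpr.fit_stage2(residuals_from(vals), toy_sheet)[0]
        diffexpr.adjust_pvalues([fit], pairwise=True)
        if fit.pairwise is not None:
            sig = fit.pairwise["p_adj"] < 0.999
            assert not sig.any()


class TestFdrSelect:
    def test_worked_example(self):
        p = pd.Series({"a": 0.001, "b": 0.01, "c": 0.02, "d": 0.5})
        sel, thr = diffexpr.fdr_select(p, 0.05)
        assert sorted(sel) == ["a", "b", "c"]
        assert thr == 0.02

    def test_all_ones(self):
        p = pd.Series(np.ones(50))
        sel, _ = diffexpr.fdr_select(p, 0.05)
        assert sel == []

    def test_empty(self):
        sel, thr = diffexpr.fdr_select(pd.Series(dtype=float), 0.05)
        assert sel == [] and thr == 0.0

    def test_invalid_pvalues(self):
        with pytest.raises(ValidationError):
            diffexpr.fdr_select(pd.Series([0.5, 1.4]), 0.05)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60), st.floats(min_value=0.01, max_value=0.2))
    def test_matches_brute_force(self, pvals, alpha):
        s = pd.Series(pvals)
        sel, _ = diffexpr.fdr_select(s, alpha)
        # brute force: largest i with p_(i) <= i*alpha/m, select all below
        ps = np.sort(np.asarray(pvals))
        m = len(ps)
        kmax = 0
        for i in range(1, m + 1):
            if ps[i - 1] <= i * alpha / m:
                kmax = i
        expect = set(s.index[s <= (ps[kmax - 1] if kmax else -1)])
        assert set(sel) == expect


class TestCountDe:
    def _fits_with_planted(self, overlap=True):
        design = simulate.ArrayDesignSpec(n_probes=40, n_duplicated=0,
                                          control_classes=(), seed=17)
        effects = simulate.EffectSpec(frac_differential=0.3, sd_noise=0.05,
                                      sd_replicate=0.0, missing_rate=0.0,
                                      effect_scale=2.0)
        exp = simulate.generate_array_experiment(design, effects)
        kept, _ = preprocess.filter_spots(exp.spots)
        lr, _ = preprocess.compute_log_ratios(kept)
        s1 = diffexpr.fit_stage1(lr, exp.sample_sheet)
        return diffexpr.fit_stage2(s1.residuals, exp.sample_sheet), exp

    def test_counts_consistent(self):
        fits, exp = self._fits_with_planted()
        de = diffexpr.count_de(fits, 0.001)
        assert (de.counts["n_sig"]
                == de.counts["n_up"] + de.counts["n_down"]).all()
        assert (de.counts["n_sig"] <= len(fits)).all()
        for _, row in de.overlaps.iterrows():
            h = row["time_h"]
            per_trt = de.counts[de.counts["time_h"] == h]["n_sig"]
            assert row["n_overlap"] <= per_trt.min()

    def test_disjoint_sets_no_overlap(self, toy_sheet):
        # P1 responds only under Spod, P2 only under Psyr
        vals = {}
        for _, r in toy_sheet.iterrows():
            vals[("P1", r["array_id"])] = 5.0 if r["treatment"] == "Spod" else 0.0
            vals[("P2", r["array_id"])] = 5.0 if r["treatment"] == "Psyr" else 0.0
        res = residuals_from(vals)
        rng = np.random.default_rng(0)
        res["residual"] += rng.normal(0, 0.05, len(res))
        fits = diffexpr.fit_stage2(res, toy_sheet)
        de = diffexpr.count_de(fits, 0.001)
        assert (de.overlaps["n_overlap"] == 0).all()

    def test_truth_comparison_on_simulation(self, toy_sheet):
        """Probes planted in BOTH treatments at 6 h show up in the overlap."""
        rng = np.random.default_rng(42)
        vals = {}
        n_both = 12
        for i in range(n_both):
            for _, r in toy_sheet.iterrows():
                v = 4.0 if r["time_h"] == 6 else 0.0
                vals[(f"B{i:02d}", r["array_id"])] = v + rng.normal(0, 0.2)
        fits = diffexpr.fit_stage2(residuals_from(vals), toy_sheet)
        de = diffexpr.count_de(fits, 0.001)
        got = int(de.overlaps.loc[de.overlaps["time_h"] == 6, "n_overlap"].iloc[0])
        assert got >= n_both - 1


class TestStage2Table:
    def test_table_shape_and_columns(self, clean_experiment):
        kept, _ = preprocess.filter_spots(clean_experiment.spots)
        lr, _ = preprocess.compute_log_ratios(kept)
        s1 = diffexpr.fit_stage1(lr, clean_experiment.sample_sheet)
        fits = diffexpr.fit_stage2(s1.residuals, clean_experiment.sample_sheet)
        diffexpr.adjust_pvalues(fits)
        tab = diffexpr.stage2_table(fits)
        assert len(tab) == len(fits)
        assert "p_trt_time" in tab.columns
        assert tab.filter(like="mean_").shape[1] == 6
        ok = tab["p_trt_time"].dropna()
        assert ((ok >= 0) & (ok <= 1)).all()
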