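import numpy as np
import pandas as pd
import pytest

from dualstress import lmm, metabolomics, simulate
from dualstress.errors import ValidationError


def tiny_peak_table():
    samples = pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "run": [1, 1], "treatment": ["Psyr", "Psyr"],
        "tc": ["T", "C"], "replicate": [1, 1],
        "sample_mass": [15.0, 10.0],
    })
    areas = pd.DataFrame({"F1": [300.0, 0.0], "F2": [150.0, 400.0]},
                         index=pd.Index(["s1", "s2"], name="sample_id"))
    rt = pd.Series({"F1": 5.0, "F2": 20.0})
    standards = pd.DataFrame({
        "sample_id": ["s1", "s1", "s2", "s2"],
        "standard": ["A", "B", "A", "B"],
        "rt": [4.0, 22.0, 4.0, 22.0],
        "area": [300.0, 100.0, 100.0, 200.0],
    })
    return samples, areas, rt, standards


class TestNormalizePeakAreas:
    def test_direct_arithmetic(self):
        samples, areas, rt, standards = tiny_peak_table()
        one = areas.iloc[[0]]
        norm = metabolomics.normalize_peak_areas(one, samples, rt, standards)
        # F1: raw 300 / mass 15 / IS-A 300 = 1/15; single sample scales to 100
        assert norm.loc["s1", "F1"] == pytest.approx(100.0)

    def test_max_scaling(self):
        samples, areas, rt, standards = tiny_peak_table()
        # construct adjusted values {2, 4} for F2
        areas = areas.copy()
        areas.loc["s1", "F2"] = 2.0 * 15.0 * 100.0   # adj 2 (IS-B area 100)
        areas.loc["s2", "F2"] = 4.0 * 10.0 * 200.0   # adj 4
        norm = metabolomics.normalize_peak_areas(areas, samples, rt, standards)
        assert norm["F2"].tolist() == pytest.approx([50.0, 100.0])

    def test_nearest_standard_tie_breaks_earlier(self):
        standards = pd.DataFrame({
            "sample_id": ["s1", "s1"], "standard": ["late", "early"],
            "rt": [15.0, 5.0], "area": [10.0, 20.0],
        })
        row = metabolomics.nearest_standard(10.0, standards)  # exactly midway
        assert row["standard"] == "early"

    def test_zero_standard_area_named(self):
        samples, areas, rt, standards = tiny_peak_table()
        standards.loc[0, "area"] = 0.0
        with pytest.raises(ValidationError, match="s1"):
            metabolomics.normalize_peak_areas(areas, samples, rt, standards)

    def test_scale_invariance(self):
        samples, areas, rt, standards = tiny_peak_table()
        norm1 = metabolomics.normalize_peak_areas(areas, samples, rt, standards)
        norm2 = metabolomics.normalize_peak_areas(areas * 7.5, samples, rt,
                                                  standards)
        pd.testing.assert_frame_equal(norm1, norm2)

    def test_sample_total_scaling_option(self):
        samples, areas, rt, standards = tiny_peak_table()
        norm = metabolomics.normalize_peak_areas(areas, samples, rt, standards,
                                                 scaling="sample_total")
        assert norm.sum(axis=1).tolist() == pytest.approx([100.0, 100.0])


class TestPartition:
    def test_always_present_is_continuous(self, metab_experiment):
        exp = metab_experiment
        norm = metabolomics.normalize_peak_areas(
            exp.areas, exp.samples, exp.fraction_rt, exp.standards)
        classes = metabolomics.partition_metabolites(norm)
        truth = exp.truth.set_index("fraction")
        always = truth.index[~truth["is_dichotomous"]]
        assert (classes[always] == "continuous").all()

    def test_condition_restricted_is_dichotomous(self, metab_experiment):
        exp = metab_experiment
        norm = metabolomics.normalize_peak_areas(
            exp.areas, exp.samples, exp.fraction_rt, exp.standards)
        classes = metabolomics.partition_metabolites(norm)
        truth = exp.truth.set_index("fraction")
        dich = truth.index[truth["is_dichotomous"]]
        assert (classes[dich] == "dichotomous").all()

    def test_threshold_sweep_monotone(self, metab_experiment):
        exp = metab_experiment
        norm = metabolomics.normalize_peak_areas(
            exp.areas, exp.samples, exp.fraction_rt, exp.standards)
        prev = None
        for thr in np.linspace(0.5, 1.0, 11):
            n_cont = (metabolomics.partition_metabolites(norm, thr)
                      == "continuous").sum()
            if prev is not None:
                assert n_cont <= prev
            prev = n_cont

    def test_invalid_threshold(self, metab_experiment):
        with pytest.raises(ValidationError):
            metabolomics.partition_metabolites(
                metab_experiment.areas, presence_threshold=0.0)


class TestFitMetaboliteModel:
    def _fit(self, spec, seed=11, **kw):
        exp = simulate.generate_metabolite_experiment(spec, seed=seed)
        norm = metabolomics.normalize_peak_areas(
            exp.areas, exp.samples, exp.fraction_rt, exp.standards)
        classes = metabolomics.partition_metabolites(norm)
        fits = metabolomics.fit_metabolite_model(norm, exp.samples, classes,
                                                 **kw)
        return exp, fits

    def test_noise_free_tc_recovery(self):
        spec = simulate.MetabDesignSpec(
            frac_affected=1.0, effect_trt=0.0, effect_tc=2.0,
            effect_trt_tc=0.0, sd_noise=0.0, sd_replicate=0.0,
            frac_dichotomous=0.0)
        exp, fits = self._fit(spec, seed=1, pairwise=False)
        truth = exp.truth.set_index("fraction")
        for f in fits:
            assert f.testable
            assert f.beta["tc"] == pytest.approx(
                truth.loc[f.fraction, "beta_tc"], abs=1e-6)

    def test_all_equal_samples(self):
        samples = []
        for run in (1, 2):
            for trt in ("Psyr", "Spod"):
                for tc in ("C", "T"):
                    for rep in range(1, 5):
                        samples.append((f"e{run}{trt}{tc}{rep}", run, trt, tc,
                                        rep, 15.0))
        samples = pd.DataFrame(samples, columns=[
            "sample_id", "run", "treatment", "tc", "replicate", "sample_mass"])
        norm = pd.DataFrame({"F1": 50.0}, index=samples["sample_id"])
        classes = pd.Series({"F1": "continuous"})
        fit = metabolomics.fit_metabolite_model(norm, samples, classes,
                                                pairwise=False)[0]
        assert fit.beta["tc"] == pytest.approx(0.0, abs=1e-10)
        assert not (fit.f_tests["trt_tc"][3] < 0.05)

    def test_ols_fallback_matches_lstsq(self, rng):
        exp, fits = self._fit(simulate.MetabDesignSpec(
            sd_replicate=0.0, frac_dichotomous=0.0, frac_affected=0.0),
            seed=23, pairwise=False)
        norm = metabolomics.normalize_peak_areas(
            exp.areas, exp.samples, exp.fraction_rt, exp.standards)
        ols_fits = [f for f in fits if f.used_ols]
        assert ols_fits
        f = ols_fits[0]
        meta = exp.samples
        y = np.log2(norm[f.fraction].to_numpy())
        treatments = list(dict.fromkeys(meta["treatment"]))
        cells = [(t, c) for t in treatments for c in ("C", "T")]
        ci = np.array([cells.index((t, c))
                       for t, c in zip(meta["treatment"], meta["tc"])])
        X = np.zeros((len(y), 4))
        X[np.arange(len(y)), ci] = 1.0
        runs = sorted(meta["run"].unique())
        X = np.column_stack([X, np.where(meta["run"] == runs[0], -0.5, 0.5)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert f.cell_means == pytest.approx(beta[:4], abs=1e-8)

    def test_dichotomous_not_modelled(self, metab_experiment):
        exp = metab_experiment
        norm = metabolomics.normalize_peak_areas(
            exp.areas, exp.samples, exp.fraction_rt, exp.standards)
        classes = metabolomics.partition_metabolites(norm)
        fits = metabolomics.fit_metabolite_model(norm, exp.samples, classes,
                                                 pairwise=False)
        for f in fits:
            if f.metab_class == "dichotomous":
                assert not f.beta
                assert not f.testable

    def test_presence_table(self, metab_experiment):
        exp = metab_experiment
        norm = metabolomics.normalize_peak_areas(
            exp.areas, exp.samples, exp.fraction_rt, exp.standards)
        classes = metabolomics.partition_metabolites(norm)
        dich = classes.index[classes == "dichotomous"]
        tab = metabolomics.presence_table(norm, exp.samples, dich)
        assert set(tab["fraction"]) == set(dich)
        assert (tab["n_present"] <= tab["n_total"]).all()

    def test_null_type_one_error(self):
        """Interaction F-test holds its level on null data (module invariant)."""
        hits = 0
        n_sims = 400
        for s in range(n_sims):
            spec = simulate.MetabDesignSpec(
                n_fractions=1, frac_affected=0.0, frac_dichotomous=0.0,
                seed=30_000 + s)
            exp = simulate.generate_metabolite_experiment(spec)
            norm = metabolomics.normalize_peak_areas(
                exp.areas, exp.samples, exp.fraction_rt, exp.standards)
            classes = metabolomics.partition_metabolites(norm)
            f = metabolomics.fit_metabolite_model(
                norm, exp.samples, classes, pairwise=False)[0]
            if f.f_tests["trt_tc"][3] < 0.05:
                hits += 1
        rate = hits / n_sims
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) <= 2.5 * se


def test_metabolite_table_columns(metab_experiment):
    exp = metab_experiment
    norm = metabolomics.normalize_peak_areas(
        exp.areas, exp.samples, exp.fraction_rt, exp.standards)
    classes = metabolomics.partition_metabolites(norm)
    fits = metabolomics.fit_metabolite_model(norm, exp.samples, classes,
                                             pairwise=False)
    tab = metabolomics.metabolite_table(fits)
    assert len(tab) == 33
    assert {"beta_tc", "p_trt_tc", "class"} <= set(tab.columns)
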