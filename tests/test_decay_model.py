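import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import decaykit as dk
from decaykit.decay_model import halflife
from decaykit.io_formats import COND_COL, REP_COL, TIME_COL

from conftest import make_dataset, make_design

LN2 = np.log(2.0)


def oracle_normal_equations(design: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """Independent OLS oracle: build the design matrix by hand and solve X'Xb = X'y."""
    t = design[TIME_COL].to_numpy(dtype=float)
    cond = design[COND_COL].to_numpy()
    reps = design[REP_COL].to_numpy()
    cols = [np.ones_like(t)]
    for r in sorted(set(reps))[1:]:
        cols.append((reps == r).astype(float))
    cols.append((cond == "CI7").astype(float))
    cols.append(t * (cond == "P"))
    cols.append(t * (cond == "CI7"))
    X = np.column_stack(cols)
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitGene:
    def test_equal_halflife_recovered_exactly(self):
        """Noise-free 120-min half-life in both states: k = ln2/120, no interaction."""
        ds = make_dataset({"G1": (120.0, 120.0)})
        fit = dk.fit_gene(np.log(ds.intensities.loc["G1"]), ds.design, gene="G1")
        assert fit.k_P == pytest.approx(LN2 / 120.0, abs=1e-12)
        assert fit.k_CI7 == pytest.approx(LN2 / 120.0, abs=1e-12)
        assert fit.halflife_P == pytest.approx(120.0)
        # zero interaction F-statistic => p at the 1 end
        assert fit.interaction_pvalue > 0.999

    def test_differential_halflives_give_known_delta(self):
        """120 vs 480 min half-lives: k_P - k_CI7 = ln2 * 3/480 per minute."""
        ds = make_dataset({"G1": (120.0, 480.0)})
        fit = dk.fit_gene(np.log(ds.intensities.loc["G1"]), ds.design, gene="G1")
        assert fit.k_P - fit.k_CI7 == pytest.approx(LN2 * 3 / 480, abs=1e-12)
        assert fit.k_P - fit.k_CI7 == pytest.approx(0.0043322, abs=1e-7)

    def test_coefficients_match_normal_equations_oracle(self):
        """OLS solution equals the brute-force normal-equations solve to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            times = [0.0] + sorted(rng.choice(np.arange(30, 600, 30), 3, replace=False))
            design = make_design(n_replicates=rng.integers(1, 3), times=times)
            y = rng.normal(5.0, 1.0, len(design))
            beta = oracle_normal_equations(design, y)
            fit = dk.fit_gene(y, design)
            assert fit.k_P == pytest.approx(-beta[-2], abs=1e-10)
            assert fit.k_CI7 == pytest.approx(-beta[-1], abs=1e-10)

    def test_per_replicate_slopes_match_independent_polyfit(self):
        rng = np.random.default_rng(1)
        design = make_design()
        y = rng.normal(5.0, 1.0, len(design))
        fit = dk.fit_gene(y, design)
        for (cond, rep), grp in design.groupby([COND_COL, REP_COL]):
            sel = design.index.get_indexer(grp.index)
            slope = np.polyfit(grp[TIME_COL], y[sel], 1)[0]
            assert fit.replicate_k[f"k_{cond}_rep{rep}"] == pytest.approx(-slope, abs=1e-10)

    def test_missing_series_marks_unfittable(self):
        ds = make_dataset({"G1": (120.0, 240.0)})
        y = np.log(ds.intensities.loc["G1"]).copy()
        y[ds.design.index[(ds.design[COND_COL] == "P") & (ds.design[REP_COL] == 1)][:2]] = np.nan
        fit = dk.fit_gene(y, ds.design, gene="G1")
        assert not fit.fittable

    def test_intensity_scaling_changes_only_intercept(self):
        """Multiplying intensities by a constant leaves k and p-values unchanged."""
        rng = np.random.default_rng(3)
        design = make_design()
        base = 6.0 - 0.004 * design[TIME_COL].to_numpy() + rng.normal(0, 0.2, len(design))
        f1 = dk.fit_gene(base, design)
        f2 = dk.fit_gene(base + np.log(37.0), design)  # x37 on the intensity scale
        assert f2.k_P == pytest.approx(f1.k_P, abs=1e-12)
        assert f2.fit_pvalue == pytest.approx(f1.fit_pvalue, rel=1e-9)
        assert f2.interaction_pvalue == pytest.approx(f1.interaction_pvalue, rel=1e-9)

    def test_time_unit_rescaling_contract(self):
        """Rescaling minutes to hours multiplies k by 60, leaves p-values alone."""
        rng = np.random.default_rng(4)
        design_min = make_design()
        y = 6.0 - 0.004 * design_min[TIME_COL].to_numpy() + rng.normal(0, 0.2, len(design_min))
        design_hr = design_min.copy()
        design_hr[TIME_COL] = design_hr[TIME_COL] / 60.0
        f_min = dk.fit_gene(y, design_min)
        f_hr = dk.fit_gene(y, design_hr)
        assert f_hr.k_P == pytest.approx(60.0 * f_min.k_P, rel=1e-9)
        assert f_hr.fit_pvalue == pytest.approx(f_min.fit_pvalue, rel=1e-9)
        assert f_hr.interaction_pvalue == pytest.approx(f_min.interaction_pvalue, rel=1e-9)


class TestHalflife:
    @pytest.mark.parametrize(
        "k, expected",
        [(LN2 / 120.0, 120.0), (LN2, 1.0), (0.0, np.nan), (-0.001, np.nan)],
    )
    def test_known_values(self, k, expected):
        out = halflife(k)
        if np.isnan(expected):
            assert np.isnan(out)
        else:
            assert out == pytest.approx(expected)


class TestFitAll:
    def test_single_gene_dataset(self):
        ds = make_dataset({"G1": (120.0, 240.0)})
        fits, summary = dk.fit_all(ds)
        assert len(fits) == 1 and summary.n_total == 1

    def test_empty_dataset_rejected(self):
        ds = make_dataset({"G1": (120.0, 240.0)})
        with pytest.raises(ValueError, match="empty"):
            dk.fit_all(ds.gene_subset([]))

    def test_exponential_genes_mostly_pass_filter(self, null_sim):
        """At noise_sd 0.2, the time-effect filter keeps >95% of true exponentials."""
        _, _, _, summary = null_sim
        assert summary.n_retained / summary.n_total > 0.95

    def test_flat_genes_pass_at_type_one_rate(self):
        """All-flat profiles pass at ~alpha: the F-test's type-I error."""
        cfg = dk.SimulationConfig(
            n_genes=2000, frac_differential=0.0, frac_nonexponential=1.0,
            nonexponential_flat_frac=1.0, noise_sd=0.2, seed=3,
        )
        ds, _ = dk.simulate_timecourse(cfg)
        _, summary = dk.fit_all(ds, alpha_fit=0.05)
        frac = summary.n_retained / summary.n_total
        half_ci = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < half_ci

    def test_noiseless_recovery_exact(self):
        cfg = dk.SimulationConfig(
            n_genes=100, noise_sd=0.0, replicate_effect_sd=0.0,
            frac_differential=0.0, frac_nonexponential=0.0, n_spikeins=0, seed=1,
        )
        ds, truth = dk.simulate_timecourse(cfg)
        fits, _ = dk.fit_all(ds)
        assert (fits["k_P"] - truth.table["k_P"]).abs().max() < 1e-9

    def test_estimator_error_shrinks_with_noise(self):
        meds = []
        for noise in (0.4, 0.2, 0.05):
            cfg = dk.SimulationConfig(
                n_genes=500, noise_sd=noise, frac_differential=0.0,
                frac_nonexponential=0.0, seed=11,
            )
            ds, truth = dk.simulate_timecourse(cfg)
            fits, _ = dk.fit_all(ds)
            meds.append(((fits["k_P"] - truth.table["k_P"]).abs() / truth.table["k_P"]).median())
        assert meds[0] > meds[1] > meds[2]

    def test_spikein_normalization_removes_sample_scale(self):
        ds = make_dataset({"G1": (120.0, 240.0), "G2": (60.0, 480.0)})
        spiked = ds.intensities.copy()
        spiked.loc["SP1"] = 500.0
        spiked.loc["SP2"] = 1500.0
        flags = pd.Series([False, False, True, True], index=spiked.index)
        scale = pd.Series(
            np.linspace(0.5, 2.0, len(spiked.columns)), index=spiked.columns
        )
        distorted = dk.TimeCourseDataset(spiked * scale, ds.design, flags)
        normed = dk.spikein_normalize(distorted)
        fits_ref, _ = dk.fit_all(
            dk.TimeCourseDataset(spiked, ds.design, flags), alpha_fit=0.05
        )
        fits_norm, _ = dk.fit_all(normed, alpha_fit=0.05)
        pd.testing.assert_series_equal(fits_norm["k_P"], fits_ref["k_P"], atol=1e-12)


class TestTestDifferential:
    def test_bh_closed_form_example(self):
        """p = {.01,.02,.03,.04} with m=4 all adjust to 0.04 under step-up BH."""
        fits = pd.DataFrame(
            {
                "interaction_pvalue": [0.01, 0.02, 0.03, 0.04],
                "passed_filter": True,
                "fittable": True,
            },
            index=pd.Index(list("abcd"), name="gene"),
        )
        out = dk.test_differential(fits)
        assert np.allclose(out["interaction_qvalue"], 0.04)
        assert out["differential"].all()

    def test_qvalue_never_below_pvalue(self, planted_sim):
        _, _, fits, _ = planted_sim
        sub = fits[fits["passed_filter"]]
        assert (sub["interaction_qvalue"] >= sub["interaction_pvalue"] - 1e-12).all()

    def test_only_retained_genes_enter_family(self, planted_sim):
        _, _, fits, _ = planted_sim
        assert fits.loc[~fits["passed_filter"], "interaction_qvalue"].isna().all()
        assert not fits.loc[~fits["passed_filter"], "differential"].any()

    def test_null_simulation_false_call_fraction_controlled(self):
        """With no true differential genes, the fraction of genes falsely
        called differential stays at or below the BH level across runs."""
        false_calls = 0
        tested = 0
        for s in range(20):
            cfg = dk.SimulationConfig(
                n_genes=2000, frac_differential=0.0, frac_nonexponential=0.0,
                noise_sd=0.2, seed=s,
            )
            ds, _ = dk.simulate_timecourse(cfg)
            fits, _ = dk.fit_all(ds)
            fits = dk.test_differential(fits)
            false_calls += int(fits["differential"].sum())
            tested += int(fits["passed_filter"].sum())
        assert false_calls / tested <= 0.05

    def test_recall_monotone_in_effect_size(self):
        recalls = []
        for effect in (0.5, 1.0, 2.0):
            cfg = dk.SimulationConfig(
                n_genes=1000, frac_differential=0.1, differential_log2_effect=effect,
                frac_nonexponential=0.0, noise_sd=0.2, seed=21,
            )
            ds, truth = dk.simulate_timecourse(cfg)
            fits, _ = dk.fit_all(ds)
            fits = dk.test_differential(fits)
            planted = truth.table["differential"]
            recalls.append(fits.loc[planted, "differential"].mean())
        assert recalls[0] <= recalls[1] <= recalls[2]
        assert recalls[2] > recalls[0]

    def test_null_interaction_pvalues_uniform(self, null_sim):
        """Under equal decay in both states, interaction p-values are U(0,1)."""
        _, _, fits, _ = null_sim
        p = fits.loc[fits["passed_filter"], "interaction_pvalue"]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_empty_retained_set_warns(self):
        fits = pd.DataFrame(
            {"interaction_pvalue": [0.5], "passed_filter": [False], "fittable": [True]},
            index=pd.Index(["a"], name="gene"),
        )
        with pytest.warns(UserWarning, match="no genes passed"):
            out = dk.test_differential(fits)
        assert not out["differential"].any()


@settings(deadline=None, max_examples=20, derandomize=True)
@given(scale=st.floats(min_value=0.01, max_value=100.0), seed=st.integers(0, 10_000))
def test_equivariance_under_intensity_rescaling(scale, seed):
    """Gene-wise intensity rescaling never moves k or the p-values."""
    rng = np.random.default_rng(seed)
    design = make_design()
    y = 6.0 - 0.003 * design[TIME_COL].to_numpy() + rng.normal(0, 0.3, len(design))
    f1 = dk.fit_gene(y, design)
    f2 = dk.fit_gene(y + np.log(scale), design)
    assert f2.k_P == pytest.approx(f1.k_P, abs=1e-10)
    assert f2.k_CI7 == pytest.approx(f1.k_CI7, abs=1e-10)
    assert f2.fit_pvalue == pytest.approx(f1.fit_pvalue, rel=1e-6, abs=1e-12)
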