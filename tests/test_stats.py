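"""CIN statistics: KDE summary, permutation tests, bootstrap, model objects."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.stats import gaussian_kde

from cinquant.stats import (
    CinComparison,
    CinModel,
    CountTable,
    bootstrap_ci,
    compare_conditions,
    deviation_fraction,
    permutation_test,
    silverman_bandwidth,
    summarise,
)
from cinquant.synth import SynthConfig, generate_condition


class TestSummarise:
    def test_rounded_gaussian_fwhm_matches_analytic(self):
        # FWHM of N(46, 4) is 2*sqrt(2 ln 2)*4 = 9.42; the KDE adds its
        # bandwidth (floored at 0.8) and rounding adds 1/12 in quadrature
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            counts = np.round(rng.normal(46, 4, 5000)).astype(int)
            vals.append(summarise(counts).fwhm)
        assert np.mean(vals) == pytest.approx(9.42, abs=0.5)

    def test_degenerate_counts(self):
        s = summarise(np.full(100, 46))
        assert s.mode == 46
        assert s.deviation_fraction == 0.0

    def test_density_is_normalised(self, rng):
        counts = np.round(rng.normal(50, 6, 400)).astype(int)
        s = summarise(counts)
        assert (s.density >= 0).all()
        assert np.trapezoid(s.density, s.grid) == pytest.approx(1.0, abs=1e-6)

    def test_kde_agrees_with_scipy_at_equal_bandwidth(self, rng):
        counts = np.round(rng.normal(46, 4, 600)).astype(int)
        s = summarise(counts)
        ref = gaussian_kde(
            counts.astype(float), bw_method=s.bandwidth / counts.std(ddof=1)
        )
        assert np.max(np.abs(ref(s.grid) - s.density)) < 1e-10

    def test_deviation_fraction_equals_tally_on_mixture(self, rng):
        counts = np.concatenate(
            [np.full(1600, 46), rng.integers(30, 61, size=400)]
        )
        s = summarise(counts)
        tally = sum(1 for c in counts if abs(c - s.mode) > 2) / len(counts)
        assert s.deviation_fraction == tally

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarise(np.array([]))

    def test_shift_equivariance(self, rng):
        counts = np.round(rng.normal(46, 3, 800)).astype(int)
        s0 = summarise(counts)
        s7 = summarise(counts + 7)
        assert s7.mode == s0.mode + 7
        assert s7.fwhm == pytest.approx(s0.fwhm, abs=1e-9)
        assert s7.deviation_fraction == s0.deviation_fraction


@given(
    counts=hst.lists(hst.integers(min_value=0, max_value=100), min_size=1, max_size=80),
    mode=hst.integers(min_value=0, max_value=100),
)
@settings(max_examples=200, deadline=None)
def test_deviation_fraction_is_exact_tally(counts, mode):
    c = np.array(counts)
    assert deviation_fraction(c, mode) == np.mean(np.abs(c - mode) > 2)


class TestPermutationTest:
    def test_identical_arrays_give_p_one(self, rng):
        a = np.round(rng.normal(46, 3, 100)).astype(int)
        p = permutation_test(a, a, "deviation_fraction", n_perm=300, seed=0)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_matches_exhaustive_enumeration_tiny_samples(self):
        a = np.array([44, 46, 46, 51])
        b = np.array([46, 45, 46, 46])
        pooled = np.concatenate([a, b])

        def stat(x):
            from cinquant.stats import _statistic_fn

            return _statistic_fn("deviation_fraction")(x)

        t_obs = stat(a) - stat(b)
        n_extreme = 0
        combos = list(itertools.combinations(range(8), 4))
        for combo in combos:
            sel = np.zeros(8, dtype=bool)
            sel[list(combo)] = True
            t = stat(pooled[sel]) - stat(pooled[~sel])
            if abs(t) >= abs(t_obs) - 1e-12:
                n_extreme += 1
        exact_p = n_extreme / len(combos)
        p = permutation_test(a, b, "deviation_fraction", n_perm=8000, seed=1)
        assert p == pytest.approx(exact_p, abs=0.03)

    def test_null_p_values_roughly_uniform(self, rng):
        # quick check; the full calibration lives in the acceptance suite
        ps = []
        for _ in range(60):
            pooled = np.round(rng.normal(46, 4, 200)).astype(int)
            ps.append(
                permutation_test(
                    pooled[:100], pooled[100:], "deviation_fraction",
                    n_perm=99, seed=int(rng.integers(2**31)),
                )
            )
        assert 0.2 < np.mean(ps) < 0.8

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.array([]), np.array([46]), "fwhm")

    def test_deterministic_given_seed(self, rng):
        a = np.round(rng.normal(46, 3, 80)).astype(int)
        b = np.round(rng.normal(46, 5, 80)).astype(int)
        p1 = permutation_test(a, b, "fwhm", n_perm=200, seed=42)
        p2 = permutation_test(a, b, "fwhm", n_perm=200, seed=42)
        assert p1 == p2


class TestBootstrap:
    def test_ci_width_matches_analytic_for_mean(self, rng):
        counts = np.round(rng.normal(46, 4, 1000)).astype(int)
        lo, hi = bootstrap_ci(counts, "mean", n_boot=1000, seed=0)
        analytic = 2 * 1.96 * 4 / np.sqrt(1000)
        assert (hi - lo) == pytest.approx(analytic, rel=0.15)

    def test_degenerate_input_zero_width(self):
        lo, hi = bootstrap_ci(np.full(50, 46), "mode", n_boot=100, seed=0)
        assert (lo, hi) == (46.0, 46.0)

    def test_deterministic_given_seed(self, rng):
        counts = np.round(rng.normal(46, 4, 200)).astype(int)
        assert bootstrap_ci(counts, "fwhm", 200, seed=3) == bootstrap_ci(
            counts, "fwhm", 200, seed=3
        )


class TestModelObjects:
    def test_fit_summary_and_table_roundtrip(self, tmp_path, rng):
        table = generate_condition(
            SynthConfig(), 0.2, mn_rate=5.0, n_nuclei=2000, seed=0, condition="treated"
        )
        model = CinModel.from_count_table(table, "treated")
        res = model.fit(n_boot=200, seed=1)
        assert res.mode == 46
        assert res.ci["fwhm"][0] <= res.fwhm <= res.ci["fwhm"][1]
        text = res.summary()
        assert "modal centromere count" in text and "fwhm" in text
        p_n, p_f = table.to_csv(tmp_path / "treated")
        back = CountTable.from_csv(p_n, p_f)
        assert (back.counts() == table.counts()).all()

    def test_comparison_detects_widened_distribution(self):
        cfg = SynthConfig()
        treated = generate_condition(cfg, 0.3, mn_rate=10.0, n_nuclei=1500, seed=2,
                                     condition="treated")
        ref = generate_condition(cfg, 0.0, mn_rate=1.0, n_nuclei=1500, seed=3,
                                 condition="ref")
        res = CinComparison(treated, ref).fit(n_perm=500, n_boot=100, seed=4)
        assert res.treated.fwhm > res.reference.fwhm
        assert res.p_fwhm < 0.05
        assert res.mn_p_value is not None and res.mn_p_value < 0.05
        assert "fwhm" in res.summary()

    def test_compare_conditions_table(self):
        cfg = SynthConfig()
        tables = [
            generate_condition(cfg, r, n_nuclei=400, seed=i, condition=f"r{r}")
            for i, r in enumerate([0.0, 0.3])
        ]
        table = CountTable.concat(tables)
        df = compare_conditions(table, "r0.0", n_perm=300, n_boot=100, seed=0)
        assert set(df["condition"]) == {"r0.0", "r0.3"}
        assert np.isnan(df.loc[df["condition"] == "r0.0", "p_fwhm"]).all()

    def test_invalid_count_table_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            CountTable(nuclei=pd.DataFrame({"condition": ["a"]}))

    def test_results_plot_annotates_fwhm(self, rng):
        import matplotlib

        matplotlib.use("Agg")
        counts = np.round(rng.normal(46, 4, 300)).astype(int)
        res = CinModel(counts, condition="demo").fit(n_boot=50, seed=0)
        ax = res.plot()
        assert ax.get_xlabel() == "centromere count"
        texts = [t.get_text() for t in ax.texts]
        assert any("FWHM" in t for t in texts)
        assert len(ax.patches) > 0  # histogram bars under the KDE
        import matplotlib.pyplot as plt

        plt.close("all")
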