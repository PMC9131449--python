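"""Calculation-vs-experiment comparison tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensemblefe.compare import (
    CompoundRecord,
    compare_to_experiment,
    correlation_with_ci,
    cross_platform_agreement,
    dg_to_pic50,
    error_metrics,
    outlier_offset,
    pic50_to_dg,
    stratify_by_charge,
)
from ensemblefe.synthetic import gen_compound_set


class TestConversion:
    def test_zero_maps_to_zero(self):
        assert pic50_to_dg(0.0) == 0.0

    def test_hand_computed_value(self):
        # -R*T*ln10*pIC50 at 300 K with R = 1.9872e-3 kcal/(mol K)
        assert pic50_to_dg(6.0, 300.0) == pytest.approx(-8.236, abs=5e-4)

    def test_one_pic50_unit_at_300K(self):
        ddg = pic50_to_dg(7.0) - pic50_to_dg(6.0)
        assert ddg == pytest.approx(-1.3727, abs=1e-4)

    @given(st.floats(-20, 20))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip_identity(self, dg):
        assert pic50_to_dg(dg_to_pic50(dg)) == pytest.approx(dg, abs=1e-12)

    def test_rejects_bad_temperature(self):
        with pytest.raises(ValueError):
            pic50_to_dg(6.0, temperature_k=0.0)


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        for method in ("pearson", "spearman"):
            res = correlation_with_ci(x, y, method, n_boot=200, seed=0)
            assert res.coefficient == pytest.approx(1.0)

    def test_strictly_decreasing_spearman(self):
        x = np.arange(8.0)
        y = np.exp(-x)
        res = correlation_with_ci(x, y, "spearman", n_boot=200, seed=0)
        assert res.coefficient == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_with_ci([1, 1, 1, 1], [1, 2, 3, 4], "pearson", seed=0)

    def test_bootstrap_ci_coverage(self):
        # bivariate normal with rho = 0.8, n = 20: the 95% CI should cover
        # the true value in at least ~90% of replications
        rho, n = 0.8, 20
        cov = [[1.0, rho], [rho, 1.0]]
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(100):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            res = correlation_with_ci(xy[:, 0], xy[:, 1], "pearson",
                                      n_boot=500, seed=rng)
            hits += res.ci_low <= rho <= res.ci_high
        assert hits >= 90

    def test_fisher_z_option(self):
        x = np.arange(20.0)
        y = x + np.sin(x)
        res = correlation_with_ci(x, y, "pearson", use_fisher_z=True)
        assert res.ci_low <= res.coefficient <= res.ci_high


class TestErrorMetrics:
    def test_identical_vectors(self):
        assert error_metrics([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_symmetric_differences(self):
        mue, mse = error_metrics([0.0, 0.0], [1.0, -1.0])
        assert mue == 1.0 and mse == 0.0

    @given(st.integers(1, 30), st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=40)
    def test_matches_brute_force_loop(self, n, seed):
        rng = np.random.default_rng(seed)
        exp, calc = rng.standard_normal(n), rng.standard_normal(n)
        mue, mse = error_metrics(exp, calc)
        bm = sum(abs(c - e) for c, e in zip(calc, exp)) / n
        bs = sum(c - e for c, e in zip(calc, exp)) / n
        assert mue == pytest.approx(bm, abs=1e-12)
        assert mse == pytest.approx(bs, abs=1e-12)


class TestOutlierOffset:
    def test_mean_of_identical_oriented_discrepancies(self):
        pairs = [(("S01", "S08"), -1.0 + 3.21, -1.0),
                 (("S02", "S08"), 0.5 + 3.21, 0.5),
                 (("S03", "S08"), 2.0 + 3.21, 2.0),
                 (("S04", "S08"), -0.7 + 3.21, -0.7)]
        assert outlier_offset("S08", pairs) == pytest.approx(3.21, abs=1e-12)

    def test_from_side_sign_flip(self):
        assert outlier_offset("S08", [(("S08", "S01"), -2.0, 0.0)]) == pytest.approx(2.0)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(2)
        pairs = []
        for i in range(6):
            other = f"S{i:02d}"
            frm, to = (other, "X") if i % 2 else ("X", other)
            pairs.append(((frm, to), rng.normal(), rng.normal()))
        reversed_pairs = [((t, f), -c, -e) for (f, t), c, e in pairs]
        assert outlier_offset("X", reversed_pairs) == pytest.approx(
            outlier_offset("X", pairs), abs=1e-12
        )

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pairs = [((("A", "B"))[0:2], 0, 0)]
        pairs = []
        for i in range(8):
            frm, to = (f"C{i}", "B") if i % 3 else ("B", f"C{i}")
            pairs.append(((frm, to), float(rng.normal()), float(rng.normal())))
        expected = np.mean(
            [(c - e) if t == "B" else -(c - e) for (f, t), c, e in pairs]
        )
        assert outlier_offset("B", pairs) == pytest.approx(expected, abs=1e-12)

    def test_absent_compound_rejected(self):
        with pytest.raises(ValueError):
            outlier_offset("Z", [(("A", "B"), 1.0, 0.0)])

    def test_recovers_injected_systematic_offset(self):
        data = gen_compound_set(8, exp_noise_sd=0.0, calc_noise_sd=0.0,
                                outlier=(3, 3.21), seed=5)
        oid = data.outlier_id
        pairs = []
        for cid in data.true_dg:
            if cid == oid:
                continue
            ddg_calc = data.dg_calc[oid] - data.dg_calc[cid]
            ddg_exp = data.dg_exp[oid] - data.dg_exp[cid]
            pairs.append(((cid, oid), ddg_calc, ddg_exp))
        assert outlier_offset(oid, pairs) == pytest.approx(3.21, abs=1e-9)


class TestCrossPlatform:
    def test_identical_sets(self):
        s = {f"S{i}": (float(i), 0.5) for i in range(5)}
        res = cross_platform_agreement(s, s)
        assert res == (0.0, 0.0, 1.0, 1.0, 5)

    def test_constructed_16_of_20_within_one_se(self):
        # 16 diffs at 0.5 combined SE, 4 at 1.5: fractions (0.8, 1.0)
        se = 0.3
        comb = math.hypot(se, se)
        a, b = {}, {}
        for i in range(20):
            a[f"S{i:02d}"] = (0.0, se)
            b[f"S{i:02d}"] = ((0.5 if i < 16 else 1.5) * comb, se)
        res = cross_platform_agreement(a, b)
        assert res.frac_within_1se == pytest.approx(0.8)
        assert res.frac_within_2se == pytest.approx(1.0)

    def test_noisy_realizations_agree_within_error(self):
        rng = np.random.default_rng(9)
        truth = rng.uniform(-12, -6, size=20)
        se = 0.4
        a = {f"S{i}": (truth[i] + se * rng.standard_normal(), se) for i in range(20)}
        b = {f"S{i}": (truth[i] + se * rng.standard_normal(), se) for i in range(20)}
        res = cross_platform_agreement(a, b)
        # mean of 20 diffs each with sd sqrt(2)*se
        assert abs(res.mean_signed_diff) <= 3 * math.sqrt(2) * se / math.sqrt(20)

    def test_unmatched_ids_rejected(self):
        with pytest.raises(ValueError):
            cross_platform_agreement({"A": (0, 1)}, {"B": (0, 1)})


class TestStratifyByCharge:
    def test_flag_when_charged_more_favorable(self):
        recs = [CompoundRecord("A", 7.0, net_charge=1),
                CompoundRecord("B", 7.0, net_charge=0)]
        _, flag = stratify_by_charge(recs, {"A": -40.0, "B": -30.0})
        assert flag is True

    def test_single_stratum_flag_undefined(self):
        recs = [CompoundRecord("A", 7.0, net_charge=0),
                CompoundRecord("B", 6.0, net_charge=0)]
        summaries, flag = stratify_by_charge(recs, {"A": -8.0, "B": -7.0})
        assert flag is None and set(summaries) == {"neutral"}

    def test_recovers_charged_offset(self):
        data = gen_compound_set(40, exp_noise_sd=0.0, calc_noise_sd=0.3,
                                charged_fraction=0.5, charged_offset=-5.0, seed=8)
        summaries, flag = stratify_by_charge(data.records, data.dg_calc)
        assert flag is True
        diff = summaries["charged"].mean_calc - summaries["neutral"].mean_calc
        # mean true dG is equal across strata up to the assignment draw;
        # allow 3 SEs of the calc noise plus the truth-assignment spread
        se = math.sqrt(summaries["charged"].sd_calc**2 / summaries["charged"].n
                       + summaries["neutral"].sd_calc**2 / summaries["neutral"].n)
        assert diff == pytest.approx(-5.0, abs=3 * se)


class TestReportAndCensoring:
    def test_noise_free_set_gives_perfect_correlation(self):
        data = gen_compound_set(10, exp_noise_sd=0.0, calc_noise_sd=0.0, seed=1)
        report = compare_to_experiment(data.records, data.dg_calc, n_boot=200, seed=0)
        assert report.pearson.coefficient == pytest.approx(1.0)
        assert report.spearman.coefficient == pytest.approx(1.0)
        assert report.mue == pytest.approx(0.0, abs=1e-9)

    def test_censored_compounds_excluded_and_listed(self):
        data = gen_compound_set(8, exp_noise_sd=0.0, calc_noise_sd=0.0, seed=2)
        data.records[2].censored = True
        report = compare_to_experiment(data.records, data.dg_calc, n_boot=200, seed=0)
        assert report.excluded_ids == [data.records[2].compound_id]
        assert report.n_pairs == 7
        full = compare_to_experiment(data.records, data.dg_calc, n_boot=200, seed=0,
                                     include_censored=True)
        assert full.n_pairs == 8 and full.excluded_ids == []

    def test_dg_exp_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CompoundRecord("A", 6.0, dg_exp=-5.0)
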