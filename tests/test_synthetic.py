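"""Synthetic-data generator tests: determinism, truth bookkeeping, moments."""

import numpy as np
import pytest

from ensemblefe.alchemical import default_lambda_schedule, ti_integrate
from ensemblefe.compare import correlation_with_ci
from ensemblefe.diststats import summarize_distribution
from ensemblefe.endpoint import esmacs_estimate
from ensemblefe.synthetic import (
    AssaySpec,
    DvdlCurveSpec,
    TraceSpec,
    gen_assay_replicates,
    gen_compound_set,
    gen_replica_traces,
    gen_ti_samples,
)

MEANS = {"complex": -100.0, "protein": -60.0, "ligand": -30.0}


class TestReplicaTraces:
    def test_zero_noise_collapses_to_mean(self):
        spec = TraceSpec(mean_g=MEANS, n_replicas=3, n_frames=5,
                         frame_sd=0.0, replica_sd=0.0, seed=1)
        data = gen_replica_traces(spec)
        for traces in data.ensembles.values():
            for t in traces:
                assert np.all(t.frames == MEANS[t.role])

    def test_determinism(self):
        spec = TraceSpec(mean_g=MEANS, n_replicas=4, n_frames=10, seed=7)
        a = gen_replica_traces(spec)
        b = gen_replica_traces(spec)
        for role in a.ensembles:
            for ta, tb in zip(a.ensembles[role], b.ensembles[role]):
                assert np.array_equal(ta.frames, tb.frames)

    def test_truth_bookkeeping(self):
        data = gen_replica_traces(TraceSpec(mean_g=MEANS, seed=1))
        assert data.true_dg == pytest.approx(-10.0)

    def test_stationary_frame_sd(self):
        spec = TraceSpec(mean_g=MEANS, n_replicas=20, n_frames=2000,
                         frame_sd=2.0, replica_sd=0.0, autocorr=0.6, seed=3)
        traces = gen_replica_traces(spec, roles=["complex"]).ensembles["complex"]
        sds = [t.frames.std(ddof=1) for t in traces]
        assert np.mean(sds) == pytest.approx(2.0, rel=0.1)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TraceSpec(mean_g=MEANS, n_replicas=0)
        with pytest.raises(ValueError):
            TraceSpec(mean_g=MEANS, frame_sd=-1.0)
        with pytest.raises(ValueError):
            TraceSpec(mean_g={"solvent": 0.0})

    def test_downstream_recovery_across_seeds(self):
        hits = 0
        for seed in range(20):
            spec = TraceSpec(mean_g=MEANS, n_replicas=25, n_frames=200,
                             frame_sd=2.0, replica_sd=0.5, seed=seed)
            data = gen_replica_traces(spec)
            est = esmacs_estimate(data.ensembles["complex"], data.ensembles["protein"],
                                  data.ensembles["ligand"], seed=seed)
            hits += abs(est.value - data.true_dg) <= 3 * est.se
        assert hits >= 18


class TestTiSamples:
    def test_constant_noiseless(self):
        spec = DvdlCurveSpec(coefficients=[2.5], noise_sd=0.0, n_replicas=2,
                             n_samples_per_window=3, seed=1)
        data = gen_ti_samples(spec, default_lambda_schedule())
        for w in data.leg.windows:
            for s in w.samples.values():
                assert np.all(s == 2.5)

    def test_linear_ground_truth_integral(self):
        spec = DvdlCurveSpec(coefficients=[0.0, 2.0], noise_sd=0.0, seed=1)
        data = gen_ti_samples(spec, default_lambda_schedule())
        assert data.true_integral == pytest.approx(1.0)

    def test_determinism(self):
        spec = DvdlCurveSpec(coefficients=[1.0, -2.0, 3.0], seed=5)
        a = gen_ti_samples(spec, default_lambda_schedule())
        b = gen_ti_samples(spec, default_lambda_schedule())
        for wa, wb in zip(a.leg.windows, b.leg.windows):
            for rid in wa.samples:
                assert np.array_equal(wa.samples[rid], wb.samples[rid])

    def test_schedule_without_endpoints_rejected(self):
        spec = DvdlCurveSpec(coefficients=[1.0], seed=1)
        with pytest.raises(ValueError, match="endpoint"):
            gen_ti_samples(spec, [0.0, 0.5])

    def test_noisy_quadratic_matches_schedule_oracle(self):
        # the estimator converges to trapezoid-on-schedule of the noiseless
        # curve, not to the analytic integral (quadrature bias is separate)
        sched = default_lambda_schedule()
        oracle = np.trapezoid([3.0 * l**2 for l in sched], sched)
        spec = DvdlCurveSpec(coefficients=[0.0, 0.0, 3.0], noise_sd=0.5,
                             n_samples_per_window=400, n_replicas=5, seed=11)
        est = ti_integrate(gen_ti_samples(spec, sched).leg, seed=0)
        assert abs(est.value - oracle) <= 3 * max(est.se, 1e-3)


class TestAssayReplicates:
    def test_normal_limit(self):
        spec = AssaySpec(n=100_000, mean=0.0, sd=1.0, skewness=0.0,
                         excess_kurtosis=0.0, seed=2)
        s = summarize_distribution(gen_assay_replicates(spec).values)
        assert abs(s.skewness) < 0.05 and abs(s.excess_kurtosis) < 0.05

    @pytest.mark.parametrize("skew, exkurt", [(0.88, 1.47), (2.04, 7.56), (2.11, 5.30)])
    def test_requested_moments_recovered(self, skew, exkurt):
        # averaged over seeds: single-sample kurtosis has sd up to ~0.3 here
        sk, ku = [], []
        for seed in range(10):
            spec = AssaySpec(n=100_000, mean=7.09, sd=0.21, skewness=skew,
                             excess_kurtosis=exkurt, seed=seed)
            s = summarize_distribution(gen_assay_replicates(spec).values)
            sk.append(s.skewness)
            ku.append(s.excess_kurtosis)
        assert np.mean(sk) == pytest.approx(skew, rel=0.05)
        assert np.mean(ku) == pytest.approx(exkurt, rel=0.05)

    def test_determinism(self):
        spec = AssaySpec(n=500, mean=7.0, sd=0.2, skewness=1.0,
                         excess_kurtosis=2.0, seed=3)
        assert np.array_equal(gen_assay_replicates(spec).values,
                              gen_assay_replicates(spec).values)

    def test_infeasible_moments_rejected_with_bound(self):
        with pytest.raises(ValueError, match="skewness\\^2 - 2"):
            AssaySpec(n=10, mean=0.0, sd=1.0, skewness=3.0, excess_kurtosis=1.0)

    def test_unattainable_family_combination_rejected(self):
        # feasible in principle (above the universal bound) but outside
        # both transformed-normal families
        with pytest.raises(ValueError, match="not attainable"):
            gen_assay_replicates(
                AssaySpec(n=10, mean=0.0, sd=1.0, skewness=2.5, excess_kurtosis=4.3)
            )

    def test_drift_preserves_mean(self):
        spec = AssaySpec(n=2001, mean=7.0, sd=0.1, drift_per_index=0.002, seed=4)
        base = AssaySpec(n=2001, mean=7.0, sd=0.1, drift_per_index=0.0, seed=4)
        drifted = gen_assay_replicates(spec).values
        flat = gen_assay_replicates(base).values
        assert drifted.mean() == pytest.approx(flat.mean(), abs=1e-9)


class TestCompoundSet:
    def test_noise_free_perfect_correlation(self):
        data = gen_compound_set(12, exp_noise_sd=0.0, calc_noise_sd=0.0, seed=1)
        ids = sorted(data.true_dg)
        exp = [data.dg_exp[i] for i in ids]
        calc = [data.dg_calc[i] for i in ids]
        res = correlation_with_ci(exp, calc, "pearson", n_boot=200, seed=0)
        assert res.coefficient == pytest.approx(1.0)

    def test_outlier_injection_recorded(self):
        data = gen_compound_set(10, exp_noise_sd=0.0, calc_noise_sd=0.0,
                                outlier=(4, 3.21), seed=2)
        oid = data.outlier_id
        assert data.dg_calc[oid] - data.dg_exp[oid] == pytest.approx(3.21, abs=1e-9)

    def test_determinism(self):
        a = gen_compound_set(8, seed=6)
        b = gen_compound_set(8, seed=6)
        assert a.dg_exp == b.dg_exp and a.dg_calc == b.dg_calc

    def test_too_few_compounds_rejected(self):
        with pytest.raises(ValueError):
            gen_compound_set(2, seed=1)

    def test_correlation_ci_coverage_on_noisy_sets(self):
        # noise chosen so the population exp/calc correlation is 0.84: equal
        # noise s on both axes gives rho = sd_t^2 / (sd_t^2 + s^2), with sd_t
        # the spread of the true-dG design
        rho = 0.84
        sd_t = np.std(np.linspace(-12.0, -6.0, 20))
        s = sd_t * np.sqrt(1 / rho - 1)
        hits = 0
        for seed in range(100):
            data = gen_compound_set(20, exp_noise_sd=s, calc_noise_sd=s, seed=seed)
            ids = sorted(data.true_dg)
            res = correlation_with_ci([data.dg_exp[i] for i in ids],
                                      [data.dg_calc[i] for i in ids],
                                      "pearson", n_boot=400, seed=seed)
            hits += res.ci_low <= rho <= res.ci_high
        assert hits >= 90
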