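"""Decay-law evaluation, fitting and derived-parameter identities."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from biophoton_qc.core import DegenerateInputError, ParameterDomainError, PhotonTrace, SampleRecord
from biophoton_qc.photonics import (
    GuFit,
    compute_cps,
    derive_dl_parameters,
    fit_gu_counts,
    fit_gu_model,
    gu_bin_means,
    gu_intensity,
    normalize_intensity,
    summarize_replicate_fits,
)
from biophoton_qc.simulate import simulate_dl_trace, simulate_spe_trace

positive = st.floats(min_value=0.05, max_value=50.0, allow_nan=False)


class TestGuIntensity:
    def test_origin_equals_initial_intensity(self, canonical_params):
        # I(0) = A*csch^2(C), the defining value of I0
        A, C = canonical_params["A"], canonical_params["C"]
        assert gu_intensity(0.0, **canonical_params) == pytest.approx(A / np.sinh(C) ** 2)

    def test_reference_value(self, canonical_params):
        # direct evaluation oracle: 100/sinh^2(0.5) = 368.269...
        assert gu_intensity(0.0, **canonical_params) == pytest.approx(368.2694376831169)

    def test_decays_to_zero(self, canonical_params):
        assert gu_intensity(1e6, **canonical_params) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [dict(B=-1, C=0.5), dict(B=10, C=0.0), dict(B=0, C=1)])
    def test_domain_errors(self, bad):
        with pytest.raises(ParameterDomainError):
            gu_intensity(0.0, A=10.0, **bad)

    @given(A=positive, B=positive, C=positive)
    def test_strictly_decreasing(self, A, B, C):
        # range chosen so csch^2 stays representable in float64
        t = np.linspace(0.0, 10.0 * B, 100)
        vals = gu_intensity(t, A, B, C)
        assert np.all(np.diff(vals) < 0)


class TestBinMeans:
    def test_matches_quadrature(self, canonical_params):
        edges = np.array([0.0, 1.0, 2.0, 5.0, 50.0])
        means = gu_bin_means(edges, **canonical_params)
        for i, m in enumerate(means):
            ref, _ = quad(lambda t: gu_intensity(t, **canonical_params),
                          edges[i], edges[i + 1])
            assert m == pytest.approx(ref, rel=1e-9)

    def test_sums_telescope(self, canonical_params):
        # concatenated bins integrate exactly like one big bin
        fine = gu_bin_means(np.linspace(0, 300, 301), **canonical_params)
        coarse = gu_bin_means(np.array([0.0, 300.0]), **canonical_params)
        assert fine.sum() == pytest.approx(coarse[0], rel=1e-12)


class TestFit:
    def test_noiseless_self_consistency(self, canonical_params):
        means = gu_bin_means(np.arange(301.0), **canonical_params)
        fit = fit_gu_counts(means)
        assert fit.converged
        assert fit.A == pytest.approx(canonical_params["A"], rel=1e-6)
        assert fit.B == pytest.approx(canonical_params["B"], rel=1e-6)
        assert fit.C == pytest.approx(canonical_params["C"], rel=1e-6)

    @pytest.mark.parametrize("weighting", ["poisson", "uniform"])
    def test_scale_equivariance(self, canonical_params, weighting):
        means = gu_bin_means(np.arange(301.0), **canonical_params)
        k = 7.5
        f1 = fit_gu_counts(means, weighting=weighting)
        f2 = fit_gu_counts(k * means, weighting=weighting)
        assert f2.A == pytest.approx(k * f1.A, rel=1e-5)
        assert f2.B == pytest.approx(f1.B, rel=1e-5)
        assert f2.C == pytest.approx(f1.C, rel=1e-5)
        d1 = derive_dl_parameters(f1)
        d2 = derive_dl_parameters(f2)
        assert d2.I0 == pytest.approx(k * d1.I0, rel=1e-5)
        assert d2.Iw == pytest.approx(k * d1.Iw, rel=1e-5)
        assert d2.T == pytest.approx(d1.T, rel=1e-5)

    def test_background_is_accounted_for(self, canonical_params):
        bg = 25.0
        means = gu_bin_means(np.arange(301.0), **canonical_params) + bg
        fit = fit_gu_counts(means, background_rate=bg)
        assert fit.A == pytest.approx(canonical_params["A"], rel=1e-6)

    def test_all_zero_trace_rejected(self):
        trace = PhotonTrace("DL", np.zeros(300, dtype=int))
        with pytest.raises(DegenerateInputError):
            fit_gu_model(trace)

    def test_too_few_bins_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_gu_counts(np.ones(5))

    def test_wrong_run_kind_rejected(self):
        trace = simulate_spe_trace(10.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            fit_gu_model(trace)

    def test_replicate_summary_reports_mean_and_sd(self):
        traces = [simulate_dl_trace(1500, 10, 0.5, seed=7, sample_id=f"r{i}")
                  for i in range(3)]
        fits = [fit_gu_model(t) for t in traces]
        combined = summarize_replicate_fits(fits)
        assert combined.n_replicates == 3
        assert combined.A == pytest.approx(np.mean([f.A for f in fits]))
        assert combined.B_sd == pytest.approx(np.std([f.B for f in fits], ddof=1))

    def test_replicate_summary_requires_convergence(self):
        bad = GuFit(np.nan, np.nan, np.nan, converged=False, residual_norm=1.0)
        with pytest.raises(DegenerateInputError):
            summarize_replicate_fits([bad])


class TestDerived:
    @pytest.mark.parametrize("m", [2.0, 3.0, 4.0])
    @pytest.mark.parametrize("A,B,C", [(100, 10, 0.5), (5, 1, 2.0), (2e4, 40, 0.1)])
    def test_decay_time_defining_relation(self, A, B, C, m):
        # I(T) must equal I0/m: the closed form vs the model itself
        d = derive_dl_parameters(GuFit(A, B, C, True, 0.0), m=m)
        assert gu_intensity(d.T, A, B, C) / d.I0 == pytest.approx(1.0 / m, rel=1e-9)

    def test_decay_time_matches_root_finder(self, canonical_params):
        from scipy.optimize import brentq
        d = derive_dl_parameters(GuFit(**canonical_params, converged=True, residual_norm=0))
        f = lambda t: gu_intensity(t, **canonical_params) - d.I0 / 3.0
        assert d.T == pytest.approx(brentq(f, 1e-9, 100.0, xtol=1e-12), rel=1e-9)

    def test_reference_values(self, canonical_params):
        # frozen oracle values: root-find for T, quadrature for Iw
        d = derive_dl_parameters(GuFit(**canonical_params, converged=True, residual_norm=0))
        assert d.T == pytest.approx(3.10771189, rel=1e-6)
        assert d.Iw == pytest.approx(3.87984471, rel=1e-6)

    def test_window_mean_matches_quadrature(self, canonical_params):
        d = derive_dl_parameters(GuFit(**canonical_params, converged=True, residual_norm=0))
        ref, _ = quad(lambda t: gu_intensity(t, **canonical_params), 0.0, 300.0)
        assert d.Iw == pytest.approx(ref / 300.0, rel=1e-6)

    def test_window_mean_below_initial(self, canonical_params):
        d = derive_dl_parameters(GuFit(**canonical_params, converged=True, residual_norm=0))
        assert 0.0 < d.Iw < d.I0

    def test_nonconverged_fit_refused(self):
        fit = GuFit(np.nan, np.nan, np.nan, converged=False, residual_norm=1.0)
        with pytest.raises(ValueError):
            derive_dl_parameters(fit)

    def test_m_outside_range_rejected(self, canonical_params):
        fit = GuFit(**canonical_params, converged=True, residual_norm=0)
        with pytest.raises(ParameterDomainError):
            derive_dl_parameters(fit, m=5.0)


class TestCps:
    def _trace(self, counts, kind):
        return PhotonTrace(kind, np.asarray(counts, dtype=int))

    def test_equal_rates_give_zero(self):
        spe = self._trace([30] * 10, "SPE")
        bg = self._trace([30] * 10, "background")
        assert compute_cps(spe, bg).cps == 0.0

    def test_arithmetic(self):
        spe = self._trace([150] * 10, "SPE")
        bg = self._trace([30] * 10, "background")
        s = compute_cps(spe, bg)
        assert (s.N, s.n, s.cps) == (150.0, 30.0, 120.0)
        assert not s.negative

    def test_negative_flagged_not_clamped(self):
        spe = self._trace([10] * 10, "SPE")
        bg = self._trace([30] * 10, "background")
        s = compute_cps(spe, bg)
        assert s.cps == -20.0 and s.negative

    def test_null_sample_centered_at_zero(self):
        # Poisson-difference oracle: zero-rate sample gives mean-zero CPS
        vals = [compute_cps(simulate_spe_trace(0.0, 30.0, seed=s, sample_id=f"n{s}"),
                            simulate_spe_trace(0.0, 30.0, seed=s, sample_id=f"n{s}",
                                               run_kind="background")).cps
                for s in range(200)]
        se = np.sqrt(2 * 30.0 / 600)   # var of a difference of two 600-bin means
        assert abs(np.mean(vals)) < 3 * se / np.sqrt(200)

    def test_bin_width_mismatch_rejected(self):
        spe = PhotonTrace("SPE", np.array([1, 2]), bin_width=1.0)
        bg = PhotonTrace("background", np.array([1, 2]), bin_width=2.0)
        with pytest.raises(ValueError):
            compute_cps(spe, bg)


class TestNormalize:
    def test_identity(self):
        s = SampleRecord("x", "control", mass=1.0, thickness=1.0)
        assert normalize_intensity(42.0, s) == 42.0

    def test_arithmetic(self):
        s = SampleRecord("x", "control", mass=0.5, thickness=0.4)
        assert normalize_intensity(120.0, s) == pytest.approx(96.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ParameterDomainError):
            SampleRecord("x", "control", mass=0.0, thickness=0.4)
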