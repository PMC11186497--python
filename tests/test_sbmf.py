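"""SBMF constants, spectral density, distance conversion and tau1 fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pre2restraints.constants import PhysicalConstants, kappa_h, mq_pre_factor
from pre2restraints.pre_extraction import PREMeasurement
from pre2restraints.sbmf import (
    SBMFParameters,
    TagSite,
    back_calculate_pre_profile,
    distance_from_gamma2,
    ensemble_r6_distance,
    fit_correlation_time,
    gamma2_from_distance,
    j_sbmf,
)
from pre2restraints.synthetic import attach_tag, make_toy_complex


class TestKappa:
    def test_conventional_prefactor(self):
        # spin-only g = 2 reproduces the classic PRE constant
        assert kappa_h() / 1e16 == pytest.approx(1.2311, abs=5e-5)

    def test_si_units(self):
        assert kappa_h(in_si=True) == pytest.approx(1.2311e-44, rel=1e-4)

    def test_codata_g_factor_variant(self):
        # the CODATA free-electron g-factor shifts kappa by (g/2)^2 ~ +0.23%
        k = PhysicalConstants.codata2018().kappa_h()
        assert k / 1e16 == pytest.approx(1.2339, abs=5e-5)

    def test_carbon_scaling(self):
        c = PhysicalConstants()
        ratio = c.with_gamma(c.gamma_c).kappa_h() / c.kappa_h()
        assert ratio == pytest.approx((c.gamma_c / c.gamma_h) ** 2, rel=1e-12)
        assert ratio == pytest.approx(0.0632, abs=1e-4)

    def test_mq_factor(self):
        assert mq_pre_factor() == pytest.approx(1.063, abs=5e-4)


class TestSpectralDensity:
    def test_zero_frequency_closed_form(self):
        p = SBMFParameters(tau_1=20e-9, tau_i=1e-9, s2=0.8)
        expected = 0.8 * 20e-9 + 0.2 * p.tau_t
        assert j_sbmf(0.0, p) == pytest.approx(expected, rel=1e-12)
        assert j_sbmf(0.0, p) == pytest.approx(1.619e-8, rel=1e-3)

    def test_rigid_limit(self):
        p = SBMFParameters(tau_1=20e-9, s2=1.0)
        w = 1e9
        assert j_sbmf(w, p) == pytest.approx(20e-9 / (1 + (w * 20e-9) ** 2), rel=1e-12)

    def test_tau_t_combination(self):
        p = SBMFParameters(tau_1=20e-9, tau_i=1e-9)
        assert p.tau_t == pytest.approx(1.0 / (1 / 20e-9 + 1 / 1e-9), rel=1e-12)
        assert p.tau_t <= p.tau_1

    @given(w=st.floats(0.0, 1e11))
    def test_monotone_below_zero_frequency(self, w):
        p = SBMFParameters(tau_1=20e-9, tau_i=2e-9, s2=0.7)
        assert j_sbmf(0.0, p) >= j_sbmf(w, p)


class TestDistanceConversion:
    def test_hand_value_at_20A(self, sbmf_params):
        assert gamma2_from_distance(20.0, sbmf_params) == pytest.approx(15.39, abs=0.01)

    def test_r6_scaling(self, sbmf_params):
        g1 = gamma2_from_distance(20.0, sbmf_params)
        g2 = gamma2_from_distance(10.0, sbmf_params)
        assert g2 / g1 == pytest.approx(64.0, rel=1e-12)

    def test_low_field_limit(self):
        p = SBMFParameters(tau_1=20e-9, field_mhz=1e-6)
        expected = p.constants.kappa_h() / 20.0**6 * 20e-9 * 7.0
        assert gamma2_from_distance(20.0, p) == pytest.approx(expected, rel=1e-6)

    @given(r=st.floats(5.0, 60.0))
    def test_round_trip_identity(self, r):
        p = SBMFParameters()
        g = gamma2_from_distance(r, p)
        assert distance_from_gamma2(g, p) == pytest.approx(r, rel=1e-9)

    def test_gamma_scaling_halves_distance(self, sbmf_params):
        g = gamma2_from_distance(20.0, sbmf_params)
        assert distance_from_gamma2(64 * g, sbmf_params) == pytest.approx(10.0, rel=1e-9)

    def test_monotone_decreasing(self, sbmf_params):
        d = [distance_from_gamma2(g, sbmf_params) for g in (1.0, 10.0, 100.0)]
        assert d[0] > d[1] > d[2]

    def test_nonpositive_gamma_rejected(self, sbmf_params):
        with pytest.raises(ValueError):
            distance_from_gamma2(0.0, sbmf_params)


class TestBackCalculation:
    def _tag(self, conformers):
        return TagSite("X1C", ("A", 1, "CB"), tuple(conformers))

    def test_single_conformer_matches_direct(self, toy_truth, sbmf_params):
        model = toy_truth.complex_model
        pos = model.position("B", 3, "N")
        tag = self._tag([(pos[0] - 18.0, pos[1], pos[2])])
        rates, skipped = back_calculate_pre_profile(model, tag, [("B", 3, "N")], sbmf_params)
        assert not skipped
        assert rates[0] == pytest.approx(gamma2_from_distance(18.0, sbmf_params), rel=1e-9)

    def test_two_conformer_r6_average(self, toy_truth, sbmf_params):
        model = toy_truth.complex_model
        pos = model.position("B", 3, "N")
        tag = self._tag(
            [(pos[0] - 15.0, pos[1], pos[2]), (pos[0] + 25.0, pos[1], pos[2])]
        )
        expected = (
            sbmf_params.constants.kappa_h()
            * (15.0**-6 + 25.0**-6) / 2
            * sbmf_params.tau_1
            * (4 + 3 / (1 + (sbmf_params.omega_h * sbmf_params.tau_1) ** 2))
        )
        rates, _ = back_calculate_pre_profile(model, tag, [("B", 3, "N")], sbmf_params)
        assert rates[0] == pytest.approx(expected, rel=1e-9)

    def test_distant_conformer_negligible(self, sbmf_params, toy_truth):
        model = toy_truth.complex_model
        pos = model.position("B", 3, "N")
        near = [(pos[0] - 15.0, pos[1], pos[2]), (pos[0] - 20.0, pos[1], pos[2])]
        far = near + [(pos[0] - 70.0, pos[1], pos[2])]
        r_near, _ = back_calculate_pre_profile(model, self._tag(near), [("B", 3, "N")], sbmf_params)
        r_far, _ = back_calculate_pre_profile(model, self._tag(far), [("B", 3, "N")], sbmf_params)
        # <r^-6> mean changes through the 1/n normalisation, but the far
        # conformer's own contribution to the sum is negligible
        assert abs(r_far[0] * 3 / 2 - r_near[0]) / r_near[0] < 0.02

    def test_unresolvable_probe_skipped(self, toy_truth, sbmf_params):
        tag = self._tag([(0.0, 0.0, -20.0)])
        rates, skipped = back_calculate_pre_profile(
            toy_truth.complex_model, tag, [("B", 999, "N")], sbmf_params
        )
        assert skipped == [("B", 999, "N")] and math.isnan(rates[0])

    def test_effective_distance_definition(self):
        tag = self._tag([(0.0, 0.0, 10.0), (0.0, 0.0, -10.0)])
        r = ensemble_r6_distance(tag, np.zeros(3))
        assert r == pytest.approx(10.0, rel=1e-12)


def _noisy_measurements(truth, params, noise, seed):
    rng = np.random.default_rng(seed)
    tag = truth.tag_sites[0]
    out = []
    for (site, chain, resnum, probe), g in truth.true_gamma2.items():
        if site != tag.site_id:
            continue
        out.append(
            PREMeasurement(
                probe_id=(chain, resnum, probe), tag_site=site,
                gamma2_h=max(g * (1 + noise * rng.standard_normal()), 1e-3),
            )
        )
    return out


class TestCorrelationTimeFit:
    def _truth(self, n_b=50, seed=0):
        from pre2restraints.pre_extraction import AcquisitionSettings
        from pre2restraints.synthetic import simulate_pre_dataset

        truth = make_toy_complex(n_residues_a=30, n_residues_b=n_b, seed=seed)
        attach_tag(truth, "A", 15)
        simulate_pre_dataset(truth, AcquisitionSettings(), noise_sigma=0.0, seed=seed)
        return truth

    def test_noiseless_self_consistency(self, sbmf_params):
        truth = self._truth()
        measurements = _noisy_measurements(truth, sbmf_params, 0.0, 0)
        tau, err, resid = fit_correlation_time(
            measurements, truth.complex_model, truth.tag_sites[0], sbmf_params,
            n_bootstrap=0,
        )
        assert abs(tau - 20e-9) < 0.1e-9

    def test_bounds_respected(self, sbmf_params):
        truth = self._truth()
        # truth generated at 20 ns, fit confined to a window excluding it
        measurements = _noisy_measurements(truth, sbmf_params, 0.0, 0)
        tau, _, _ = fit_correlation_time(
            measurements, truth.complex_model, truth.tag_sites[0], sbmf_params,
            bounds=(5e-9, 10e-9), n_bootstrap=0,
        )
        assert 5e-9 <= tau <= 10e-9

    def test_all_unquantified_rejected(self, sbmf_params, toy_truth):
        bad = [
            PREMeasurement(probe_id=("B", i, "N"), status="bleached")
            for i in range(1, 8)
        ]
        with pytest.raises(ValueError):
            fit_correlation_time(
                bad, toy_truth.complex_model, toy_truth.tag_sites[0], sbmf_params
            )

    def test_noisy_recovery_median_within_2ns(self, sbmf_params):
        truth = self._truth()
        errors = []
        for seed in range(20):
            measurements = _noisy_measurements(truth, sbmf_params, 0.10, seed)
            tau, _, _ = fit_correlation_time(
                measurements, truth.complex_model, truth.tag_sites[0], sbmf_params,
                bounds=(5e-9, 40e-9), n_bootstrap=0,
            )
            errors.append(abs(tau - 20e-9))
        assert np.median(errors) < 2e-9
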