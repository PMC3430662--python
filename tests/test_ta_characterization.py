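"""Tendon/aponeurosis strain computation, quadratic fits and T-A combination."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tahill.errors import (DegenerateTrialError, InconsistentGeometryError,
                           InvalidGeometryError, MonotoneViolationError,
                           RankDeficiencyError)
from tahill.ta_characterization import (CurveKind, ForceStrainCurve,
                                        StrainSample, aponeurosis_length,
                                        aponeurosis_strain, combine_ta_curve,
                                        fit_force_strain, normalized_force,
                                        ta_ratio, tendon_strain)


class TestStrains:
    def test_identity_and_arithmetic(self):
        assert tendon_strain(200.0, 200.0) == 0.0
        assert tendon_strain(210.0, 200.0) == pytest.approx(0.05, abs=1e-15)
        assert aponeurosis_strain(220.0, 220.0) == 0.0
        assert aponeurosis_strain(231.0, 220.0) == pytest.approx(0.05, abs=1e-15)

    def test_elementwise_matches_scalar_recomputation(self):
        rng = np.random.default_rng(0)
        lengths = rng.uniform(180.0, 260.0, 64)
        rest = 205.3
        series = tendon_strain(lengths, rest)
        oracle = np.array([(l - rest) / rest for l in lengths])
        np.testing.assert_allclose(series, oracle, atol=1e-12)

    @pytest.mark.parametrize("func", [tendon_strain, aponeurosis_strain])
    def test_nonpositive_rest_length_rejected(self, func):
        with pytest.raises(InvalidGeometryError):
            func(np.array([200.0]), 0.0)


class TestAponeurosisLength:
    def test_collinear_limit(self):
        assert aponeurosis_length(400.0, 150.0, 50.0, 0.0) == pytest.approx(200.0)

    def test_rest_geometry_round_trip(self):
        # medial gastrocnemius rest values: the series-path model must return
        # the aponeurosis length the muscle-tendon length was built from
        pen = math.radians(19.4)
        mt = 209.9 + 219.3 + 59.5 * math.cos(pen)
        assert aponeurosis_length(mt, 209.9, 59.5, pen) == pytest.approx(
            219.3, abs=1e-9)

    def test_forward_construct_oracle(self):
        rng = np.random.default_rng(1)
        lt = rng.uniform(60, 230, 32)
        la = rng.uniform(150, 230, 32)
        lf = rng.uniform(40, 80, 32)
        pen = rng.uniform(0.1, 0.5, 32)
        mt = lt + la + lf * np.cos(pen)
        np.testing.assert_allclose(aponeurosis_length(mt, lt, lf, pen), la,
                                   atol=1e-9)

    def test_inconsistent_geometry_names_index(self):
        mt = np.array([400.0, 100.0])
        with pytest.raises(InconsistentGeometryError, match="index 1"):
            aponeurosis_length(mt, 150.0, 50.0, 0.0)


class TestNormalizedForce:
    def test_examples(self):
        np.testing.assert_allclose(normalized_force([0.0, 50.0, 100.0]),
                                   [0.0, 0.5, 1.0])
        np.testing.assert_allclose(normalized_force([7.0, 7.0, 7.0]),
                                   [1.0, 1.0, 1.0])

    def test_maximum_is_exactly_one(self):
        rng = np.random.default_rng(2)
        out = normalized_force(rng.uniform(1.0, 90.0, 100))
        assert out.max() == 1.0

    def test_degenerate_series_rejected(self):
        with pytest.raises(DegenerateTrialError):
            normalized_force([0.0, 0.0])
        with pytest.raises(DegenerateTrialError):
            normalized_force([-5.0, -1.0])


def _samples_from_quadratic(c2, c1, strains, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    f = c2 * strains**2 + c1 * strains + rng.normal(0.0, noise, strains.size)
    return [StrainSample(normalized_force=float(np.clip(fv, 0, 1)),
                         tendon_strain=float(e))
            for fv, e in zip(f, strains)]


class TestFitForceStrain:
    def test_noiseless_quadratic_is_exact(self):
        eps = np.linspace(0.0, 0.1, 20)
        curve = fit_force_strain(_samples_from_quadratic(10.0, 5.0, eps),
                                 CurveKind.TENDON)
        assert curve.c2 == pytest.approx(10.0, abs=1e-9)
        assert curve.c1 == pytest.approx(5.0, abs=1e-9)
        assert curve.coefficients[2] == 0.0

    def test_all_zero_strain_is_rank_deficient(self):
        samples = [StrainSample(normalized_force=f, tendon_strain=0.0)
                   for f in np.linspace(0, 1, 8)]
        with pytest.raises(RankDeficiencyError):
            fit_force_strain(samples, CurveKind.TENDON)

    def test_noisy_recovery_within_three_standard_errors(self):
        c2, c1, sigma, n = 60.0, 4.0, 0.01, 50
        eps = np.linspace(0.001, 0.095, n)
        curve = fit_force_strain(
            _samples_from_quadratic(c2, c1, eps, noise=sigma, seed=3),
            CurveKind.TENDON)
        design = np.column_stack([eps**2, eps])
        cov = sigma**2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        assert abs(curve.c2 - c2) < 3 * se[0]
        assert abs(curve.c1 - c1) < 3 * se[1]

    def test_coefficient_bias_shrinks_with_sample_size(self):
        c2, c1, sigma = 60.0, 4.0, 0.01
        errs = []
        for n in (50, 5000):
            eps = np.linspace(0.001, 0.095, n)
            curve = fit_force_strain(
                _samples_from_quadratic(c2, c1, eps, noise=sigma, seed=4),
                CurveKind.TENDON)
            errs.append(abs(curve.c2 - c2) + abs(curve.c1 - c1))
        assert errs[1] < errs[0]

    def test_decreasing_data_raises_monotone_violation(self):
        eps = np.linspace(0.0, 0.1, 10)
        samples = [StrainSample(normalized_force=float(f), tendon_strain=float(e))
                   for f, e in zip(1.0 - 10 * eps, eps)]
        with pytest.raises(MonotoneViolationError):
            fit_force_strain(samples, CurveKind.TENDON)


class TestTaRatio:
    @pytest.mark.parametrize("lt, la, expected", [
        (222.1, 194.0, 0.53),   # lateral gastrocnemius rest means
        (209.9, 219.3, 0.49),   # medial gastrocnemius
        (61.4, 217.8, 0.22),    # soleus
    ])
    def test_rest_mean_ratios(self, lt, la, expected):
        assert round(ta_ratio(lt, la), 2) == expected

    def test_equal_lengths_give_half(self):
        assert ta_ratio(123.4, 123.4) == 0.5

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidGeometryError):
            ta_ratio(0.0, 100.0)


@pytest.fixture
def tendon_apo_curves():
    tendon = ForceStrainCurve(CurveKind.TENDON, c2=86.4, c1=3.33, eps_max=0.09)
    apo = ForceStrainCurve(CurveKind.APONEUROSIS, c2=240.1, c1=5.56,
                           eps_max=0.054)
    return tendon, apo


class TestCombineTaCurve:
    def test_ratio_near_one_recovers_tendon(self, tendon_apo_curves):
        tendon, apo = tendon_apo_curves
        combined = combine_ta_curve(tendon, apo, 1.0 - 1e-9)
        grid = np.linspace(0.05, 1.0, 9)
        np.testing.assert_allclose(combined.strain_at(grid),
                                   tendon.strain_at(grid), rtol=1e-4)

    def test_midpoint_strain(self, tendon_apo_curves):
        tendon, apo = tendon_apo_curves
        f = 0.6
        expected = 0.5 * (tendon.strain_at(f) + apo.strain_at(f))
        combined = combine_ta_curve(tendon, apo, 0.5)
        assert combined.strain_at(f) == pytest.approx(expected, rel=2e-3)

    def test_series_spring_elongation_oracle(self, tendon_apo_curves):
        # two springs in series sharing one force: the rest-length-weighted
        # strain combination must equal total elongation / total rest length
        tendon, apo = tendon_apo_curves
        lt0, la0 = 209.9, 219.3
        r = lt0 / (lt0 + la0)
        for f in np.linspace(0.0, 1.0, 11):
            eps_t, eps_a = tendon.strain_at(f), apo.strain_at(f)
            dlt, dla = eps_t * lt0, eps_a * la0
            series_strain = (dlt + dla) / (lt0 + la0)
            assert r * eps_t + (1 - r) * eps_a == pytest.approx(
                series_strain, abs=1e-12)

    @given(ratio=st.floats(0.05, 0.95))
    def test_combined_curve_is_compliance_intermediate(self, ratio):
        tendon = ForceStrainCurve(CurveKind.TENDON, c2=86.4, c1=3.33,
                                  eps_max=0.09)
        apo = ForceStrainCurve(CurveKind.APONEUROSIS, c2=240.1, c1=5.56,
                               eps_max=0.054)
        combined = combine_ta_curve(tendon, apo, ratio)
        for f in np.linspace(0.1, 1.0, 7):
            lo = min(tendon.strain_at(f), apo.strain_at(f))
            hi = max(tendon.strain_at(f), apo.strain_at(f))
            assert lo - 1e-6 <= combined.strain_at(f) <= hi + 1e-6

    def test_force_grid_outside_unit_interval_rejected(self, tendon_apo_curves):
        tendon, apo = tendon_apo_curves
        with pytest.raises(ValueError):
            combine_ta_curve(tendon, apo, 0.5, force_grid=[0.0, 1.2])


class TestForceStrainCurve:
    def test_passes_through_origin_and_monotone(self, tendon_apo_curves):
        tendon, _ = tendon_apo_curves
        assert tendon.force(0.0) == 0.0
        grid = np.linspace(0.0, tendon.eps_max, 50)
        assert np.all(np.diff(tendon.force(grid)) > 0)

    def test_inverse_round_trip(self, tendon_apo_curves):
        tendon, _ = tendon_apo_curves
        forces = np.linspace(0.0, 1.0, 21)
        np.testing.assert_allclose(tendon.force(tendon.strain_at(forces)),
                                   forces, atol=1e-10)

    def test_tangent_extrapolation_is_monotone_clamp_is_flat(self):
        c = ForceStrainCurve(CurveKind.TENDON, c2=50.0, c1=2.0, eps_max=0.05)
        beyond = c.force(0.08)
        assert beyond > c.force(0.05)
        cc = ForceStrainCurve(CurveKind.TENDON, c2=50.0, c1=2.0, eps_max=0.05,
                              extrapolation="clamp")
        assert cc.force(0.08) == pytest.approx(cc.force(0.05))

    def test_non_monotone_coefficients_rejected(self):
        with pytest.raises(MonotoneViolationError):
            ForceStrainCurve(CurveKind.TENDON, c2=-100.0, c1=1.0, eps_max=0.09)
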