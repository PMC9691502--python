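"""Forward map (noise ACF -> SCCs), closed-form families, inverse map,
sum rule, DC power, parameter estimation and pattern classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynthresh import (
    ARNoiseSpec,
    DomainError,
    ISIStats,
    NoiseACF,
    ParameterError,
    PatternLabel,
    SCCSequence,
    UnfittablePatternError,
    acf_ar1,
    acf_from_scc,
    classify_pattern,
    dc_power,
    estimate_a,
    limiting_sum,
    scc_from_acf,
    scc_type1,
    scc_type2,
)
from .conftest import random_psd_acf


class TestForwardMap:
    def test_white_noise_gives_degenerate_pattern(self):
        acf = NoiseACF(np.array([2.0, 0.0, 0.0, 0.0, 0.0]))
        sccs = scc_from_acf(acf)
        assert sccs.rho[0] == 1.0
        assert sccs.rho[1] == pytest.approx(-0.5)
        np.testing.assert_allclose(sccs.rho[2:], 0.0, atol=1e-15)

    def test_type1_acf_reproduces_closed_form(self):
        acf = acf_ar1(ARNoiseSpec(a=0.4, sign=+1, r0=1.0), K=6)
        sccs = scc_from_acf(acf, K=4)
        np.testing.assert_allclose(
            sccs.rho[1:4], [-0.3, -0.12, -0.048], rtol=1e-12
        )

    def test_type2_acf_reproduces_closed_form(self):
        acf = acf_ar1(ARNoiseSpec(a=0.69, sign=-1, r0=1.0), K=6)
        sccs = scc_from_acf(acf, K=3)
        np.testing.assert_allclose(
            sccs.rho[1:3], [-0.845, 0.58305], rtol=1e-12
        )

    def test_scale_invariance(self, rng):
        r = random_psd_acf(rng, K=12)
        a = scc_from_acf(NoiseACF(r))
        b = scc_from_acf(NoiseACF(17.3 * r))
        np.testing.assert_allclose(a.rho, b.rho, rtol=1e-12)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(DomainError):
            scc_from_acf(NoiseACF(np.array([1.0, 1.0, 0.5, 0.2])))

    def test_separability_identity(self, rng):
        # rho_1 = -1/2 + (R_1 - R_2)/(2 (R_0 - R_1)) for every ACF
        r = random_psd_acf(rng, K=6)
        sccs = scc_from_acf(NoiseACF(r), K=1)
        expected = -0.5 + (r[1] - r[2]) / (2.0 * (r[0] - r[1]))
        assert sccs.rho[1] == pytest.approx(expected, rel=1e-12)

    def test_telescoping_partial_sums(self, rng):
        # sum_{k=1..K} rho_k = -(R0 - R1 - RK + R_{K+1}) / (2 (R0 - R1))
        r = random_psd_acf(rng, K=20)
        sccs = scc_from_acf(NoiseACF(r), K=19)
        sums = limiting_sum(sccs)
        for K in range(1, 20):
            expected = -(r[0] - r[1] - r[K] + r[K + 1]) / (2 * (r[0] - r[1]))
            assert sums[K - 1] == pytest.approx(expected, rel=1e-10, abs=1e-12)


class TestClosedFormFamilies:
    def test_type1_hand_values_and_shape(self):
        sccs = scc_type1(0.4, K=5)
        np.testing.assert_allclose(
            sccs.rho[1:4], [-0.3, -0.12, -0.048], rtol=1e-12
        )
        assert np.all(sccs.rho[1:] < 0)
        assert np.all(np.diff(sccs.rho[1:]) > 0)  # increasing toward 0

    def test_type2_hand_values_and_alternation(self):
        sccs = scc_type2(0.69, K=5)
        np.testing.assert_allclose(
            sccs.rho[1:4], [-0.845, 0.58305, -0.4023045], rtol=1e-12
        )
        signs = np.sign(sccs.rho[1:])
        np.testing.assert_allclose(signs, [-1, 1, -1, 1, -1])

    def test_type1_small_a_limit_is_type3(self):
        sccs = scc_type1(1e-9, K=3)
        assert sccs.rho[1] == pytest.approx(-0.5, abs=1e-9)
        assert abs(sccs.rho[2]) < 1e-9

    @pytest.mark.parametrize("family", [scc_type1, scc_type2])
    def test_geometric_ratio_constant(self, family):
        sccs = family(0.35, K=10)
        ratios = sccs.rho[2:] / sccs.rho[1:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    @pytest.mark.parametrize("family", [scc_type1, scc_type2])
    @pytest.mark.parametrize("bad_a", [0.0, 1.0, -0.2, 1.5])
    def test_a_outside_open_interval_rejected(self, family, bad_a):
        with pytest.raises(ParameterError):
            family(bad_a, K=3)


class TestInverseMap:
    def test_degenerate_pattern_inverts_to_white_noise(self):
        sccs = SCCSequence(np.array([1.0, -0.5, 0.0, 0.0, 0.0]))
        result = acf_from_scc(sccs)
        np.testing.assert_allclose(result.acf.values[0], 1.0)
        np.testing.assert_allclose(result.acf.values[1:], 0.0, atol=1e-12)
        assert result.residual == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "a,sign", [(0.2, +1), (0.4, +1), (0.69, +1), (0.2, -1), (0.4, -1), (0.69, -1)]
    )
    def test_round_trip_recovers_ar1_acf(self, a, sign):
        K = 50
        acf = acf_ar1(ARNoiseSpec(a=a, sign=sign, r0=3.7), K + 1)
        sccs = scc_from_acf(acf, K=K)
        result = acf_from_scc(sccs, K=K)
        expected = (sign * a) ** np.arange(K + 1)
        np.testing.assert_allclose(result.acf.values[: K + 1], expected, atol=1e-8)
        assert result.residual < 1e-6

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        a=st.floats(min_value=0.05, max_value=0.9),
        sign=st.sampled_from([-1, +1]),
    )
    def test_round_trip_property(self, a, sign):
        K = 60
        acf = acf_ar1(ARNoiseSpec(a=a, sign=sign, r0=1.0), K + 1)
        sccs = scc_from_acf(acf, K=K)
        result = acf_from_scc(sccs, K=K)
        expected = (sign * a) ** np.arange(K + 1)
        tail = a ** (K + 1)
        np.testing.assert_allclose(
            result.acf.values[: K + 1], expected, atol=max(1e-8, 3 * tail)
        )

    def test_residual_flags_inconsistent_sum(self):
        # rho_1 = -0.3 alone sums to -0.3 != -0.5: residual must not vanish
        sccs = SCCSequence(np.array([1.0, -0.3, 0.0, 0.0]))
        result = acf_from_scc(sccs)
        assert result.residual > 1e-3


class TestEstimateA:
    def test_type1_lag1_inversion(self):
        sccs = scc_type1(0.4, K=3)
        a, clipped = estimate_a(sccs, method="rho1", pattern=PatternLabel.TYPE_I)
        assert a == pytest.approx(0.4, rel=1e-12) and not clipped

    def test_type2_lag1_inversion(self):
        sccs = scc_type2(0.69, K=3)
        a, _ = estimate_a(sccs, method="rho1", pattern=PatternLabel.TYPE_II)
        assert a == pytest.approx(0.69, rel=1e-12)

    @pytest.mark.parametrize(
        "family,pattern", [(scc_type1, PatternLabel.TYPE_I), (scc_type2, PatternLabel.TYPE_II)]
    )
    def test_ratio_method(self, family, pattern):
        sccs = family(0.4, K=3)
        a, _ = estimate_a(sccs, method="ratio", pattern=pattern)
        assert a == pytest.approx(0.4, rel=1e-12)

    def test_type3_ratio_is_undefined(self):
        sccs = SCCSequence(np.array([1.0, -0.5, 0.0]))
        with pytest.raises(UnfittablePatternError):
            estimate_a(sccs, method="ratio", pattern=PatternLabel.TYPE_III)

    def test_clipping_flagged(self):
        # ratio above 1 (invalid magnitude) must clip and flag
        sccs = SCCSequence(np.array([1.0, -0.1, -0.2]), kind="estimated")
        a, clipped = estimate_a(sccs, method="ratio", pattern=PatternLabel.TYPE_I)
        assert clipped and 0.0 <= a < 1.0


class TestSumRuleAndDCPower:
    def test_type3_partial_sum_constant(self):
        sccs = SCCSequence(np.array([1.0, -0.5, 0.0, 0.0, 0.0]))
        sums = limiting_sum(sccs)
        np.testing.assert_allclose(sums, -0.5, rtol=1e-15)

    @pytest.mark.parametrize("family,a", [(scc_type1, 0.4), (scc_type2, 0.69)])
    def test_closed_form_sums_to_minus_half(self, family, a):
        sums = limiting_sum(family(a, K=1000))
        assert sums[-1] == pytest.approx(-0.5, abs=1e-6)

    def test_arbitrary_decorrelating_acf_sums_to_minus_half(self, rng):
        # damp a random PSD ACF so R_40 ~ 0, then the sum telescopes to -1/2
        r = random_psd_acf(rng, K=41) * 0.75 ** np.arange(42)
        sums = limiting_sum(scc_from_acf(NoiseACF(r), K=40))
        assert sums[-1] == pytest.approx(-0.5, abs=0.005)

    def test_dc_block_when_sum_is_minus_half(self):
        stats = ISIStats(t1=2.42, v1=(0.3 * 2.42) ** 2)
        sccs = SCCSequence(np.array([1.0, -0.5, 0.0]))
        assert dc_power(stats, sccs) == pytest.approx(0.0, abs=1e-15)

    def test_renewal_level(self):
        stats = ISIStats(t1=2.42, v1=(0.3 * 2.42) ** 2)
        sccs = SCCSequence(np.array([1.0, 0.0, 0.0]))
        assert dc_power(stats, sccs) == pytest.approx(0.09 / (2 * np.pi * 2.42))

    def test_partial_dc_leakage(self):
        stats = ISIStats(t1=2.42, v1=(0.3 * 2.42) ** 2)
        sccs = SCCSequence(np.array([1.0, -0.475]))
        expected = 0.09 / (2 * np.pi * 2.42) * 0.05
        assert dc_power(stats, sccs) == pytest.approx(expected, rel=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "rho,expected",
        [
            ([1.0, -0.3, -0.12, -0.05], PatternLabel.TYPE_I),
            ([1.0, -0.7, 0.4, -0.2], PatternLabel.TYPE_II),
            ([1.0, -0.5, 0.0, 0.0], PatternLabel.TYPE_III),
            ([1.0, 0.3, 0.1], PatternLabel.OTHER),
            ([1.0, -0.7, -0.2], PatternLabel.OTHER),
        ],
    )
    def test_rules(self, rho, expected):
        sccs = SCCSequence(np.array(rho), kind="estimated")
        assert classify_pattern(sccs, tol=1e-6) == expected

    def test_tolerance_widens_type3(self):
        sccs = SCCSequence(np.array([1.0, -0.49, -0.01]), kind="estimated")
        assert classify_pattern(sccs, tol=0.02) == PatternLabel.TYPE_III
        assert classify_pattern(sccs, tol=1e-4) == PatternLabel.TYPE_I
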