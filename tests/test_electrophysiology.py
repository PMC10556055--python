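import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clawpore.electrophysiology import (
    BathComposition,
    DILUTED_RINGER,
    FluxSeries,
    GHKBoundError,
    LITHIUM_RINGER,
    RINGER,
    absolute_permeabilities,
    apparent_permeability,
    biionic_ratio,
    correct_teer,
    dilution_ratio,
    ghk_potential,
)
from clawpore.synthetic_data import make_ephys_record, make_flux_series

RTF_MV = 8.31446261815324 * 310.15 / 96485.33212 * 1000.0


class TestTeer:
    def test_blank_and_area_correction(self):
        assert correct_teer(300.0, 100.0, 1.12) == pytest.approx(224.0)

    def test_zero_blank(self):
        assert correct_teer(250.0, 0.0, 2.0) == pytest.approx(500.0)

    def test_roundtrip(self):
        teer = correct_teer(310.0, 95.0, 1.12)
        assert teer / 1.12 + 95.0 == pytest.approx(310.0, abs=1e-12)

    def test_nonphysical_monolayer_rejected(self):
        with pytest.raises(ValueError):
            correct_teer(90.0, 100.0, 1.12)


class TestBathComposition:
    def test_electroneutrality_enforced(self):
        with pytest.raises(ValueError):
            BathComposition(na=140.0, cl=100.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            BathComposition(na=-1.0, cl=-1.0)


class TestDilutionRatio:
    def test_zero_potential_means_beta_one(self):
        assert dilution_ratio(0.0) == pytest.approx(1.0, abs=1e-12)

    def test_beyond_nernst_bound_errors(self):
        v_na = RTF_MV * np.log(28.0 / 140.0)
        with pytest.raises(GHKBoundError, match="limit"):
            dilution_ratio(v_na)  # exactly at the cation-only limit
        with pytest.raises(GHKBoundError):
            dilution_ratio(v_na - 5.0)

    def test_antisymmetric_under_side_swap(self):
        v = -7.3
        beta = dilution_ratio(v, RINGER, DILUTED_RINGER)
        swapped = dilution_ratio(
            -v,
            BathComposition(na=28.0, cl=28.0),
            BathComposition(na=140.0, cl=140.0),
        )
        assert swapped == pytest.approx(beta, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        beta=st.floats(min_value=0.1, max_value=10.0),
        dilution=st.sampled_from([2.0, 4.0, 5.0]),
    )
    def test_forward_inverse_roundtrip_property(self, beta, dilution):
        """GHK inversion recovers beta across dilutions 1:2, 1:4, 1:5."""
        basal = BathComposition(na=140.0 / dilution, cl=140.0 / dilution)
        p_cl = 1e-6
        v = ghk_potential(beta * p_cl, p_cl, RINGER, basal)
        assert dilution_ratio(v, RINGER, basal) == pytest.approx(beta, rel=1e-6)


class TestBiionicRatio:
    def test_symmetric_case_is_unity(self):
        v = ghk_potential(1e-6, 1e-6, RINGER, LITHIUM_RINGER, p_li=1e-6)
        assert biionic_ratio(v, beta=1.0) == pytest.approx(1.0, rel=1e-9)

    def test_pcl_zero_limit_is_biionic_nernst(self):
        """With P_Cl -> 0 the bi-ionic potential reduces to the Nernst form
        V = (RT/F) ln(P_Li [Li]_b / (P_Na [Na]_a))."""
        p_na, p_li = 1e-6, 1.4e-6
        v = ghk_potential(p_na, 1e-20, RINGER, LITHIUM_RINGER, p_li=p_li)
        nernst_ratio = np.exp(v / RTF_MV) * RINGER.na / LITHIUM_RINGER.li
        assert nernst_ratio == pytest.approx(p_li / p_na, rel=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        ratio=st.floats(min_value=0.5, max_value=2.0),
        beta=st.floats(min_value=0.5, max_value=5.0),
    )
    def test_forward_inverse_roundtrip_property(self, ratio, beta):
        p_cl = 1e-6
        p_na = beta * p_cl
        v = ghk_potential(p_na, p_cl, RINGER, LITHIUM_RINGER, p_li=ratio * p_na)
        assert biionic_ratio(v, beta=beta) == pytest.approx(ratio, rel=1e-6)


class TestAbsolutePermeabilities:
    def test_symmetric_split_at_beta_one(self):
        g = 1.0 / 224.0
        p_na, p_cl = absolute_permeabilities(g, 1.0, 140.0, 310.15)
        expected = 8.31446261815324 * 310.15 * g / (2 * 96485.33212**2 * 140e-6)
        assert p_na == pytest.approx(expected, rel=1e-12)
        assert p_cl == pytest.approx(p_na)

    def test_linearity_in_conductance(self):
        a = absolute_permeabilities(1e-3, 1.5)
        b = absolute_permeabilities(2e-3, 1.5)
        assert b[0] == pytest.approx(2 * a[0], rel=1e-12)

    def test_unit_oracle_value(self):
        """Hand unit-checked: G = 1/224 S/cm^2, beta 1.5, 140 mM, 37 C."""
        p_na, p_cl = absolute_permeabilities(1.0 / 224.0, 1.5, 140.0, 310.15)
        # (8.31446 * 310.15 / 96485.33212^2) * (1/224) * 1.5/2.5 / 1.4e-4
        assert p_na == pytest.approx(5.2998e-06, rel=1e-4)
        assert p_na / p_cl == pytest.approx(1.5, rel=1e-12)

    def test_ratio_identity(self):
        for beta in (0.3, 1.0, 4.2):
            p_na, p_cl = absolute_permeabilities(2e-3, beta)
            assert p_na / (p_na + p_cl) == pytest.approx(
                beta / (1 + beta), rel=1e-12
            )


class TestApparentPermeability:
    def test_exact_linear_series(self):
        t = np.array([0.0, 30.0, 60.0, 90.0])
        k = 5.0  # ug per second
        series = FluxSeries(t, k * t * 60.0, donor_concentration=200.0, area=1.12)
        assert apparent_permeability(series) == pytest.approx(
            k / (1.12 * 200.0), rel=1e-12
        )

    def test_zero_flux(self):
        series = FluxSeries(np.array([0.0, 30.0, 60.0]), np.zeros(3),
                            donor_concentration=200.0, area=1.12)
        assert apparent_permeability(series) == 0.0

    def test_negative_slope_warns_but_returns(self):
        series = FluxSeries(np.array([0.0, 30.0, 60.0]),
                            np.array([10.0, 5.0, 0.0]),
                            donor_concentration=200.0, area=1.12)
        with pytest.warns(UserWarning, match="negative"):
            assert apparent_permeability(series) < 0

    def test_sink_violation_warns(self):
        series = make_flux_series(1e-7)
        big = FluxSeries(series.timepoints_min,
                         series.receiver_amounts + 1e5,
                         donor_concentration=200.0, area=1.12,
                         receiver_volume=1.5)
        with pytest.warns(UserWarning, match="sink"):
            apparent_permeability(big)

    def test_noisy_recovery_mean_within_one_percent(self):
        true_papp = 2e-7
        estimates = [
            apparent_permeability(make_flux_series(true_papp, noise_frac=0.02,
                                                   seed=seed))
            for seed in range(200)
        ]
        assert np.mean(estimates) == pytest.approx(true_papp, rel=0.01)


class TestNoisyGhkRecovery:
    def test_median_beta_error_under_noise(self):
        """0.5 mV measurement noise keeps the median beta error below 5%."""
        true_beta = 2.0
        errors = []
        for seed in range(500):
            rec = make_ephys_record(2e-6, 1e-6, 2.6e-6, noise_sd_mv=0.5,
                                    seed=seed)
            beta = dilution_ratio(rec.dilution_potential_mv, rec.apical,
                                  rec.basal_dilution)
            errors.append(abs(beta - true_beta) / true_beta)
        assert np.median(errors) < 0.05
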