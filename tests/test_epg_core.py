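"""EPG operator algebra and MESE signal properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myot2.bloch import mese_bloch
from myot2.epg_core import (
    EPGState,
    SequenceConfig,
    TissueParams,
    epg_relax_shift,
    epg_rf_rotation,
    mese_single_component,
    mese_single_component_batch,
    mese_two_component,
)


def _energy(state):
    return (
        np.sum(np.abs(state.f_plus) ** 2)
        + np.sum(np.abs(state.f_minus) ** 2)
        + 2 * np.sum(np.abs(state.z) ** 2)
    )


class TestRFRotation:
    def test_zero_flip_is_identity(self):
        s = EPGState(5)
        s.f_plus[2] = 0.3 + 0.1j
        out = epg_rf_rotation(s, 0.0, 45.0)
        np.testing.assert_allclose(out.f_plus, s.f_plus)
        np.testing.assert_allclose(out.z, s.z)

    def test_full_excitation_from_equilibrium(self):
        out = epg_rf_rotation(EPGState(5), 90.0, 90.0)
        assert np.abs(out.f_plus[0]) == pytest.approx(1.0)
        assert np.abs(out.z[0]) == pytest.approx(0.0, abs=1e-12)
        # F0- is the conjugate partner of F0+
        assert out.f_minus[0] == pytest.approx(np.conj(out.f_plus[0]))

    def test_perfect_refocusing_swaps_f_states(self):
        s = EPGState(5)
        s.z[0] = 0.0
        s.f_plus[1] = 1.0
        out = epg_rf_rotation(s, 180.0, 90.0)
        assert np.abs(out.f_minus[1]) == pytest.approx(1.0)
        assert np.abs(out.f_plus[1]) == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(out.z, s.z, atol=1e-12)

    @given(
        flip=st.floats(1.0, 179.0),
        phase=st.floats(0.0, 360.0),
    )
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_energy_conserved(self, flip, phase):
        s = EPGState(4)
        s.f_plus[1] = 0.4 - 0.2j
        s.f_minus[1] = np.conj(s.f_plus[1])
        s.z[0] = 0.5
        before = _energy(s)
        after = _energy(epg_rf_rotation(s, flip, phase))
        assert after == pytest.approx(before, rel=1e-10)

    def test_nonfinite_flip_rejected(self):
        with pytest.raises(ValueError):
            epg_rf_rotation(EPGState(3), np.nan, 0.0)


class TestRelaxShift:
    def test_zero_dt_shifts_orders_without_decay(self):
        s = EPGState(4)
        s.f_plus[0] = 1.0
        out = epg_relax_shift(s, 1400.0, 50.0, 0.0)
        assert out.f_plus[1] == pytest.approx(1.0)

    def test_transverse_decay_closed_form(self):
        s = EPGState(4)
        s.f_plus[0] = 1.0
        out = epg_relax_shift(s, 1400.0, 50.0, 3.75)
        assert np.abs(out.f_plus[1]) == pytest.approx(np.exp(-3.75 / 50.0), rel=1e-12)
        assert np.abs(out.f_plus[1]) == pytest.approx(0.92774, abs=5e-6)

    def test_longitudinal_recovery_closed_form(self):
        s = EPGState(4)
        s.z[0] = 0.0
        out = epg_relax_shift(s, 1400.0, 50.0, 3.75)
        assert out.z[0].real == pytest.approx(1.0 - np.exp(-3.75 / 1400.0), rel=1e-12)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            epg_relax_shift(EPGState(3), 1400.0, 50.0, -1.0)

    def test_shift_truncates_highest_order(self):
        s = EPGState(3)
        s.f_plus[3] = 1.0
        out = epg_relax_shift(s, 1e9, 1e9, 0.0)
        assert np.abs(out.f_plus).max() == pytest.approx(0.0, abs=1e-15)


class TestMESESingleComponent:
    def test_cpmg_limit_monoexponential(self, seq_ideal):
        echoes = mese_single_component(1400.0, 50.0, 1.0, seq_ideal)
        n = np.arange(1, 18)
        np.testing.assert_allclose(echoes, np.exp(-n * 7.5 / 50.0), rtol=1e-6)
        assert echoes[0] == pytest.approx(0.86071, abs=5e-6)
        assert echoes[16] == pytest.approx(0.07808, abs=5e-6)

    def test_cpmg_limit_random_t2(self, seq_ideal):
        rng = np.random.default_rng(42)
        n = np.arange(1, 18)
        for t2 in rng.uniform(10.0, 250.0, 20):
            echoes = mese_single_component(1400.0, t2, 1.0, seq_ideal)
            np.testing.assert_allclose(echoes, np.exp(-n * 7.5 / t2), rtol=1e-6)

    def test_no_decay_limit(self, seq_ideal):
        echoes = mese_single_component(1e12, 1e9, 1.0, seq_ideal)
        np.testing.assert_allclose(echoes, 1.0, atol=1e-6)

    def test_reduced_flip_matches_bloch_oracle(self, seq_ideal):
        """Stimulated-echo pathways at B1=0.8 against the isochromat simulation."""
        epg = mese_single_component(1400.0, 50.0, 0.8, seq_ideal)
        oracle = mese_bloch(1400.0, 50.0, 0.8, seq_ideal, n_dephase=128)
        assert np.max(np.abs(epg - oracle)) / oracle.max() < 1e-4

    def test_profile_cases_match_bloch_oracle(self, seq_profile):
        rng = np.random.default_rng(0)
        for _ in range(3):
            t2 = rng.uniform(15.0, 200.0)
            b1 = rng.uniform(0.4, 1.2)
            epg = mese_single_component(1400.0, t2, b1, seq_profile)
            oracle = mese_bloch(1400.0, t2, b1, seq_profile, n_dephase=64)
            assert np.max(np.abs(epg - oracle)) / oracle.max() < 1e-3

    def test_monotone_decay_and_range(self, seq_ideal):
        echoes = mese_single_component(1400.0, 35.0, 1.0, seq_ideal)
        assert np.all(np.diff(echoes) < 0)
        assert np.all((echoes >= 0) & (echoes <= 1))

    def test_batch_agrees_with_single_calls(self, seq_profile):
        t2 = np.array([20.0, 45.0, 90.0])
        b1 = np.array([0.7, 1.0, 1.15])
        batch = mese_single_component_batch(t2, b1, 1400.0, seq_profile)
        for i in range(3):
            single = mese_single_component(1400.0, t2[i], b1[i], seq_profile)
            np.testing.assert_allclose(batch[i], single, rtol=1e-12)


class TestMESETwoComponent:
    def test_pure_water_and_pure_fat_limits(self, seq_profile):
        w = mese_single_component(1400.0, 35.0, 0.9, seq_profile)
        f = mese_single_component(365.0, 150.0, 0.9, seq_profile)
        p0 = TissueParams(t2f_ms=150.0, t2w_ms=35.0, ff=0.0, b1=0.9)
        p1 = TissueParams(t2f_ms=150.0, t2w_ms=35.0, ff=1.0, b1=0.9)
        np.testing.assert_allclose(mese_two_component(p0, seq_profile), w)
        np.testing.assert_allclose(mese_two_component(p1, seq_profile), f)

    def test_cpmg_superposition(self, seq_ideal):
        p = TissueParams(t2f_ms=150.0, t2w_ms=35.0, ff=0.5, b1=1.0)
        n = np.arange(1, 18)
        expected = 0.5 * np.exp(-n * 7.5 / 35.0) + 0.5 * np.exp(-n * 7.5 / 150.0)
        np.testing.assert_allclose(mese_two_component(p, seq_ideal), expected, rtol=1e-6)

    @given(ff=st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=10, derandomize=True)
    def test_exactly_linear_in_ff(self, seq_profile, ff):
        mk = lambda f: mese_two_component(
            TissueParams(t2f_ms=140.0, t2w_ms=40.0, ff=f, b1=0.85), seq_profile
        )
        mix = mk(ff)
        expected = ff * mk(1.0) + (1.0 - ff) * mk(0.0)
        np.testing.assert_allclose(mix, expected, atol=1e-14)


class TestValidation:
    def test_sequence_config_rejects_bad_values(self):
        with pytest.raises(ValueError):
            SequenceConfig(te_ms=-1.0, etl=17)
        with pytest.raises(ValueError):
            SequenceConfig(te_ms=7.5, etl=0)
        with pytest.raises(ValueError):
            SequenceConfig(te_ms=7.5, etl=17, ex_profile=[90.0, 90.0], ref_profile=[180.0])

    def test_tissue_params_rejects_bad_values(self):
        with pytest.raises(ValueError):
            TissueParams(t2f_ms=150.0, t2w_ms=35.0, ff=1.2, b1=1.0)
        with pytest.raises(ValueError):
            TissueParams(t2f_ms=-5.0, t2w_ms=35.0, ff=0.2, b1=1.0)

    def test_seq_hash_tracks_profile_changes(self, seq_ideal, seq_profile):
        assert seq_ideal.seq_hash != seq_profile.seq_hash
        again = SequenceConfig(te_ms=7.5, etl=17)
        assert again.seq_hash == seq_ideal.seq_hash
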