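import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taulogp.dataset import IonClass
from taulogp.speciation import (
    SpeciationProfile,
    TautomerMixture,
    classify_ionization,
    enumerate_microstates,
    log_d,
    macro_logp,
    species_fractions,
    speciation_table,
)


class TestEnumerateMicrostates:
    def test_no_sites(self):
        states = enumerate_microstates(0, 0)
        assert len(states) == 1
        assert states[0].net_charge == 0

    def test_one_acid_one_base(self):
        # the four speciations of a molecule like Piroxicam
        states = enumerate_microstates(1, 1)
        assert len(states) == 4
        assert sorted(s.net_charge for s in states) == [-1, 0, 0, 1]

    def test_diprotic_acid_charges(self):
        states = enumerate_microstates(2, 0)
        assert sorted(s.net_charge for s in states) == [-2, -1, -1, 0]

    def test_counts_power_of_two(self):
        for na, nb in [(0, 1), (2, 1), (3, 2)]:
            assert len(enumerate_microstates(na, nb)) == 2 ** (na + nb)

    def test_negative_counts_fatal(self):
        with pytest.raises(ValueError):
            enumerate_microstates(-1, 0)


class TestSpeciesFractions:
    def test_henderson_hasselbalch_midpoint(self):
        fr = species_fractions([7.0], [], pH=7.0)
        assert fr == pytest.approx([0.5, 0.5])

    def test_acid_mostly_neutral_below_pka(self):
        fr = species_fractions([7.0], [], pH=3.0)
        # protonated (neutral) microstate is first
        assert fr[0] == pytest.approx(1 / (1 + 10**-4))

    def test_extreme_ph_limits(self):
        fr_low = species_fractions([5.0, 9.0], [4.0], pH=-20.0)
        assert fr_low[0] == pytest.approx(1.0)  # fully protonated listed first
        fr_high = species_fractions([5.0, 9.0], [4.0], pH=40.0)
        assert fr_high[-1] == pytest.approx(1.0)  # fully deprotonated last

    def test_fractions_sum_to_one_many_draws(self, rng):
        for _ in range(10_000):
            na, nb = rng.integers(0, 3), rng.integers(0, 2)
            pka = rng.uniform(-2, 14, size=na).tolist()
            pkb = rng.uniform(-2, 14, size=nb).tolist()
            pH = float(rng.uniform(-5, 19))
            fr = species_fractions(pka, pkb, pH)
            assert abs(fr.sum() - 1.0) < 1e-9
            assert np.all(fr >= 0) and np.all(fr <= 1)


class TestLogD:
    def test_single_species(self):
        assert log_d([3.7], [1.0]) == pytest.approx(3.7, abs=1e-12)

    def test_hand_arithmetic(self):
        # 0.5*100 + 0.5*0.01 = 50.005
        assert log_d([2.0, -2.0], [0.5, 0.5]) == pytest.approx(np.log10(50.005), abs=1e-12)
        assert log_d([2.0, -2.0], [0.5, 0.5]) == pytest.approx(1.6990, abs=1e-4)

    def test_convexity_bounds(self, rng):
        for _ in range(200):
            logps = rng.uniform(-6, 8, size=4)
            f = rng.dirichlet(np.ones(4))
            val = log_d(logps, f)
            assert logps.min() - 1e-9 <= val <= logps.max() + 1e-9

    def test_permutation_invariant(self):
        assert log_d([1.0, 2.0, 3.0], [0.2, 0.3, 0.5]) == pytest.approx(
            log_d([3.0, 1.0, 2.0], [0.5, 0.2, 0.3]), abs=1e-12
        )

    def test_all_equal_logps_exact(self):
        assert log_d([2.2, 2.2, 2.2], [0.1, 0.4, 0.5]) == pytest.approx(2.2, abs=1e-12)

    def test_extreme_magnitudes_stable(self):
        assert log_d([400.0, -400.0], [0.5, 0.5]) == pytest.approx(400.0 + np.log10(0.5), abs=1e-6)

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            log_d([], [])


class TestMacroLogp:
    def test_single_tautomer(self):
        assert macro_logp(TautomerMixture([1.5], [1.0])) == pytest.approx(1.5, abs=1e-12)

    def test_nitrosophenol_pair_hand_arithmetic(self):
        expected = np.log10(0.8 * 10**1.29 + 0.2 * 10**1.08)
        got = macro_logp(TautomerMixture([1.29, 1.08], [0.8, 0.2]))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(1.2554, abs=1e-4)

    def test_dominant_limit(self):
        got = macro_logp(TautomerMixture([3.0, 0.0], [1.0 - 1e-12, 1e-12]))
        assert got == pytest.approx(3.0, abs=1e-9)

    def test_same_kernel_as_log_d(self):
        logps, fracs = [2.0, 0.5, -1.0], [0.3, 0.3, 0.4]
        assert macro_logp(TautomerMixture(logps, fracs)) == log_d(logps, fracs)

    def test_invalid_fractions_fatal(self):
        with pytest.raises(ValueError):
            TautomerMixture([1.0, 2.0], [0.7, 0.7])


class TestClassifyIonization:
    def test_phthalic_acid_anion(self):
        assert classify_ionization([2.5, 5.5], None) == IonClass.ANION

    def test_neutral_inside_window(self):
        assert classify_ionization([7.0], None) == IonClass.NEUTRAL

    def test_zwitterion_as_printed(self):
        assert classify_ionization([5.0], [4.0]) == IonClass.ZWITTERION

    def test_zwitterion_conventional_direction(self):
        assert classify_ionization([5.0], [4.0], zwitterion_rule="conventional") == IonClass.NEUTRAL
        assert classify_ionization([4.0], [9.5], zwitterion_rule="conventional") == IonClass.ZWITTERION

    def test_cation(self):
        assert classify_ionization(None, [10.0]) == IonClass.CATION

    def test_no_data_unknown(self):
        assert classify_ionization(None, None) == IonClass.UNKNOWN
        assert classify_ionization([], []) == IonClass.UNKNOWN


class TestSpeciationTable:
    def test_single_point_equals_fractions(self):
        profile = SpeciationProfile(pka_acidic=[5.0], pka_basic=[3.0])
        table = speciation_table(profile, [2.0])
        assert np.allclose(table.drop(columns="pH").iloc[0].to_numpy(), profile.fractions(2.0))

    def test_monoprotic_neutral_fraction_decreases(self):
        profile = SpeciationProfile(pka_acidic=[6.0], pka_basic=[])
        table = speciation_table(profile, np.linspace(0, 14, 30))
        neutral = table.iloc[:, 1].to_numpy()  # protonated state column
        assert np.all(np.diff(neutral) < 0)

    def test_rows_sum_to_one(self):
        profile = SpeciationProfile(pka_acidic=[5.0, 8.0], pka_basic=[3.0])
        table = speciation_table(profile, np.arange(0, 12, 0.5))
        assert np.allclose(table.drop(columns="pH").sum(axis=1), 1.0, atol=1e-9)

    def test_cation_dominates_at_low_ph(self):
        profile = SpeciationProfile(pka_acidic=[5.0], pka_basic=[2.0])
        fr = profile.fractions(0.0)
        cation = [
            st.net_charge for st in profile.microstates
        ]
        idx = cation.index(1)
        assert fr[idx] > 0.98

    def test_profile_log_d(self):
        profile = SpeciationProfile(pka_acidic=[4.0], pka_basic=[], logp_species=[3.0, -1.0])
        assert profile.log_d(1.0) == pytest.approx(3.0, abs=1e-2)


@settings(max_examples=60, deadline=None)
@given(
    pka=st.lists(st.floats(min_value=-2, max_value=16), min_size=0, max_size=3),
    pkb=st.lists(st.floats(min_value=-2, max_value=16), min_size=0, max_size=2),
    pH=st.floats(min_value=-10, max_value=24),
)
def test_fractions_normalized_property(pka, pkb, pH):
    fr = species_fractions(pka, pkb, pH)
    assert abs(fr.sum() - 1.0) < 1e-9
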