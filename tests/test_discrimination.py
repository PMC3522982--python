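import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oriet.discrimination import (
    USEFUL_COUPLING_RANGE,
    OdorantSpectrum,
    ReceptorDefinition,
    VibrationalMode,
    activation_matrix,
    apply_isotope_substitution,
    generate_synthetic_spectrum,
    isotope_discrimination,
    read_spectrum,
    receptor_activation,
    write_spectrum,
)


class TestSpectrumIO:
    def test_round_trip(self, tmp_path, h2s_spectrum):
        path = tmp_path / "h2s.tsv"
        write_spectrum(h2s_spectrum, path)
        back = read_spectrum(path, name="h2s")
        assert back.modes == h2s_spectrum.modes

    def test_header_only_warns_and_yields_empty(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("label\tfreq_cm1\thuang_rhys\n")
        with pytest.warns(UserWarning, match="header only"):
            spectrum = read_spectrum(path)
        assert spectrum.modes == ()

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("label\tfreq_cm1\nx\t100\n")
        with pytest.raises(ValueError, match="huang_rhys"):
            read_spectrum(path)

    def test_negative_frequency_names_the_line(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text(
            "label\tfreq_cm1\thuang_rhys\nok\t2600\t0.1\nbad\t-100\t0.1\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_spectrum(path)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            OdorantSpectrum(
                "x",
                (VibrationalMode("a", 100, 0.1), VibrationalMode("a", 200, 0.1)),
            )


class TestReceptorActivation:
    def test_sh_stretch_activates_sulphur_receptor(self, h2s_spectrum, sulphur_receptor):
        report = receptor_activation(h2s_spectrum, sulphur_receptor)
        assert report.activated
        assert [m.label for m in report.matching_modes] == ["sh_stretch"]
        assert report.matching_modes[0].detuning == 0.0

    def test_decaborane_smells_sulphurous_too(self, decaborane_spectrum, sulphur_receptor):
        # strongest B-H stretch sits 25 cm^-1 from the S-H stretch: still inside
        # the receptor's resolution window (boundary inclusive)
        report = receptor_activation(decaborane_spectrum, sulphur_receptor)
        assert report.activated
        assert report.matching_modes[0].detuning == -25.0

    def test_empty_spectrum_never_activates(self, sulphur_receptor):
        empty = OdorantSpectrum("nothing", ())
        assert not receptor_activation(empty, sulphur_receptor).activated

    def test_coupling_outside_range_blocks_activation(self, sulphur_receptor):
        weak = OdorantSpectrum("weak", (VibrationalMode("m", 2600, 0.001),))
        strong = OdorantSpectrum("strong", (VibrationalMode("m", 2600, 0.9),))
        assert not receptor_activation(weak, sulphur_receptor).activated
        assert not receptor_activation(strong, sulphur_receptor).activated

    def test_coupling_boundaries_inclusive(self, sulphur_receptor):
        lo = OdorantSpectrum("lo", (VibrationalMode("m", 2600, 0.01),))
        hi = OdorantSpectrum("hi", (VibrationalMode("m", 2600, 0.3),))
        assert receptor_activation(lo, sulphur_receptor).activated
        assert receptor_activation(hi, sulphur_receptor).activated

    def test_useful_coupling_preset_is_stricter(self):
        narrow = ReceptorDefinition("r", 2600, coupling_range=USEFUL_COUPLING_RANGE)
        borderline = OdorantSpectrum("b", (VibrationalMode("m", 2600, 0.02),))
        assert not receptor_activation(borderline, narrow).activated

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_mode_order_and_labels_are_irrelevant(self, seed):
        spectrum = generate_synthetic_spectrum(8, seed=seed)
        receptor = ReceptorDefinition("r", 2700, 150)
        rng = random.Random(seed)
        shuffled_modes = list(spectrum.modes)
        rng.shuffle(shuffled_modes)
        relabelled = OdorantSpectrum(
            spectrum.name,
            tuple(
                VibrationalMode(f"z{i}", m.frequency, m.huang_rhys,
                                m.reduced_mass, m.involves_hydrogen)
                for i, m in enumerate(shuffled_modes)
            ),
        )
        assert receptor_activation(relabelled, receptor).activated == \
            receptor_activation(spectrum, receptor).activated

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000), extra=st.floats(1.0, 500.0))
    def test_widening_the_window_never_deactivates(self, seed, extra):
        spectrum = generate_synthetic_spectrum(6, seed=seed)
        narrow = ReceptorDefinition("r", 2650, 25)
        wide = ReceptorDefinition("r", 2650, 25 + extra)
        if receptor_activation(spectrum, narrow).activated:
            assert receptor_activation(spectrum, wide).activated


class TestActivationMatrix:
    def test_identical_spectra_give_identical_rows(self, h2s_spectrum, sulphur_receptor):
        twin = OdorantSpectrum("twin", h2s_spectrum.modes)
        matrix = activation_matrix([h2s_spectrum, twin], [sulphur_receptor])
        assert (matrix.loc["h2s"] == matrix.loc["twin"]).all()

    def test_mirror_image_multisets_indistinguishable(self, sulphur_receptor):
        # enantiomers: same (frequency, S) multiset, different labels/order
        left = OdorantSpectrum(
            "left", (VibrationalMode("a", 2600, 0.1), VibrationalMode("b", 900, 0.2))
        )
        right = OdorantSpectrum(
            "right", (VibrationalMode("y", 900, 0.2), VibrationalMode("x", 2600, 0.1))
        )
        panel = [
            sulphur_receptor,
            ReceptorDefinition("mid", 900, 25),
            ReceptorDefinition("off", 1500, 25),
        ]
        matrix = activation_matrix([left, right], panel)
        assert (matrix.loc["left"] == matrix.loc["right"]).all()

    def test_zero_receptors_gives_empty_row(self, h2s_spectrum):
        matrix = activation_matrix([h2s_spectrum], [])
        assert matrix.shape == (1, 0)

    def test_single_covered_mode_difference_flips_exactly_one_column(self):
        base_modes = (VibrationalMode("a", 1000, 0.1), VibrationalMode("b", 2600, 0.1))
        alt_modes = (VibrationalMode("a", 1000, 0.1), VibrationalMode("b", 2200, 0.1))
        panel = [
            ReceptorDefinition("r2600", 2600, 25),
            ReceptorDefinition("r1000", 1000, 25),
            ReceptorDefinition("r500", 500, 25),
        ]
        matrix = activation_matrix(
            [OdorantSpectrum("base", base_modes), OdorantSpectrum("alt", alt_modes)],
            panel,
        )
        diffs = (matrix.loc["base"] != matrix.loc["alt"]).sum()
        assert diffs == 1
        assert bool(matrix.loc["base", "r2600"]) and not bool(matrix.loc["alt", "r2600"])

    def test_no_odorants_rejected(self, sulphur_receptor):
        with pytest.raises(ValueError):
            activation_matrix([], [sulphur_receptor])


class TestIsotopeSubstitution:
    def test_h_modes_shift_by_about_800_wavenumbers(self):
        spectrum = OdorantSpectrum(
            "ch", (VibrationalMode("ch_stretch", 2730.0, 0.1, involves_hydrogen=True),)
        )
        shifted = apply_isotope_substitution(spectrum)
        drop = spectrum.modes[0].frequency - shifted.modes[0].frequency
        assert drop == pytest.approx(2730 * (1 - 1 / math.sqrt(2)), rel=1e-12)
        assert drop == pytest.approx(800, abs=5)

    def test_couplings_and_other_modes_untouched(self, h2s_spectrum):
        shifted = apply_isotope_substitution(h2s_spectrum)
        for old, new in zip(h2s_spectrum.modes, shifted.modes):
            assert new.huang_rhys == old.huang_rhys
            if old.involves_hydrogen:
                assert new.frequency < old.frequency
            else:
                assert new.frequency == old.frequency

    def test_spectrum_without_hydrogen_unchanged(self):
        spectrum = OdorantSpectrum("noH", (VibrationalMode("m", 1000, 0.1),))
        assert apply_isotope_substitution(spectrum).modes == spectrum.modes

    def test_double_substitution_is_factor_squared(self):
        spectrum = OdorantSpectrum(
            "x", (VibrationalMode("m", 2000, 0.1, involves_hydrogen=True),)
        )
        once = apply_isotope_substitution(spectrum)
        twice = apply_isotope_substitution(once)
        assert twice.modes[0].frequency == pytest.approx(2000 / 2, rel=1e-12)

    def test_labelled_subset_rule(self, h2s_spectrum):
        shifted = apply_isotope_substitution(h2s_spectrum, rule=["sh_stretch"])
        assert shifted.modes[0].frequency == h2s_spectrum.modes[0].frequency
        assert shifted.modes[1].frequency < h2s_spectrum.modes[1].frequency

    def test_unknown_rule_rejected(self, h2s_spectrum):
        with pytest.raises(ValueError, match="unknown isotope rule"):
            apply_isotope_substitution(h2s_spectrum, rule="all_H_to_T")
        with pytest.raises(ValueError, match="unknown mode labels"):
            apply_isotope_substitution(h2s_spectrum, rule=["no_such_mode"])

    def test_input_not_mutated(self, h2s_spectrum):
        before = h2s_spectrum.modes
        apply_isotope_substitution(h2s_spectrum)
        assert h2s_spectrum.modes == before

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_flagged_frequencies_strictly_lowered(self, seed):
        spectrum = generate_synthetic_spectrum(10, h_fraction=0.7, seed=seed)
        shifted = apply_isotope_substitution(spectrum)
        for old, new in zip(spectrum.modes, shifted.modes):
            if old.involves_hydrogen:
                assert new.frequency < old.frequency
            else:
                assert new.frequency == old.frequency


class TestIsotopeDiscrimination:
    def test_ch_band_receptor_discriminates_deuteration(self):
        # acetophenone-like odorant: C-H stretch band + a receptor tuned to it
        spectrum = OdorantSpectrum(
            "acetophenone-like",
            (
                VibrationalMode("co_stretch", 1700, 0.15),
                VibrationalMode("ch_stretch", 3050, 0.1, involves_hydrogen=True),
            ),
        )
        receptors = [
            ReceptorDefinition("carbonyl", 1700, 25),
            ReceptorDefinition("ch_band", 3050, 25),
        ]
        flag, which = isotope_discrimination(spectrum, receptors)
        assert flag and which == "ch_band"

    def test_receptors_far_from_h_modes_cannot_tell(self, h2s_spectrum):
        receptors = [ReceptorDefinition("far", 600, 25)]
        assert isotope_discrimination(h2s_spectrum, receptors) == (False, None)

    def test_no_receptors_no_discrimination(self, h2s_spectrum):
        assert isotope_discrimination(h2s_spectrum, []) == (False, None)


class TestSyntheticSpectrum:
    def test_reproducible(self):
        a = generate_synthetic_spectrum(8, seed=123)
        b = generate_synthetic_spectrum(8, seed=123)
        assert a.modes == b.modes

    def test_zero_modes(self):
        assert generate_synthetic_spectrum(0, seed=1).modes == ()

    def test_frequencies_fall_in_bands(self):
        bands = ((500.0, 800.0), (2400.0, 2700.0))
        spectrum = generate_synthetic_spectrum(10_000, bands=bands, seed=99)
        for m in spectrum.modes:
            assert any(lo <= m.frequency <= hi for lo, hi in bands)

    def test_couplings_in_requested_range(self):
        spectrum = generate_synthetic_spectrum(500, s_range=(0.05, 0.2), seed=4)
        assert all(0.05 <= m.huang_rhys <= 0.2 for m in spectrum.modes)

    def test_empty_bands_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_spectrum(3, bands=(), seed=0)
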