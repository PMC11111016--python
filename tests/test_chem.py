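"""Exact masses, label shifts, extraction windows and isotope envelopes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silkms.chem import (
    ISOTOPES,
    Formula,
    LabelScheme,
    LabelingDesign,
    MzWindow,
    UnknownElementError,
    build_target_table,
    ion_mz,
    isotopologue_envelope,
    labeled_mz,
    monoisotopic_mass,
    window_for,
)

QUINOLINIUM = Formula.parse("C9H8N")
IAA = Formula.parse("C10H9NO2")


class TestMonoisotopicMass:
    def test_empty_formula_is_identity(self):
        assert monoisotopic_mass(Formula({})) == 0.0

    @pytest.mark.parametrize(
        "formula, expected",
        [("H2O", 18.010565), ("C9H8N", 130.065674), ("C10H9NO2", 175.063329)],
    )
    def test_hand_summed_masses(self, formula, expected):
        assert monoisotopic_mass(Formula.parse(formula)) == pytest.approx(expected, abs=1e-6)

    def test_unknown_element_named_in_error(self):
        with pytest.raises(UnknownElementError, match="Se"):
            Formula({"Se": 1})


class TestIonMz:
    def test_quinolinium_cation(self):
        assert round(ion_mz(QUINOLINIUM), 4) == 130.0651

    def test_protonated_iaa(self):
        assert ion_mz(IAA, protonated=True) == pytest.approx(176.0706, abs=5e-5)

    def test_bare_proton(self):
        assert ion_mz(Formula.parse("H")) == pytest.approx(1.007276, abs=1e-6)

    def test_charge_zero_rejected(self):
        with pytest.raises(ValueError):
            ion_mz(QUINOLINIUM, charge=0)


class TestLabeledMz:
    @pytest.mark.parametrize(
        "scheme, expected",
        [("15N1", 131.0622), ("13C6", 136.0853), ("2H4", 134.0902), ("13C8,15N1", 139.0890)],
    )
    def test_labeled_quinolinium_centers(self, scheme, expected):
        mz = labeled_mz(ion_mz(QUINOLINIUM), LabelScheme.parse(scheme))
        assert round(mz, 4) == expected

    def test_empty_scheme_is_identity(self):
        assert labeled_mz(500.0, LabelScheme()) == 500.0

    def test_oversubstitution_rejected(self):
        with pytest.raises(ValueError, match="only"):
            LabelScheme.parse("15N2").validate(QUINOLINIUM)

    @given(st.integers(0, 6), st.integers(0, 1), st.integers(0, 4))
    @settings(deadline=None)
    def test_additivity_of_schemes(self, nc, nn, nh):
        """Applying labels separately equals applying them jointly."""
        base = ion_mz(QUINOLINIUM)
        parts = []
        if nc:
            parts.append(("C", 13, nc))
        if nn:
            parts.append(("N", 15, nn))
        if nh:
            parts.append(("H", 2, nh))
        joint = labeled_mz(base, LabelScheme(tuple(parts)))
        stepwise = base
        for p in parts:
            stepwise = labeled_mz(stepwise, LabelScheme((p,)))
        assert abs(joint - stepwise) < 1e-9


class TestWindows:
    # all five published quinolinium extraction ranges, 4 d.p.
    PRINTED = {
        "": (130.0641, 130.0661),
        "15N1": (131.0612, 131.0632),
        "2H4": (134.0892, 134.0912),
        "13C6": (136.0843, 136.0863),
        "13C8,15N1": (139.0880, 139.0900),
    }

    @pytest.mark.parametrize("scheme", list(PRINTED))
    def test_reproduces_published_quinolinium_windows(self, scheme):
        mz = labeled_mz(ion_mz(QUINOLINIUM), LabelScheme.parse(scheme))
        w = window_for(mz)
        assert (w.low, w.high) == self.PRINTED[scheme]

    def test_symmetric_bounds(self):
        assert window_for(100.0) == MzWindow(99.9990, 100.0010)

    def test_ppm_mode(self):
        w = window_for(200.0, 5.0, ppm=True)
        assert (w.low, w.high) == (199.9990, 200.0010)

    def test_nonpositive_half_width_rejected(self):
        with pytest.raises(ValueError):
            window_for(100.0, 0.0)


def brute_force_envelope(formula: Formula, max_shift: int) -> np.ndarray:
    """Oracle: enumerate every isotope assignment over all atoms."""
    atoms = [el for el, n in formula.counts.items() for _ in range(n)]
    acc = np.zeros(max_shift + 1)
    choices = [ISOTOPES.isotopes(el) for el in atoms]
    base = [c[0][0] for c in choices]
    for combo in itertools.product(*choices):
        shift = sum(mn for mn, _, _ in combo) - sum(base)
        if shift <= max_shift:
            prob = 1.0
            for _, _, a in combo:
                prob *= a
            acc[shift] += prob
    return 100.0 * acc / acc[0]


class TestEnvelope:
    def test_iaa_m1_near_eleven_percent(self):
        env = isotopologue_envelope(IAA, 1)
        assert env[1] == pytest.approx(11.1, abs=0.5)

    def test_single_carbon_ratio(self):
        env = isotopologue_envelope(Formula.parse("C"), 1)
        assert env[1] == pytest.approx(100 * 0.0107 / 0.9893, rel=1e-9)

    @pytest.mark.parametrize("formula", ["H2O", "C3H5N", "C2H2O2", "CH4S", "C2Cl2"])
    def test_matches_brute_force_enumeration(self, formula):
        f = Formula.parse(formula)
        got = isotopologue_envelope(f, 3)
        want = brute_force_envelope(f, 3)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    @given(
        st.integers(1, 12),
        st.integers(0, 10),
        st.integers(0, 3),
        st.integers(0, 3),
    )
    @settings(deadline=None, max_examples=40)
    def test_chno_satellites_decay_monotonically(self, nc, nh, nn, no):
        counts = {k: v for k, v in zip("CHNO", (nc, nh, nn, no)) if v}
        env = isotopologue_envelope(Formula(counts), 3)
        assert env[1] >= env[2] >= env[3]

    def test_unknown_element_rejected(self):
        with pytest.raises(UnknownElementError):
            isotopologue_envelope(Formula({"Br": 2}), 1)  # type: ignore[arg-type]


class TestIsotopeTable:
    @pytest.mark.parametrize(
        "el, mn, expected", [("C", 13, 1.00335), ("H", 2, 1.00628), ("N", 15, 0.99703)]
    )
    def test_printed_mass_increments(self, el, mn, expected):
        assert round(ISOTOPES.heavy_shift(el, mn), 5) == expected


class TestTargetTable:
    DESIGN = LabelingDesign(
        tracer=LabelScheme.parse("13C6"),
        baseline=LabelScheme.parse("15N1"),
        internal_standard=LabelScheme.parse("2H4"),
    )

    def test_three_channels_at_published_centers(self):
        targets = build_target_table(
            [("IAA", QUINOLINIUM, (4.0, 5.0), None)], self.DESIGN
        )
        by_channel = {t.channel: round(t.mz, 4) for t in targets}
        assert by_channel == {
            "endogenous": 131.0622,
            "tracer": 136.0853,
            "internal-standard": 134.0902,
        }
        assert not any(t.warnings for t in targets)

    def test_dual_label_tracer_center(self):
        design = LabelingDesign(tracer=LabelScheme.parse("13C8,15N1"))
        (_, tracer) = build_target_table(
            [("IAA", QUINOLINIUM, (4.0, 5.0), None)], design
        )
        assert tracer.channel == "tracer"
        assert round(tracer.mz, 4) == 139.0890

    def test_identical_schemes_flag_cross_talk(self):
        design = LabelingDesign(
            tracer=LabelScheme.parse("15N1"), baseline=LabelScheme.parse("15N1")
        )
        targets = build_target_table([("IAA", QUINOLINIUM, (4.0, 5.0), None)], design)
        assert all("cross-talk" in w for t in targets for w in t.warnings)
        assert all(t.warnings for t in targets)
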