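"""Peptide parsing, compositions, envelopes and fragment bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pmass

from c2hdx import (
    ParseError,
    elemental_composition,
    fragment_ions,
    monoisotopic_mass,
    natural_envelope,
    parse_sequence,
)
from c2hdx.peptide import BETA_ASP, PHOS_HIS, PROTON_MASS

from conftest import EXTRA_SEQUENCES, PANEL_SEQUENCES

# Independent oracle: textbook molecular formulas of free amino acids.
FREE_AA_FORMULA = {"G": {"C": 2, "H": 5, "N": 1, "O": 2},
                   "A": {"C": 3, "H": 7, "N": 1, "O": 2},
                   "H": {"C": 6, "H": 9, "N": 3, "O": 2},
                   "F": {"C": 9, "H": 11, "N": 1, "O": 2}}


class TestParsing:
    def test_plain_hexapeptide(self):
        p = parse_sequence("AAAHAF")
        assert len(p) == 6
        assert p.his_positions == (4,)
        assert p.modifications == {}
        assert p.c_terminus == "free-acid"

    def test_phospho_tag(self):
        p = parse_sequence("AAAH[p]AF")
        assert p.residues == tuple("AAAHAF")
        assert p.modifications == {4: PHOS_HIS}
        assert p.is_phosphorylated

    def test_amide_terminus_and_two_his(self):
        p = parse_sequence("NHFWKTHT-NH2")
        assert len(p) == 8
        assert p.c_terminus == "amide"
        assert p.his_positions == (2, 7)

    def test_beta_asp_token(self):
        p = parse_sequence("bDRVYIHPF")
        assert p.residues[0] == "D"
        assert p.modifications == {1: BETA_ASP}
        # beta linkage is an isomerism: composition identical to plain Asp
        assert elemental_composition(p) == elemental_composition(parse_sequence("DRVYIHPF"))

    def test_display_roundtrip(self):
        for text in ["AAAH[p]AF", "bDRVYIHPF", "NHFWKTHT-NH2"]:
            assert parse_sequence(text).display() == text

    @pytest.mark.parametrize("bad", ["", "AAZX", "A[p]AF", "AAAHAF-XYZ"])
    def test_errors_name_the_token(self, bad):
        with pytest.raises(ParseError):
            parse_sequence(bad)

    def test_phospho_requires_his(self):
        with pytest.raises(ParseError):
            parse_sequence("AAAA[p]AF")


class TestComposition:
    @pytest.mark.parametrize("aa,formula", sorted(FREE_AA_FORMULA.items()))
    def test_free_amino_acid_formula(self, aa, formula):
        assert dict(elemental_composition(parse_sequence(aa))) == formula

    def test_phospho_delta_is_hpo3(self):
        delta = elemental_composition(parse_sequence("AAAH[p]AF")) - elemental_composition(parse_sequence("AAAHAF"))
        assert dict(delta) == {"H": 1, "P": 1, "O": 3}

    def test_order_invariance(self):
        assert elemental_composition(parse_sequence("AG")) == elemental_composition(parse_sequence("GA"))

    def test_glycine_monoisotopic_mass(self):
        assert monoisotopic_mass(elemental_composition(parse_sequence("G"))) == pytest.approx(75.03203, abs=1e-4)

    def test_phospho_mass_delta(self):
        d = monoisotopic_mass(elemental_composition(parse_sequence("AAAH[p]AF"))) - \
            monoisotopic_mass(elemental_composition(parse_sequence("AAAHAF")))
        assert d == pytest.approx(79.96633, abs=1e-4)

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            monoisotopic_mass(pmass.Composition())

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            monoisotopic_mass(pmass.Composition({"Xx": 1}))

    @given(st.permutations(list("AGHFDR")))
    @settings(max_examples=20, deadline=None)
    def test_composition_permutation_invariant(self, perm):
        assert elemental_composition(parse_sequence("".join(perm))) == \
            elemental_composition(parse_sequence("AGHFDR"))


def brute_force_envelope(comp, n_peaks):
    """Oracle: direct repeated convolution of per-atom distributions, atom by atom."""
    env = np.array([1.0])
    for el, count in comp.items():
        iso = pmass.nist_mass[el]
        numbers = sorted(a for a in iso if a != 0 and iso[a][1] > 0)
        dist = np.zeros(numbers[-1] - numbers[0] + 1)
        for a in numbers:
            dist[a - numbers[0]] = iso[a][1]
        for _ in range(count):
            env = np.convolve(env, dist)
    env = env[:n_peaks]
    return env / env.sum()


class TestNaturalEnvelope:
    def test_single_hydrogen_matches_iupac_abundance(self):
        env = natural_envelope(pmass.Composition({"H": 1}), 2)
        assert env == pytest.approx([0.999885, 0.000115], abs=1e-6)

    @pytest.mark.parametrize("seq", ["G", "AG", "AAAHAF"])
    def test_matches_brute_force_convolution(self, seq):
        comp = elemental_composition(parse_sequence(seq))
        np.testing.assert_allclose(natural_envelope(comp, 6), brute_force_envelope(comp, 6), atol=1e-12)

    def test_additivity_under_convolution(self):
        c1 = elemental_composition(parse_sequence("AG"))
        c2 = elemental_composition(parse_sequence("GF"))
        joint = natural_envelope(c1 + c2, 6)
        conv = np.convolve(natural_envelope(c1, 6), natural_envelope(c2, 6))[:6]
        np.testing.assert_allclose(joint, conv / conv.sum(), atol=1e-10)

    @pytest.mark.parametrize("seq", PANEL_SEQUENCES + EXTRA_SEQUENCES)
    def test_normalized_and_nonnegative(self, seq):
        env = natural_envelope(elemental_composition(parse_sequence(seq)), 8)
        assert np.all(env >= 0)
        assert env.sum() == pytest.approx(1.0, abs=1e-12)

    def test_needs_two_peaks(self):
        with pytest.raises(ValueError):
            natural_envelope(pmass.Composition({"C": 10}), 1)


class TestFragments:
    def test_b6_contains_his_b1_to_b5_do_not(self):
        frags = {f.label: f for f in fragment_ions(parse_sequence("bDRVYIHPF"))}
        assert frags["b6"].contains_his
        for i in range(1, 6):
            assert not frags[f"b{i}"].contains_his

    def test_dipeptide_boundary(self):
        frags = fragment_ions(parse_sequence("AG"), exchange_site=None)
        assert sorted(f.label for f in frags) == ["b1", "y1"]

    @pytest.mark.parametrize("seq", PANEL_SEQUENCES + ["bDRVYIHPF"])
    def test_by_complementarity(self, seq):
        p = parse_sequence(seq)
        mh = monoisotopic_mass(elemental_composition(p)) + PROTON_MASS
        frags = {f.label: f for f in fragment_ions(p)}
        n = len(p)
        for i in range(1, n):
            total = frags[f"b{i}"].singly_protonated_mass + frags[f"y{n - i}"].singly_protonated_mass
            assert total == pytest.approx(mh + PROTON_MASS, abs=1e-4)

    def test_complementarity_with_amide_terminus(self):
        p = parse_sequence("NHFWKTHT-NH2")
        mh = monoisotopic_mass(elemental_composition(p)) + PROTON_MASS
        frags = {f.label: f for f in fragment_ions(p, exchange_site=7)}
        for i in range(1, len(p)):
            total = frags[f"b{i}"].singly_protonated_mass + frags[f"y{len(p) - i}"].singly_protonated_mass
            assert total == pytest.approx(mh + PROTON_MASS, abs=1e-4)

    @pytest.mark.parametrize("seq", PANEL_SEQUENCES + ["bDRVYIHPF", "NHFWKTHT-NH2"])
    def test_his_flags_monotone(self, seq):
        p = parse_sequence(seq)
        site = p.his_positions[0]
        frags = fragment_ions(p, exchange_site=site)
        b_flags = [f.contains_his for f in frags if f.ion_type == "b"]
        y_flags = [f.contains_his for f in frags if f.ion_type == "y"]
        assert b_flags == sorted(b_flags)   # non-decreasing in i
        assert y_flags == sorted(y_flags)   # likewise from the C-terminus

    def test_exchange_site_flags_follow_designation(self):
        p = parse_sequence("NHFWKTHT-NH2")
        by2 = {f.label: f for f in fragment_ions(p, exchange_site=2)}
        by7 = {f.label: f for f in fragment_ions(p, exchange_site=7)}
        assert by2["b2"].contains_exchange_site and not by7["b2"].contains_exchange_site
        assert by7["y2"].contains_exchange_site and not by2["y2"].contains_exchange_site

    def test_multi_his_requires_designation(self):
        with pytest.raises(ValueError):
            fragment_ions(parse_sequence("NHFWKTHT-NH2"))
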