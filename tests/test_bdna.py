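"""Ideal B-DNA construction, screw transforms, threading, and sequence utils."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wingdock.bdna import (BACKBONE_ATOMS, DuplexSequence, HelicalParameters,
                           at_content, base_pair_centers, build_bdna,
                           duplex_sequence_of, helical_step, helix_axis,
                           reverse_complement, thread_sequence)


class TestSequenceUtils:
    @pytest.mark.parametrize("seq,expected", [
        ("ATAT", 1.0), ("GCGC", 0.0), ("ATGC", 0.5), ("atgc", 0.5),
    ])
    def test_at_content(self, seq, expected):
        assert at_content(seq) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", ["", "ATXG"])
    def test_at_content_rejects_bad_input(self, bad):
        with pytest.raises(ValueError):
            at_content(bad)

    def test_duplex_bottom_strand_is_reverse_complement(self):
        d = DuplexSequence("ATGCCA")
        assert d.bottom == "TGGCAT" == reverse_complement(d.top)


class TestHelicalStep:
    def test_full_turn_is_pure_translation(self):
        p = HelicalParameters(rise=3.38, twist=36.0)
        t = helical_step(p, 10)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
        assert np.linalg.norm(t.translation) == pytest.approx(33.8, abs=1e-9)

    def test_zero_step_is_identity(self):
        assert helical_step(HelicalParameters(), 0).is_identity(atol=1e-12)

    @given(a=st.floats(-15, 15), b=st.floats(-15, 15))
    @settings(max_examples=40, deadline=None)
    def test_one_parameter_group_additivity(self, a, b):
        p = HelicalParameters(rise=3.38, twist=34.3,
                              axis=[0.3, -0.2, 0.93], anchor=[1.0, 2.0, -3.0])
        lhs = helical_step(p, a).compose(helical_step(p, b))
        rhs = helical_step(p, a + b)
        assert np.allclose(lhs.rotation, rhs.rotation, atol=1e-9)
        assert np.allclose(lhs.translation, rhs.translation, atol=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HelicalParameters(rise=-1.0)
        with pytest.raises(ValueError):
            HelicalParameters(twist=90.0)


class TestBuildBdna:
    def test_base_pair_centers_spaced_by_rise(self):
        s = build_bdna("ATGCATGCAT", HelicalParameters(rise=3.38, twist=36.0))
        centers = base_pair_centers(s)
        gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        assert gaps == pytest.approx(3.38, abs=1e-6)

    def test_projected_twist_between_consecutive_pairs(self):
        s = build_bdna("ATGCATGCAT")
        top, bottom = s.chains
        n = len(top.residues)

        def c1c1(i):
            return (bottom.residues[n - 1 - i].atom("C1'").coords
                    - top.residues[i].atom("C1'").coords)

        v0, v1 = c1c1(0)[:2], c1c1(1)[:2]
        ang = math.degrees(math.atan2(v0[0] * v1[1] - v0[1] * v1[0],
                                      float(np.dot(v0, v1))))
        assert ang == pytest.approx(36.0, abs=0.1)

    def test_sequence_roundtrip_and_backbone_names(self):
        seq = "ATGCCGTA"
        s = build_bdna(seq)
        assert duplex_sequence_of(s).top == seq
        internal = s.chains[0].residues[3]
        for name in BACKBONE_ATOMS:
            assert internal.has_atom(name)

    def test_terminal_nucleotides_lack_phosphate(self):
        s = build_bdna("A")
        assert sum(len(c.residues) for c in s.chains) == 2
        for chain in s.chains:
            for res in chain.residues:
                assert not res.has_atom("P")
        # both 5' ends of a longer duplex too
        s = build_bdna("ATGC")
        assert not s.chains[0].residues[0].has_atom("P")
        assert not s.chains[1].residues[0].has_atom("P")
        assert s.chains[0].residues[1].has_atom("P")

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            build_bdna("ATXG")

    def test_helix_axis_of_ideal_duplex_is_z(self):
        p = HelicalParameters()
        ax = helix_axis(build_bdna("ATGCATGC", p))
        assert abs(ax.axis @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)


class TestThreading:
    def test_self_threading_is_near_identity(self):
        s = build_bdna("ATGCAT")
        t = thread_sequence(s, ("A", "B"), "ATGCAT")
        assert duplex_sequence_of(t).top == "ATGCAT"
        rmsd = np.sqrt(np.mean((t.coords() - s.coords()) ** 2))
        assert rmsd < 0.3

    def test_backbone_exactly_preserved_for_any_sequence(self):
        s = build_bdna("ATGCAT")
        t = thread_sequence(s, ("A", "B"), "GGGGGG")
        for c0, c1 in zip(s.chains, t.chains):
            for r0, r1 in zip(c0.residues, c1.residues):
                for name in BACKBONE_ATOMS:
                    if r0.has_atom(name):
                        assert np.array_equal(r0.atom(name).coords,
                                              r1.atom(name).coords)

    def test_purine_replacing_guanine_gets_adenine_atom_set(self):
        s = build_bdna("GGG")
        t = thread_sequence(s, ("A", "B"), "AAA")
        res = t.chains[0].residues[1]
        assert res.name == "DA"
        names = {a.name for a in res.atoms}
        assert {"N9", "N7", "C8", "N6", "N1", "C2", "N3"} <= names
        assert "O6" not in names and "N2" not in names  # guanine-only atoms gone

    def test_idempotent_for_same_target(self):
        s = build_bdna("ATGC")
        once = thread_sequence(s, ("A", "B"), "TTAA")
        twice = thread_sequence(once, ("A", "B"), "TTAA")
        assert np.abs(once.coords() - twice.coords()).max() < 1e-9

    def test_length_mismatch_rejected(self):
        s = build_bdna("ATGC")
        with pytest.raises(ValueError, match="length"):
            thread_sequence(s, ("A", "B"), "AT")

    def test_missing_c1_names_residue(self):
        s = build_bdna("ATGC")
        res = s.chains[0].residues[2]
        res.atoms = [a for a in res.atoms if a.name != "C1'"]
        with pytest.raises(ValueError, match="C1'"):
            thread_sequence(s, ("A", "B"), "ATGC")

    def test_screw_composition_matches_direct_placement(self):
        # stepping a built duplex by the screw transform overlays it on the
        # corresponding downstream base pairs of a longer duplex
        p = HelicalParameters()
        long = build_bdna("ATGCATGCAT", p)
        centers = base_pair_centers(long)
        t = helical_step(p, 3)
        stepped = t.apply(centers[:5])
        assert np.allclose(stepped, centers[3:8], atol=1e-9)
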