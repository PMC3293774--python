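"""Template admissibility, motif fitting, dimer closure, and model ranking."""

import numpy as np
import pytest

from wingdock.fixtures import DEFAULT_MOTIF_LAYOUT, make_template_complex
from wingdock.geometry import RigidTransform
from wingdock.structure import Atom, Chain, Residue, Structure, apply_transform
from wingdock.surface import ContactReport
from wingdock.templates import (DockModel, MotifSpec, Restraint, RestraintSet,
                                TemplateComplex, check_template_criteria,
                                close_dimer, fit_monomer, rank_models)


def pairwise_distances(coords):
    return np.linalg.norm(coords[:, None] - coords[None], axis=-1)


class TestCriteria:
    def test_valid_synthetic_template_passes_all(self, template):
        rep = check_template_criteria(template)
        assert rep.duplex_length_ok and rep.homodimer_ok
        assert rep.wing_topology_ok and rep.resolution_ok
        assert rep.overall

    def test_short_duplex_fails_size_criterion(self):
        t = make_template_complex(dna_seq="ATATTAATTATATATTAA")  # 18 bp
        rep = check_template_criteria(t)
        assert not rep.duplex_length_ok and not rep.overall
        assert rep.homodimer_ok

    def test_heterodimer_fails_homodimer_criterion(self, template):
        st = template.structure.copy()
        st.chain("Q").residues[0].name = "ALA"
        t = TemplateComplex(st, template.motif, template.dna_chains,
                            template.resolution)
        rep = check_template_criteria(t)
        assert not rep.homodimer_ok and not rep.overall

    def test_single_wing_strand_fails_topology(self):
        layout = {k: v for k, v in DEFAULT_MOTIF_LAYOUT.items() if k != "S2"}
        t = make_template_complex(motif_layout=layout)
        assert not check_template_criteria(t).wing_topology_ok

    def test_poor_resolution_fails(self, template):
        t = TemplateComplex(template.structure, template.motif,
                            template.dna_chains, resolution=3.5)
        assert not check_template_criteria(t).resolution_ok

    def test_missing_motif_is_an_error(self, template):
        with pytest.raises(ValueError, match="MotifSpec"):
            TemplateComplex(template.structure, None, template.dna_chains, 2.0)


class TestMotifSpec:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            MotifSpec(segments={"H4": (("P", 10, 20),), "S1": (("P", 18, 25),)})

    def test_recognition_helix_must_be_present(self):
        with pytest.raises(ValueError, match="recognition helix"):
            MotifSpec(segments={"H3": (("P", 1, 5),)})


class TestFitMonomer:
    def test_self_fit_is_identity(self, fitted):
        assert fitted.fit_rmsd == pytest.approx(0.0, abs=1e-9)
        t = fitted.transforms[0]
        assert t.is_identity(atol=1e-6)

    def test_recovers_known_displacement(self, template, toy_monomer, rng):
        monomer, motif = toy_monomer
        t0 = RigidTransform.from_rotvec(rng.normal(scale=0.5, size=3),
                                        rng.normal(scale=10.0, size=3))
        displaced = apply_transform(monomer, t0.inverse())
        model = fit_monomer(displaced, motif, template)
        assert model.fit_rmsd < 1e-6
        assert np.allclose(model.transforms[0].rotation, t0.rotation, atol=1e-6)
        assert np.allclose(model.transforms[0].translation, t0.translation,
                           atol=1e-5)

    def test_rigid_placement_preserves_internal_geometry(self, template,
                                                         toy_monomer, rng):
        monomer, motif = toy_monomer
        displaced = apply_transform(
            monomer, RigidTransform.from_rotvec(rng.normal(size=3),
                                                rng.normal(scale=20, size=3)))
        model = fit_monomer(displaced, motif, template)
        placed = model.structure.subset(model.protein_chains).coords()
        original = monomer.coords()
        assert np.abs(pairwise_distances(placed)
                      - pairwise_distances(original)).max() < 1e-9

    def test_unresolvable_range_is_an_error(self, template, toy_monomer):
        monomer, _ = toy_monomer
        bad = MotifSpec(segments={"H4": (("P", 900, 910),),
                                  "S1": (("P", 920, 923),),
                                  "S2": (("P", 930, 933),)})
        with pytest.raises(ValueError, match="resolves"):
            fit_monomer(monomer, bad, template)

    def test_fit_rmsd_bit_identical_across_runs(self, template, toy_monomer):
        monomer, motif = toy_monomer
        r1 = fit_monomer(monomer, motif, template, "H3H4S1S2").fit_rmsd
        r2 = fit_monomer(monomer, motif, template, "H3H4S1S2").fit_rmsd
        assert r1 == r2


class TestCloseDimer:
    def test_already_satisfying_dimer_refines_to_zero(self, fitted, toy_dimer,
                                                      template_restraints):
        dimer, motifs = toy_dimer
        closed = close_dimer(fitted, dimer, motifs, template_restraints,
                             compute_contact=False)
        assert closed.restraint_rms == pytest.approx(0.0, abs=1e-6)
        assert closed.converged

    def test_recovers_from_small_displacement(self, fitted, toy_dimer,
                                              template_restraints):
        dimer, motifs = toy_dimer
        pert = RigidTransform.from_rotvec([0.02, -0.015, 0.01], [0.3, -0.2, 0.1])
        st = fitted.structure.copy()
        chain = st.chain(fitted.protein_chains[0])
        for atom in chain.atoms():
            atom.coords = pert.apply(atom.coords)
        displaced = DockModel(structure=st,
                              protein_chains=fitted.protein_chains,
                              dna_chains=fitted.dna_chains,
                              motif=fitted.motif,
                              superposition_type=fitted.superposition_type)
        closed = close_dimer(displaced, dimer, motifs, template_restraints,
                             compute_contact=False)
        assert closed.restraint_rms < 0.1

    def test_objective_log_is_monotone_descent(self, fitted, toy_dimer,
                                               template_restraints):
        dimer, motifs = toy_dimer
        closed = close_dimer(fitted, dimer, motifs, template_restraints,
                             compute_contact=False)
        log = np.asarray(closed.objective_log)
        assert np.all(np.diff(log) <= 1e-12)

    def test_dimer_internal_geometry_untouched(self, fitted, toy_dimer,
                                               template_restraints):
        dimer, motifs = toy_dimer
        closed = close_dimer(fitted, dimer, motifs, template_restraints,
                             compute_contact=False)
        final = closed.structure.subset(closed.protein_chains).coords()
        assert np.abs(pairwise_distances(final)
                      - pairwise_distances(dimer.coords())).max() < 1e-9

    def test_fewer_than_three_restraints_rejected(self, fitted, toy_dimer,
                                                  template_restraints):
        dimer, motifs = toy_dimer
        two = RestraintSet(tuple(template_restraints)[:2])
        with pytest.raises(ValueError, match="3 restraints"):
            close_dimer(fitted, dimer, motifs, two)

    def test_restraint_validation(self):
        with pytest.raises(ValueError, match="> 0"):
            Restraint(("P", 1, "CA"), ("A", 1, "P"), target=-2.0)


def _dummy_model(cs, label, restraint_rms=None):
    s = Structure(label, [Chain("Z", [
        Residue("GLY", 1, "", [Atom("CA", "C", [0, 0, 0])])])])
    return DockModel(structure=s, protein_chains=("Z",), dna_chains=("Z", "Z"),
                     contact=ContactReport(2 * cs, 0.0, 0.0),
                     restraint_rms=restraint_rms, label=label)


class TestRankModels:
    def test_h4s1s2_contact_surfaces_rank_expected_template_first(self):
        models = [_dummy_model(cs, name) for name, cs in
                  [("1C0W", 900.0), ("1SAX", 890.0), ("1U8R", 949.0),
                   ("1Z9C", 1006.0)]]
        ranked = rank_models(models)
        assert ranked[0].label == "1Z9C"
        assert [m.contact.cs for m in ranked] == [1006.0, 949.0, 900.0, 890.0]

    def test_final_model_contact_surfaces_order(self):
        models = [_dummy_model(cs, str(cs)) for cs in (1852.0, 1083.0, 1230.0)]
        assert [m.contact.cs for m in rank_models(models)] == [1852.0, 1230.0,
                                                               1083.0]

    def test_ties_broken_by_restraint_rms_then_input_order(self):
        a = _dummy_model(500.0, "a", restraint_rms=0.5)
        b = _dummy_model(500.0, "b", restraint_rms=0.1)
        c = _dummy_model(500.0, "c", restraint_rms=0.1)
        assert [m.label for m in rank_models([a, b, c])] == ["b", "c", "a"]

    def test_single_model_returned_unchanged(self):
        m = _dummy_model(10.0, "only")
        assert rank_models([m]) == [m]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            rank_models([])
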