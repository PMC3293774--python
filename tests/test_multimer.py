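"""Dimer sliding, spacing classification, multimer assembly, switch logic."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wingdock.fixtures import ToyDimerSpec, make_toy_dimer_complex
from wingdock.multimer import (build_multimer,
                               multimer_footprint_span, place_dimer_at_offset,
                               scan_spacings, switch_report)
from wingdock.promoter import GenePromoter
from wingdock.surface import sasa

RISE, TWIST = 3.38, 36.0
SPHERE_R = 8.0          # sphere-pair lobe radius in the session fixture
LOBE_RADIUS = 19.0      # lobe center distance from the helix axis
PROBE = 1.4


def lobe_centers(model):
    return np.array([list(model.structure.chain(c).atoms())[0].coords
                     for c in model.protein_chains])


def sphere_oracle_label(centers, offset, thresholds):
    """Closed-form classification of a sphere-pair dimer at a given offset.

    Uses rotation matrices and sphere-cap geometry directly, independent of
    the screw-transform and SASA code paths under test.
    """
    ang = np.deg2rad(TWIST * offset)
    R = Rotation.from_rotvec([0, 0, ang]).as_matrix()
    moved = centers @ R.T + [0, 0, RISE * offset]
    dmin = min(np.linalg.norm(a - b) for a in centers for b in moved)
    if dmin < 2 * SPHERE_R - thresholds.overlap_tol:
        return "clash"
    solvent_r = SPHERE_R + PROBE
    # CS of two spheres = 2*pi*R*h per the cap formula, summed over pairs
    cs = 0.0
    for a in centers:
        for b in moved:
            d = np.linalg.norm(a - b)
            if d < 2 * solvent_r:
                cs += 2 * np.pi * solvent_r * (solvent_r - d / 2)
    return "contact" if cs >= thresholds.cs_min else "separated"


class TestPlacement:
    def test_zero_offset_is_coincident(self, sphere_model):
        model, _ = sphere_model
        placed = place_dimer_at_offset(model, 0)
        original = model.structure.subset(model.protein_chains)
        assert np.abs(placed.coords() - original.coords()).max() < 1e-9

    def test_full_turn_is_pure_translation(self, sphere_model):
        model, _ = sphere_model
        placed = place_dimer_at_offset(model, 10)
        original = model.structure.subset(model.protein_chains)
        assert np.allclose(placed.coords(),
                           original.coords() + [0, 0, 10 * RISE], atol=1e-8)

    def test_offsets_compose_additively(self, sphere_model):
        from wingdock.templates import DockModel

        model, _ = sphere_model
        first = place_dimer_at_offset(model, 3)
        chains = [c.copy() for c in first.chains] + \
            [model.structure.chain(c).copy() for c in model.dna_chains]
        from wingdock.structure import Structure
        intermediate = DockModel(
            structure=Structure("step", chains),
            protein_chains=model.protein_chains, dna_chains=model.dna_chains)
        two_step = place_dimer_at_offset(intermediate, 4)
        one_step = place_dimer_at_offset(model, 7)
        assert np.abs(two_step.coords() - one_step.coords()).max() < 1e-8

    def test_offset_beyond_duplex_rejected(self, sphere_model):
        model, _ = sphere_model
        with pytest.raises(ValueError, match="exceeds"):
            place_dimer_at_offset(model, 44)


@pytest.fixture(scope="module")
def scan(sphere_model):
    model, radii = sphere_model
    return scan_spacings(model, 30, radii=radii, n_points=480,
                         include_dna_buried=False)


@pytest.fixture(scope="module")
def small_sphere_model():
    # lobes small enough that 3 bp spacing does not clash
    spec = ToyDimerSpec(envelope="sphere-pair", atom_radius=3.0, standoff=1.0)
    return make_toy_dimer_complex(spec, "AT" * 30)


class TestScanSpacings:
    def test_labels_match_sphere_geometry_oracle(self, sphere_model, scan):
        model, _ = sphere_model
        centers = lobe_centers(model)
        for rec in scan.records:
            expected = sphere_oracle_label(centers, rec.offset_bp,
                                           scan.thresholds)
            assert rec.label == expected, f"offset {rec.offset_bp}"

    def test_classification_is_threshold_consistent(self, scan):
        for rec in scan.records:
            if rec.label == "clash":
                assert rec.n_clash > 0
            elif rec.label == "contact":
                assert rec.n_clash == 0
                assert rec.cs_dd >= scan.thresholds.cs_min
            else:
                assert rec.n_clash == 0
                assert rec.cs_dd < scan.thresholds.cs_min

    def test_tail_beyond_last_contact_is_separated(self, sphere_model, scan):
        model, _ = sphere_model
        centers = lobe_centers(model)
        oracle = [sphere_oracle_label(centers, s, scan.thresholds)
                  for s in range(1, 31)]
        last_interacting = max(i for i, lbl in enumerate(oracle)
                               if lbl != "separated")
        for rec in scan.records[last_interacting + 1:]:
            assert rec.label == "separated"

    def test_dna_overlap_plateaus_at_twice_single_dimer(self, sphere_model):
        model, radii = sphere_model
        scan = scan_spacings(model, 15, radii=radii, n_points=240,
                             include_dna_buried=True)
        dna = model.structure.subset(model.dna_chains)
        dimer = model.structure.subset(model.protein_chains)
        dna_atoms = list(dna.atoms())
        free = sasa(dna_atoms, radii, n_points=240).total
        with_one = sasa(dna_atoms + list(dimer.atoms()), radii,
                        n_points=240).per_atom[:len(dna_atoms)].sum()
        single = free - with_one
        # a full helical turn is a pure translation of the copy, so the two
        # copies bury exactly twice the single-dimer area
        full_turn = scan.record(10)
        assert full_turn.label == "separated"
        assert full_turn.dna_overlapped_surface == pytest.approx(2 * single,
                                                                 rel=0.01)
        # past the contact regime the buried area never exceeds the 2x
        # plateau (within sampling noise); comparisons between offsets are
        # made a full turn apart so the copies sample the same azimuth
        tail = {r.offset_bp: r.dna_overlapped_surface
                for r in scan.records if r.label == "separated"}
        for s, value in tail.items():
            assert value <= 2 * single * 1.05
        for s in (2, 3):
            if s in tail and s + 10 in tail:
                assert tail[s + 10] <= tail[s] * 1.05

    def test_max_offset_beyond_capacity_rejected(self, sphere_model):
        model, radii = sphere_model
        with pytest.raises(ValueError, match="exceeds"):
            scan_spacings(model, 60, radii=radii)


class TestBuildMultimer:
    def test_hexamer_0_3_6_assembles_without_clash(self, small_sphere_model):
        model, radii = small_sphere_model
        mm = build_multimer(model, [0, 3, 6], radii=radii,
                            compute_surfaces=False)
        assert len(mm.copy_chains) == 3
        assert mm.offsets == (0, 3, 6)

    def test_seven_dimer_polymer_at_6bp_spacing(self, small_sphere_model):
        model, radii = small_sphere_model
        offsets = [0, 6, 12, 18, 24, 30, 36]
        mm = build_multimer(model, offsets, radii=radii, compute_surfaces=False)
        assert len(mm.copy_chains) == 7
        ids = [cid for copy in mm.copy_chains for cid in copy]
        assert len(ids) == len(set(ids))  # unique chain ids in the assembly

    def test_clashing_offsets_error_names_pair(self, sphere_model):
        model, radii = sphere_model
        with pytest.raises(ValueError, match="0 and 1"):
            build_multimer(model, [0, 1], radii=radii)

    def test_force_overrides_clash(self, sphere_model):
        model, radii = sphere_model
        mm = build_multimer(model, [0, 1], radii=radii, force=True,
                            compute_surfaces=False)
        assert len(mm.copy_chains) == 2

    @pytest.mark.parametrize("offsets", [[], [0, 0], [3, 6], [0, 6, 3]])
    def test_invalid_offset_lists_rejected(self, sphere_model, offsets):
        model, radii = sphere_model
        with pytest.raises(ValueError):
            build_multimer(model, offsets, radii=radii)

    def test_assembly_metrics_consistent_with_scan(self, sphere_model):
        model, radii = sphere_model
        scan = scan_spacings(model, 5, radii=radii, n_points=240,
                             include_dna_buried=False)
        mm = build_multimer(model, [0, 5], radii=radii, n_points=240)
        assert mm.adjacent_cs[0] == scan.record(5).cs_dd


class TestFootprintSpan:
    @pytest.mark.parametrize("offsets,footprint,expected", [
        ([0, 3, 6], 21, 27),
        ([0, 6, 12], 21, 33),
        ([0], 21, 21),
    ])
    def test_span_arithmetic(self, offsets, footprint, expected):
        assert multimer_footprint_span(offsets, footprint) == expected

    def test_span_formula_property(self, rng):
        for _ in range(20):
            offs = np.unique(rng.integers(1, 40, size=4)).tolist()
            offs = [0] + offs
            w = int(rng.integers(1, 30))
            assert multimer_footprint_span(offs, w) == w + max(offs)

    @pytest.mark.parametrize("offsets,footprint", [
        ([], 21), ([0, 3], 0), ([3, 6], 21), ([0, 6, 3], 21),
    ])
    def test_invalid_inputs_rejected(self, offsets, footprint):
        with pytest.raises(ValueError):
            multimer_footprint_span(offsets, footprint)


class TestSwitchReport:
    @pytest.fixture
    def genes(self):
        return {
            "left": GenePromoter("left", "-", 105, minus10=(112, 117),
                                 minus35=(135, 140)),
            "right": GenePromoter("right", "+", 195, minus10=(183, 188)),
        }

    def test_interval_covering_both_minus10_blocks_both(self, genes):
        rep = switch_report((110, 190), genes)
        assert rep.verdict("left") == "blocked"
        assert rep.verdict("right") == "blocked"

    def test_interval_overlapping_neither_frees_both(self, genes):
        rep = switch_report((10, 60), genes)
        assert rep.verdict("left") == "free"
        assert rep.verdict("right") == "free"

    def test_removing_end_dimer_flips_one_gene(self, genes):
        # a multimer anchored at 100 spanning both promoters blocks both genes
        anchor = 100
        span_full = multimer_footprint_span([0, 33, 66], 21)      # 87 bp
        rep_full = switch_report((anchor, anchor + span_full - 1), genes)
        assert rep_full.verdict("left") == "blocked"
        assert rep_full.verdict("right") == "blocked"
        # drop the right-end dimer: the protected interval retreats leftward
        span_reduced = multimer_footprint_span([0, 33], 21)       # 54 bp
        rep_reduced = switch_report((anchor, anchor + span_reduced - 1), genes)
        assert rep_reduced.verdict("left") == "blocked"
        assert rep_reduced.verdict("right") == "free"

    def test_inverted_interval_rejected(self, genes):
        with pytest.raises(ValueError):
            switch_report((50, 40), genes)
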