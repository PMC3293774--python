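"""Template admissibility, motif-based monomer fitting, and dimer closure.

The protocol models a winged helix-turn-helix (wHTH) dimer bound to DNA by
analogy with an experimentally solved template complex:

1.  A candidate template must pass four admissibility criteria — target
    duplex of at least 20 bp, homodimeric protein, an HTH whose recognition
    helix is followed by two antiparallel beta-strands (the wing), and
    adequate crystallographic resolution.
2.  The target monomer is rigidly fitted onto the template by least-squares
    superposition of the backbone of a superposition motif — the recognition
    helix plus the wing strands (H4+S1+S2), optionally including the
    preceding helix (H3+H4+S1+S2) — which places its recognition helix in
    the template DNA's major groove.
3.  The complex is closed by matching the intact dimer onto the placed
    monomer and then refining a single rigid-body transform of the whole
    dimer against distance restraints between motif atoms and the DNA
    backbone.  Only rigid motions are ever applied, so the protein's
    internal geometry is preserved exactly.

Candidate models are ranked by the contact surface of the final dimer-DNA
interface (association free energies are out of scope here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform, superpose
from .structure import Structure, apply_transform
from .surface import DEFAULT_RADII, ContactReport, RadiiSet, contact_surface

__all__ = [
    "MotifSpec", "TemplateComplex", "Restraint", "RestraintSet", "DockModel",
    "CriteriaReport", "check_template_criteria", "fit_monomer", "close_dimer",
    "rank_models", "restraints_from_template",
]

BACKBONE_PROTEIN = ("N", "CA", "C", "O")

_SUPERPOSITION_SEGMENTS = {
    "H4S1S2": ("H4", "S1", "S2"),
    "H3H4S1S2": ("H3", "H4", "S1", "S2"),
}


@dataclass(frozen=True)
class MotifSpec:
    """Residue ranges of the secondary-structure elements of one monomer.

    `segments` maps element names (H1…H5, S1…S5) to lists of
    ``(chain_id, first_seq_id, last_seq_id)`` ranges (inclusive, author
    numbering).  `wing_antiparallel` records the annotation that the two
    strands following the recognition helix pair antiparallel — this is
    supplied, not predicted.
    """

    segments: dict[str, tuple[tuple[str, int, int], ...]]
    recognition_helix: str = "H4"
    superposition_type: str = "H4S1S2"
    wing_antiparallel: bool = True

    def __post_init__(self) -> None:
        segs = {
            name: tuple(tuple(r) for r in ranges)
            for name, ranges in self.segments.items()
        }
        object.__setattr__(self, "segments", segs)
        if self.recognition_helix not in segs:
            raise ValueError(
                f"recognition helix {self.recognition_helix!r} not among segments "
                f"{sorted(segs)}")
        if self.superposition_type not in _SUPERPOSITION_SEGMENTS:
            raise ValueError(f"unknown superposition type {self.superposition_type!r}")
        # ranges must not overlap within a chain
        per_chain: dict[str, list[tuple[int, int, str]]] = {}
        for name, ranges in segs.items():
            for chain, lo, hi in ranges:
                if lo > hi:
                    raise ValueError(f"segment {name}: inverted range {lo}-{hi}")
                per_chain.setdefault(chain, []).append((lo, hi, name))
        for chain, ranges in per_chain.items():
            ranges.sort()
            for (lo1, hi1, n1), (lo2, hi2, n2) in zip(ranges, ranges[1:]):
                if lo2 <= hi1:
                    raise ValueError(
                        f"segments {n1} and {n2} overlap on chain {chain}")

    def segment_names(self) -> tuple[str, ...]:
        return tuple(self.segments)

    def residues(self, structure: Structure, names=None):
        """Motif residues in segment order; raises if a range is unresolvable."""
        names = names or self.segment_names()
        out = []
        for name in names:
            if name not in self.segments:
                raise KeyError(f"motif has no segment {name!r}")
            for chain_id, lo, hi in self.segments[name]:
                chain = structure.chain(chain_id)
                found = [r for r in chain.residues if lo <= r.seq_id <= hi]
                if len(found) != hi - lo + 1:
                    raise ValueError(
                        f"segment {name}: range {chain_id}:{lo}-{hi} resolves to "
                        f"{len(found)} residues (expected {hi - lo + 1})")
                out.extend(found)
        return out

    def backbone_coords(self, structure: Structure, names=None) -> np.ndarray:
        """(N, 3) backbone (N, CA, C, O) coordinates over motif residues."""
        coords = []
        for res in self.residues(structure, names):
            for atom_name in BACKBONE_PROTEIN:
                if not res.has_atom(atom_name):
                    raise ValueError(
                        f"residue {res.name} {res.seq_id} lacks backbone atom "
                        f"{atom_name}")
                coords.append(res.atom(atom_name).coords)
        return np.array(coords)

    def wing_strands_after_recognition_helix(self) -> tuple[str, ...]:
        """Strand segments that start (in seq_id) after the recognition helix."""
        helix_end = max(hi for _, _, hi in self.segments[self.recognition_helix])
        strands = [
            name for name, ranges in self.segments.items()
            if name.startswith("S") and min(lo for _, lo, _ in ranges) > helix_end
        ]
        strands.sort(key=lambda n: min(lo for _, lo, _ in self.segments[n]))
        return tuple(strands)


@dataclass(frozen=True)
class TemplateComplex:
    """An experimental (or synthetic) protein-DNA complex used as template."""

    structure: Structure
    motif: MotifSpec
    dna_chains: tuple[str, str]
    resolution: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.motif is None:
            raise ValueError("template requires a MotifSpec")
        protein = [c for c in self.structure.chains if c.kind == "protein"]
        if not protein:
            raise ValueError("template has no protein chain")
        for cid in self.dna_chains:
            if self.structure.chain(cid).kind != "dna":
                raise ValueError(f"chain {cid} is not DNA")

    def duplex_length(self) -> int:
        return min(len(self.structure.chain(c).residues) for c in self.dna_chains)

    def protein_chain_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.structure.chains if c.kind == "protein")


@dataclass(frozen=True)
class CriteriaReport:
    duplex_length_ok: bool
    homodimer_ok: bool
    wing_topology_ok: bool
    resolution_ok: bool
    details: dict = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return (self.duplex_length_ok and self.homodimer_ok
                and self.wing_topology_ok and self.resolution_ok)


def check_template_criteria(t: TemplateComplex, min_bp: int = 20,
                            max_resolution: float = 3.0) -> CriteriaReport:
    """Evaluate the four template admissibility criteria.

    1. duplex target site of at least `min_bp` base pairs;
    2. the DNA-bound protein is a homodimer (two chains, identical residue
       sequences);
    3. the recognition helix is followed in sequence by two strand segments
       annotated antiparallel (wing topology, from the MotifSpec);
    4. crystallographic resolution at most `max_resolution` Å.
    """
    n_bp = t.duplex_length()
    protein_ids = t.protein_chain_ids()
    sequences = [t.structure.chain(cid).sequence() for cid in protein_ids]
    homodimer = len(protein_ids) == 2 and sequences[0] == sequences[1]
    strands = t.motif.wing_strands_after_recognition_helix()
    wing_ok = len(strands) >= 2 and t.motif.wing_antiparallel
    res_ok = t.resolution is not None and t.resolution <= max_resolution
    return CriteriaReport(
        duplex_length_ok=n_bp >= min_bp,
        homodimer_ok=homodimer,
        wing_topology_ok=wing_ok,
        resolution_ok=res_ok,
        details={
            "duplex_length": n_bp, "min_bp": min_bp,
            "protein_chains": protein_ids,
            "wing_strands": strands,
            "resolution": t.resolution, "max_resolution": max_resolution,
        },
    )


@dataclass
class DockModel:
    """An assembled (protein + DNA) model and the record of how it was built."""

    structure: Structure
    protein_chains: tuple[str, ...]
    dna_chains: tuple[str, str]
    transforms: list[RigidTransform] = field(default_factory=list)
    motif: MotifSpec | None = None
    superposition_type: str | None = None
    fit_rmsd: float | None = None
    restraint_rms: float | None = None
    contact: ContactReport | None = None
    converged: bool = True
    objective_log: tuple[float, ...] = ()
    label: str = ""

    def protein_atoms(self):
        out = []
        for cid in self.protein_chains:
            out.extend(self.structure.chain(cid).atoms())
        return out

    def dna_atoms(self):
        out = []
        for cid in self.dna_chains:
            out.extend(self.structure.chain(cid).atoms())
        return out

    @property
    def cs(self) -> float | None:
        return None if self.contact is None else self.contact.cs


def _assemble(protein_src: Structure, protein_ids, dna_src: Structure, dna_ids,
              name: str) -> Structure:
    chains = [protein_src.chain(cid).copy() for cid in protein_ids]
    chains += [dna_src.chain(cid).copy() for cid in dna_ids]
    ids = [c.id for c in chains]
    if len(ids) != len(set(ids)):
        raise ValueError(f"chain id collision between protein and DNA: {ids}")
    return Structure(name=name, chains=chains, provenance={"transforms": []})


def fit_monomer(monomer: Structure, monomer_motif: MotifSpec,
                template: TemplateComplex,
                superposition_type: str | None = None) -> DockModel:
    """Rigidly place a monomer on the template DNA via its wHTH motif.

    Superposes the backbone (N, CA, C, O) of the chosen superposition motif
    of `monomer` onto the equivalent atoms of the template's bound protein,
    then applies the resulting transform to the whole monomer.  The placed
    monomer is returned assembled with a copy of the template DNA; its
    internal geometry is untouched (rigid placement).
    """
    sup_type = superposition_type or monomer_motif.superposition_type
    if sup_type not in _SUPERPOSITION_SEGMENTS:
        raise ValueError(f"unknown superposition type {sup_type!r}")
    segs = _SUPERPOSITION_SEGMENTS[sup_type]
    mobile = monomer_motif.backbone_coords(monomer, segs)
    reference = template.motif.backbone_coords(template.structure, segs)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"superposition motifs differ in size: {mobile.shape[0]} vs "
            f"{reference.shape[0]} backbone atoms")
    transform, rmsd = superpose(mobile, reference)
    placed = apply_transform(monomer, transform)
    protein_ids = tuple(c.id for c in placed.chains)
    structure = _assemble(placed, protein_ids, template.structure,
                          template.dna_chains, name=f"fit-{template.name}")
    return DockModel(
        structure=structure,
        protein_chains=protein_ids,
        dna_chains=template.dna_chains,
        transforms=[transform],
        motif=monomer_motif,
        superposition_type=sup_type,
        fit_rmsd=rmsd,
        label=template.name,
    )


@dataclass(frozen=True)
class Restraint:
    """A target distance between a protein atom and a DNA atom.

    Atom selectors are ``(chain_id, seq_id, atom_name)`` triples.
    """

    protein_atom: tuple[str, int, str]
    dna_atom: tuple[str, int, str]
    target: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise ValueError(f"restraint target distance must be > 0, got {self.target}")
        if self.weight <= 0:
            raise ValueError("restraint weight must be > 0")


@dataclass(frozen=True)
class RestraintSet:
    restraints: tuple[Restraint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "restraints", tuple(self.restraints))

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)


def _atom_coords(structure: Structure, selector) -> np.ndarray:
    chain_id, seq_id, atom_name = selector
    return structure.chain(chain_id).residue(seq_id).atom(atom_name).coords


def restraints_from_template(placed: DockModel, helix_segment: str = "H4",
                             dna_atom_name: str = "P",
                             weight: float = 1.0) -> RestraintSet:
    """Measure default restraints from an already-placed model.

    For each CA of the recognition-helix segment, the nearest DNA atom named
    `dna_atom_name` (phosphate by default) is taken as partner with the
    observed distance as target — restraints encoding the wHTH/DNA geometry
    of the template pattern.  Override with explicit restraints where the
    template geometry should not be trusted.
    """
    if placed.motif is None:
        raise ValueError("model carries no motif; cannot derive restraints")
    dna_atoms = [
        (cid, res.seq_id, atom.name, atom.coords)
        for cid in placed.dna_chains
        for res in placed.structure.chain(cid).residues
        for atom in res.atoms
        if atom.name == dna_atom_name
    ]
    if not dna_atoms:
        raise ValueError(f"no DNA atoms named {dna_atom_name!r}")
    out = []
    for res in placed.motif.residues(placed.structure, (helix_segment,)):
        if not res.has_atom("CA"):
            continue
        ca = res.atom("CA").coords
        dists = [np.linalg.norm(ca - coords) for *_, coords in dna_atoms]
        k = int(np.argmin(dists))
        cid, seq_id, name, _ = dna_atoms[k]
        chain_id = placed.motif.segments[helix_segment][0][0]
        out.append(Restraint((chain_id, res.seq_id, "CA"), (cid, seq_id, name),
                             float(dists[k]), weight))
    return RestraintSet(tuple(out))


# eight fixed axis-angle perturbations (body-diagonal axes, 0.1 rad) used to
# multi-start the rigid refinement deterministically
_MULTISTART_AXES = [
    np.array([sx, sy, sz]) / np.sqrt(3.0)
    for sx in (1.0, -1.0) for sy in (1.0, -1.0) for sz in (1.0, -1.0)
]
_MULTISTART_ANGLE = 0.1


def close_dimer(partial: DockModel, dimer: Structure, dimer_motifs,
                restraints: RestraintSet, max_iter: int = 400,
                probe: float = 1.4, radii: RadiiSet = DEFAULT_RADII,
                n_points: int = 240,
                compute_contact: bool = True) -> DockModel:
    """Close the complex by placing the intact dimer onto the DNA.

    Two steps, both rigid:

    1. superpose the dimer onto the partial model through the motif of the
       already-placed monomer (``dimer_motifs['A']``, or a bare MotifSpec);
    2. refine a single rigid transform of the whole dimer that minimises the
       weighted sum of squared restraint violations, with a deterministic
       derivative-free optimiser multi-started from 8 fixed axis-angle
       perturbations (plus the unperturbed start); the best objective wins,
       ties broken by the smaller parameter norm.

    The dimer interface and all internal distances are untouched.  At least
    3 restraints are required.  Non-convergence is flagged on the result
    (``converged=False``), never silent.
    """
    from scipy.optimize import minimize

    if len(restraints) < 3:
        raise ValueError(f"dimer closure needs at least 3 restraints, got {len(restraints)}")
    motif_a: MotifSpec = dimer_motifs["A"] if isinstance(dimer_motifs, dict) \
        else dimer_motifs
    if partial.motif is None:
        raise ValueError("partial model carries no motif for step-1 matching")
    sup_type = partial.superposition_type or motif_a.superposition_type
    segs = _SUPERPOSITION_SEGMENTS[sup_type]
    mobile = motif_a.backbone_coords(dimer, segs)
    reference = partial.motif.backbone_coords(partial.structure, segs)
    if mobile.shape != reference.shape:
        raise ValueError("dimer motif does not match the placed monomer motif")
    step1, _ = superpose(mobile, reference)
    dimer0 = apply_transform(dimer, step1)

    dna = partial.structure.subset(partial.dna_chains)
    coords0 = dimer0.coords()
    center = coords0.mean(axis=0)
    prot_idx: list[int] = []
    atom_lookup = {}
    i = 0
    for chain in dimer0.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom_lookup[(chain.id, res.seq_id, atom.name)] = i
                i += 1
    dna_targets = []
    weights = []
    targets = []
    for r in restraints:
        if r.protein_atom not in atom_lookup:
            raise KeyError(f"restraint protein atom {r.protein_atom} not in dimer")
        prot_idx.append(atom_lookup[r.protein_atom])
        dna_targets.append(_atom_coords(dna, r.dna_atom))
        weights.append(r.weight)
        targets.append(r.target)
    prot_idx = np.asarray(prot_idx)
    dna_targets = np.asarray(dna_targets)
    weights = np.asarray(weights)
    targets = np.asarray(targets)
    psel = coords0[prot_idx]

    from scipy.spatial.transform import Rotation

    def transform_points(params, pts):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        return (pts - center) @ R.T + center + params[3:]

    def objective(params):
        moved = transform_points(params, psel)
        d = np.linalg.norm(moved - dna_targets, axis=1)
        return float(np.sum(weights * (d - targets) ** 2))

    starts = [np.zeros(6)]
    starts += [np.concatenate([_MULTISTART_ANGLE * ax, np.zeros(3)])
               for ax in _MULTISTART_AXES]
    best = None
    log: list[float] = []
    for x0 in starts:
        history = [objective(x0)]
        res = minimize(objective, x0, method="Powell",
                       callback=lambda xk: history.append(objective(xk)),
                       options={"maxiter": max_iter, "xtol": 1e-10, "ftol": 1e-12})
        cand = (res.fun, float(np.linalg.norm(res.x)), res, history)
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand
    fbest, _, res, history = best
    # monotone best-so-far trace of the winning start
    log = list(np.minimum.accumulate(history))
    params = res.x
    R = Rotation.from_rotvec(params[:3]).as_matrix()
    step2 = RigidTransform(R, center - R @ center + params[3:])
    final_dimer = apply_transform(dimer0, step2)
    protein_ids = tuple(c.id for c in final_dimer.chains)
    structure = _assemble(final_dimer, protein_ids, partial.structure,
                          partial.dna_chains, name=f"closed-{partial.label}")
    rms = float(np.sqrt(fbest / weights.sum()))
    contact = None
    if compute_contact:
        contact = contact_surface(
            [structure.chain(c) for c in protein_ids],
            [structure.chain(c) for c in partial.dna_chains],
            probe=probe, radii=radii, n_points=n_points)
    return DockModel(
        structure=structure,
        protein_chains=protein_ids,
        dna_chains=partial.dna_chains,
        transforms=[step1, step2],
        motif=motif_a,
        superposition_type=sup_type,
        fit_rmsd=partial.fit_rmsd,
        restraint_rms=rms,
        contact=contact,
        converged=bool(res.success),
        objective_log=tuple(log),
        label=partial.label,
    )


def rank_models(models) -> list[DockModel]:
    """Order models by descending contact surface.

    Ties (identical CS) are broken by lower restraint RMS, then input order.
    Every model must carry a ContactReport.
    """
    models = list(models)
    if not models:
        raise ValueError("no models to rank")
    for m in models:
        if m.contact is None:
            raise ValueError(f"model {m.label!r} has no ContactReport")
    indexed = list(enumerate(models))
    indexed.sort(key=lambda im: (
        -im[1].contact.cs,
        im[1].restraint_rms if im[1].restraint_rms is not None else float("inf"),
        im[0],
    ))
    return [m for _, m in indexed]
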