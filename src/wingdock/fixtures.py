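"""Synthetic fixtures: toy dimers, template complexes, promoter sequences.

These generators make the whole pipeline exercisable without any external
structure or sequence.  They are first-class, deterministic constructions:

* :func:`make_toy_dimer_complex` places a pseudo-atom dimer envelope on an
  ideal duplex whose DNA footprint is *calibrated at construction time*
  against :func:`wingdock.surface.dna_footprint` to hit a requested span;
* :func:`make_template_complex` builds a homodimeric pseudo-protein (ideal
  α-helix and β-strand backbone traces for H1…H5/S1…S5) bound to a duplex,
  with a MotifSpec, so that template admissibility, motif fitting and dimer
  closure have a ground-truth complex to work against;
* :func:`make_promoter_sequence` plants promoter elements (−10/−35 boxes,
  extended −10, AT-only runs, repeat arrays) at exact promoter coordinates
  in a seeded random background and records the ground truth.

Everything is deterministic given its seed (default 0); geometry-only
fixtures use no randomness at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bdna import (DuplexSequence, HelicalParameters, build_bdna,
                   reverse_complement)
from .promoter import GenePromoter, PromoterAnnotation, promoter_to_index
from .structure import Atom, Chain, Residue, Structure
from .surface import DEFAULT_RADII, RadiiSet, dna_footprint
from .templates import DockModel, MotifSpec, TemplateComplex

__all__ = [
    "ToyDimerSpec", "make_toy_dimer_complex", "make_template_complex",
    "make_toy_monomer", "make_toy_dimer_protein", "make_promoter_sequence",
    "DEFAULT_MOTIF_LAYOUT",
]

#: Outer radius of the duplex envelope built by :func:`build_bdna` (Å);
#: used to place pseudo-atoms just off the DNA surface.
_DNA_RADIUS = 10.0


@dataclass(frozen=True)
class ToyDimerSpec:
    """Parameters of a pseudo-atom dimer envelope.

    ``envelope='sphere-pair'`` gives two fat pseudo-atoms (one per monomer
    lobe) whose radius is `atom_radius` — sphere geometry with closed-form
    contact/clash offsets.  ``envelope='helix-bundle'`` gives two lobes of
    carbon-radius pseudo-atom rods hugging the duplex, suited to footprint
    work.  `standoff` is the gap between the DNA envelope surface and the
    pseudo-atom surface.
    """

    footprint_bp: int = 21
    envelope: str = "helix-bundle"
    atom_radius: float = 1.7
    standoff: float = 0.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.footprint_bp < 1:
            raise ValueError("footprint must be >= 1 bp")
        if self.standoff < 0:
            raise ValueError("standoff must be >= 0")
        if self.envelope not in ("sphere-pair", "helix-bundle"):
            raise ValueError(f"unknown envelope {self.envelope!r}")


def _pseudo_residue(name: str, seq_id: int, atoms) -> Residue:
    return Residue(name, seq_id, "", atoms)


def _sphere_pair_chains(spec: ToyDimerSpec, params: HelicalParameters,
                        center_bp: float) -> tuple[list[Chain], RadiiSet]:
    """Two single-atom lobes on opposite faces of the duplex."""
    z = center_bp * params.rise
    rc = _DNA_RADIUS + spec.atom_radius + spec.standoff
    radii = DEFAULT_RADII.with_entry("Q", spec.atom_radius)
    chains = []
    for cid, phi in (("P", 0.0), ("Q", math.pi)):
        pos = np.array([rc * math.cos(phi), rc * math.sin(phi), z])
        chains.append(Chain(cid, [
            _pseudo_residue("TOY", 1, [Atom("Q1", "Q", pos, is_hetero=True)])]))
    return chains, radii


def _bundle_chains(z_window: tuple[float, float], spec: ToyDimerSpec,
                   params: HelicalParameters) -> list[Chain]:
    """Two lobes of carbon pseudo-atom rods covering a z-extent (Å).

    Rods run parallel to the axis at several azimuths per lobe, with atoms
    every ~1.5 Å in z, close enough to the duplex surface to bury it.
    """
    z0, z1 = z_window
    rc = _DNA_RADIUS + 1.7 + spec.standoff - 1.0  # slightly embedded in the probe shell
    n_z = max(2, int(round((z1 - z0) / 1.5)) + 1)
    zs = np.linspace(z0, z1, n_z)
    chains = []
    azimuths = np.deg2rad([-60, -30, 0, 30, 60])
    for cid, phi0 in (("P", 0.0), ("Q", math.pi)):
        atoms = []
        k = 1
        for az in azimuths:
            for z in zs:
                phi = phi0 + az
                pos = np.array([rc * math.cos(phi), rc * math.sin(phi), z])
                atoms.append(Atom(f"C{k}", "C", pos, is_hetero=True))
                k += 1
        res = [_pseudo_residue("TOY", i + 1, [a]) for i, a in enumerate(atoms)]
        chains.append(Chain(cid, res))
    return chains


def make_toy_dimer_complex(spec: ToyDimerSpec, dna_seq,
                           params: HelicalParameters | None = None,
                           probe: float = 1.4, n_points: int = 240,
                           ) -> tuple[DockModel, RadiiSet]:
    """A pseudo-atom dimer bound to an ideal duplex, with a known footprint.

    For the helix-bundle envelope the construction is calibrated: the lobe
    extent is adjusted (±1 bp at a time) until the measured buried-surface
    footprint span equals ``spec.footprint_bp``, and the construction
    asserts the match.  Returns the model and the radii set to use with it
    (the sphere-pair envelope needs its custom pseudo-atom radius).
    """
    params = params or HelicalParameters()
    duplex = dna_seq if isinstance(dna_seq, DuplexSequence) else DuplexSequence(dna_seq)
    n_bp = len(duplex)
    if n_bp < spec.footprint_bp:
        raise ValueError(
            f"{n_bp} bp duplex cannot carry a {spec.footprint_bp} bp footprint")
    dna = build_bdna(duplex, params, chain_ids=("A", "B"))
    center = (n_bp - 1) / 2.0
    if spec.envelope == "sphere-pair":
        chains, radii = _sphere_pair_chains(spec, params, center)
        structure = Structure("toy-dimer", chains + [c.copy() for c in dna.chains])
        model = DockModel(structure=structure, protein_chains=("P", "Q"),
                          dna_chains=("A", "B"), label="toy-sphere-pair")
        return model, radii
    # helix-bundle: calibrate the lobe z-extent against the footprint measure.
    # The window is centered so that symmetric growth matches the parity of
    # the requested span, and the half-extent is bisected: the measured span
    # is integer-valued and monotone non-decreasing in the extent.
    radii = DEFAULT_RADII
    target = spec.footprint_bp
    center_bp = n_bp // 2 if target % 2 == 1 else n_bp // 2 - 0.5
    center_z = center_bp * params.rise

    def measure(half_bp: float):
        zw = (center_z - half_bp * params.rise, center_z + half_bp * params.rise)
        chains = _bundle_chains(zw, spec, params)
        structure = Structure("toy-dimer", chains + [c.copy() for c in dna.chains])
        model = DockModel(structure=structure, protein_chains=("P", "Q"),
                          dna_chains=("A", "B"), label="toy-helix-bundle")
        result = dna_footprint(structure, ("A", "B"), ("P", "Q"),
                               probe=probe, radii=radii, n_points=n_points)
        return model, result.span_bp

    lo_h = max(0.1, target / 2.0 - 2.0)
    hi_h = target / 2.0 + 1.5
    model, span = measure(hi_h)
    if span < target:
        raise ValueError(
            f"could not calibrate a {target} bp footprint on a {n_bp} bp duplex")
    if span == target:
        return model, radii
    for _ in range(20):
        mid = (lo_h + hi_h) / 2.0
        model, span = measure(mid)
        if span == target:
            return model, radii
        if span > target:
            hi_h = mid
        else:
            lo_h = mid
        if hi_h - lo_h < 0.01:
            break
    raise ValueError(
        f"could not calibrate a {target} bp footprint on a {n_bp} bp duplex "
        f"(reached span {span})")


# ---------------------------------------------------------------------------
# pseudo-protein template

# default segment layout of the pseudo-monomer: element name → residue count
DEFAULT_MOTIF_LAYOUT = {
    "H1": 8, "H2": 6, "H3": 7, "H4": 9, "S1": 4, "S2": 4, "H5": 8,
}

_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = 100.0   # degrees per residue
_STRAND_RISE = 3.3


def _backbone_residue(seq_id: int, ca: np.ndarray, direction: np.ndarray,
                      side: np.ndarray) -> Residue:
    """A glycine-like residue with N, CA, C, O at idealized local offsets."""
    d = direction / np.linalg.norm(direction)
    s = side / np.linalg.norm(side)
    atoms = [
        Atom("N", "N", ca - 1.46 * d + 0.3 * s),
        Atom("CA", "C", ca),
        Atom("C", "C", ca + 1.52 * d + 0.3 * s),
        Atom("O", "O", ca + 1.52 * d + 1.53 * s),
    ]
    return Residue("GLY", seq_id, "", atoms)


def _helix_segment(start: np.ndarray, axis: np.ndarray, n_res: int,
                   seq_start: int, phase: float = 0.0) -> list[Residue]:
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the helix axis
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    out = []
    for i in range(n_res):
        ang = phase + math.radians(_HELIX_TWIST) * i
        ca = (start + _HELIX_RISE * i * axis
              + _HELIX_RADIUS * (math.cos(ang) * u + math.sin(ang) * v))
        nxt = (start + _HELIX_RISE * (i + 1) * axis
               + _HELIX_RADIUS * (math.cos(ang + math.radians(_HELIX_TWIST)) * u
                                  + math.sin(ang + math.radians(_HELIX_TWIST)) * v))
        out.append(_backbone_residue(seq_start + i, ca, nxt - ca, v))
    return out


def _strand_segment(start: np.ndarray, direction: np.ndarray, n_res: int,
                    seq_start: int) -> list[Residue]:
    d = direction / np.linalg.norm(direction)
    side = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(side) < 1e-6:
        side = np.cross(d, [1.0, 0.0, 0.0])
    side /= np.linalg.norm(side)
    return [
        _backbone_residue(seq_start + i, start + _STRAND_RISE * i * d, d, side)
        for i in range(n_res)
    ]


def _pseudo_monomer(layout: dict[str, int], chain_id: str
                    ) -> tuple[Chain, dict[str, tuple[int, int]]]:
    """A pseudo-monomer hovering over the major groove near the origin.

    The recognition helix H4 runs roughly along the groove at the duplex
    surface; the wing strands S1/S2 trail antiparallel behind it; the other
    helices stack further out.  Returns the chain and the seq-id span of
    every segment.
    """
    segments: list[tuple[str, list[Residue]]] = []
    spans: dict[str, tuple[int, int]] = {}
    seq = 1
    # H4 recognition helix: axis tangential to the duplex, center above the
    # major groove at x ~ +11 Å
    order = [k for k in ("H1", "H2", "H3", "H4", "S1", "S2", "H5") if k in layout]
    placements = {
        "H4": lambda n: _helix_segment(
            np.array([11.0, -0.5 * _HELIX_RISE * n, 2.0]), np.array([0.1, 1.0, 0.0]),
            n, seq),
        "H3": lambda n: _helix_segment(
            np.array([16.0, -6.0, 5.0]), np.array([1.0, 0.3, 0.2]), n, seq),
        "H2": lambda n: _helix_segment(
            np.array([20.0, -12.0, 8.0]), np.array([0.2, 1.0, 0.0]), n, seq),
        "H1": lambda n: _helix_segment(
            np.array([24.0, -4.0, 12.0]), np.array([0.0, 1.0, 0.3]), n, seq),
        "S1": lambda n: _strand_segment(
            np.array([14.0, 8.0, 6.0]), np.array([0.3, 1.0, 0.1]), n, seq),
        "S2": lambda n: _strand_segment(
            np.array([18.0, 8.0 + _STRAND_RISE * (layout.get("S1", 4) - 1), 6.0]),
            np.array([-0.3, -1.0, 0.1]), n, seq),
        "H5": lambda n: _helix_segment(
            np.array([26.0, 4.0, 16.0]), np.array([0.0, 1.0, 1.0]), n, seq),
    }
    residues: list[Residue] = []
    for name in order:
        n_res = layout[name]
        placed = placements[name](n_res)
        spans[name] = (seq, seq + n_res - 1)
        residues.extend(placed)
        seq += n_res
        segments.append((name, placed))
    return Chain(chain_id, residues), spans


def _dyad_flip(chain: Chain, new_id: str, dyad_z: float) -> Chain:
    """Copy a chain through the duplex dyad: 180° about x, shifted along z."""
    out = chain.copy()
    out.id = new_id
    for res in out.residues:
        for atom in res.atoms:
            x, y, z = atom.coords
            atom.coords = np.array([x, -y, 2 * dyad_z - z])
    return out


def make_toy_monomer(layout=None, chain_id: str = "P"
                     ) -> tuple[Structure, MotifSpec]:
    """The pseudo-monomer in its bound pose, with its MotifSpec."""
    layout = dict(layout or DEFAULT_MOTIF_LAYOUT)
    chain, spans = _pseudo_monomer(layout, chain_id)
    motif = MotifSpec(
        segments={name: ((chain_id, lo, hi),) for name, (lo, hi) in spans.items()},
        recognition_helix="H4",
    )
    return Structure("toy-monomer", [chain]), motif


def make_toy_dimer_protein(layout=None, chain_ids=("P", "Q"), n_bp: int = 25,
                           params: HelicalParameters | None = None
                           ) -> tuple[Structure, dict[str, MotifSpec]]:
    """A homodimeric pseudo-protein (two monomers related by the duplex dyad).

    Returns the dimer and the MotifSpecs of both monomers keyed 'A'/'B'.
    """
    params = params or HelicalParameters()
    layout = dict(layout or DEFAULT_MOTIF_LAYOUT)
    monomer, motif_a = make_toy_monomer(layout, chain_ids[0])
    chain_a = monomer.chains[0]
    dyad_z = (n_bp - 1) / 2.0 * params.rise
    chain_b = _dyad_flip(chain_a, chain_ids[1], dyad_z / 2.0)
    dimer = Structure("toy-dimer-protein", [chain_a.copy(), chain_b])
    spans = {name: ranges[0][1:] for name, ranges in motif_a.segments.items()}
    motif_b = MotifSpec(
        segments={name: ((chain_ids[1], lo, hi),) for name, (lo, hi) in spans.items()},
        recognition_helix="H4",
    )
    return dimer, {"A": motif_a, "B": motif_b}


def make_template_complex(dna_seq: str | None = None, motif_layout=None,
                          params: HelicalParameters | None = None,
                          resolution: float = 2.0,
                          wing_antiparallel: bool = True,
                          name: str = "toy-template") -> TemplateComplex:
    """A synthetic homodimer-on-duplex template that passes all criteria.

    The default DNA is a symmetric 25 bp AT-rich duplex.  Pass a
    `motif_layout` without S2 (single wing strand) or
    ``wing_antiparallel=False`` to produce templates that fail the wing
    criterion on purpose.
    """
    params = params or HelicalParameters()
    if dna_seq is None:
        half = "ATATTAATTATA"                       # 12 bp
        dna_seq = half + "T" + reverse_complement(half)   # 25 bp, dyad-symmetric
    layout = dict(motif_layout or DEFAULT_MOTIF_LAYOUT)
    dna = build_bdna(dna_seq, params, chain_ids=("A", "B"))
    n_bp = len(dna.chains[0].residues)
    dimer, motifs = make_toy_dimer_protein(layout, ("P", "Q"), n_bp, params)
    chains = [c.copy() for c in dimer.chains] + [c.copy() for c in dna.chains]
    structure = Structure(name, chains)
    motif = MotifSpec(segments=motifs["A"].segments,
                      recognition_helix="H4",
                      wing_antiparallel=wing_antiparallel)
    return TemplateComplex(structure=structure, motif=motif,
                           dna_chains=("A", "B"), resolution=resolution,
                           name=name)


# ---------------------------------------------------------------------------
# promoter fixture

def make_promoter_sequence(length: int = 300, planted=(), at_run=None,
                           genes=None, seed: int = 0, gc: float = 0.5
                           ) -> tuple[PromoterAnnotation, dict]:
    """A seeded random promoter region with exactly planted elements.

    `genes` maps gene names to ``(strand, tss_index)``; default is a
    divergent pair ('right' on the top strand, 'left' on the bottom).
    `planted` entries are ``(motif, gene, promoter_position)`` — the motif
    string is written on that gene's strand with its 5'-most base at the
    given promoter coordinate.  `at_run` is ``(top_strand_index, run_len)``
    for an AT-only tract.  Overlapping plants raise.  Returns the
    annotation and a ground-truth dict for scanner tests.
    """
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = {"right": ("+", int(length * 0.65)),
                 "left": ("-", int(length * 0.35))}
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    seq = list(rng.choice(list("ACGT"), size=length,
                          p=[p_at, p_gc, p_gc, p_at]))
    # keep the random background free of accidental AT runs where one is planted
    gene_objs = {
        nm: GenePromoter(nm, strand, tss) for nm, (strand, tss) in genes.items()
    }
    occupied: dict[int, str] = {}
    truth: dict = {"planted": [], "at_run": None, "genes": dict(genes)}

    def write(idx: int, base: str, label: str) -> None:
        if idx < 0 or idx >= length:
            raise ValueError(f"plant {label} falls outside the sequence at {idx}")
        prev = occupied.get(idx)
        if prev is not None and seq[idx] != base:
            raise ValueError(f"plants {prev} and {label} overlap at index {idx}")
        seq[idx] = base
        occupied[idx] = label

    for motif, gene_name, pos in planted:
        g = gene_objs[gene_name]
        motif = motif.upper()
        tss_off = g.tss_index if g.strand == "+" else length - 1 - g.tss_index
        start = promoter_to_index(pos, tss_off)
        top = motif if g.strand == "+" else reverse_complement(motif)
        # gene-strand index → top-strand index
        if g.strand == "+":
            top_start = start
        else:
            top_start = length - (start + len(motif))
        for k, base in enumerate(top):
            write(top_start + k, base, f"{gene_name}:{motif}@{pos}")
        truth["planted"].append({"motif": motif, "gene": gene_name,
                                 "position": pos, "top_start": top_start})
    if at_run is not None:
        start, run_len = at_run
        pattern = rng.choice(list("AT"), size=run_len)
        for k in range(run_len):
            write(start + k, str(pattern[k]), "at-run")
        # flanks must break the run so it is exactly maximal
        for idx, flank in ((start - 1, "G"), (start + run_len, "C")):
            if 0 <= idx < length and idx not in occupied:
                seq[idx] = flank
        truth["at_run"] = {"start": start, "length": run_len}
    annotation = PromoterAnnotation("".join(seq), gene_objs)
    return annotation, truth
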