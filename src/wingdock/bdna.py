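"""Ideal B-DNA construction, per-base-pair screw transforms and threading.

The duplex is built on the standard base-pair reference frame: each base's
heavy atoms are tabulated in a frame whose origin lies on the helix axis of
an ideal regular duplex, with the pair's long axis along x and the helix
axis along z.  Successive base pairs are related by the screw transform of
the helix — a rotation by the twist about the axis plus a translation by the
rise along it.  Complementary-strand bases are the 180-degree rotation of
their partner's frame about x (antiparallel strands).

Full-atom nucleotides (sugar-phosphate backbone included) are obtained by
rigidly placing idealized residue geometry from the chemical component
dictionary onto each base frame, so every nucleotide has identical local
geometry and the backbone traces a regular helix.  Sequence-dependent fine
structure (roll, propeller, slide...) is deliberately absent: the builder
produces canonical, straight-axis B-DNA.

``thread_sequence`` mutates the bases of an existing duplex onto a new
sequence while keeping every sugar-phosphate backbone atom bit-identical,
mirroring how a template complex's DNA is rewritten to a target site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .geometry import RigidTransform, superpose
from .structure import Atom, Chain, Residue, Structure

__all__ = [
    "HelicalParameters", "DuplexSequence", "build_bdna", "helical_step",
    "thread_sequence", "at_content", "reverse_complement", "base_pair_centers",
    "helix_axis", "duplex_sequence_of", "read_fasta_sequence",
    "BACKBONE_ATOMS",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Sugar-phosphate atom names of a DNA nucleotide (5'-terminal residues lack
#: the phosphate group P/OP1/OP2).
BACKBONE_ATOMS = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
                  "C2'", "C1'")

# Heavy-atom base coordinates (plus the glycosidic C1') in the standard
# base-pair reference frame: origin on the ideal helix axis, base plane in
# z = 0, pair long axis along x.  Idealized planar geometry.
_STD_BASE: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000), "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000), "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000), "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000), "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000), "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000), "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000), "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000), "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000), "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000), "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001), "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000), "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000), "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000), "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001), "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.000), "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000), "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000), "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000), "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001), "C6": (-0.024, 5.057, 0.000),
    },
}

# Ring atoms used (with C1') to fit a base onto its reference frame.
_FRAME_FIT_ATOMS = {
    "A": ("C1'", "N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("C1'", "N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("C1'", "N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("C1'", "N1", "C2", "N3", "C4", "C5", "C6"),
}

# Ring-only variant (no C1') used when rebuilding bases on a fixed backbone:
# fitting on atoms that are themselves replaced makes re-threading an exact
# fixed point (idempotent), which a mixed fit with the preserved C1' is not.
_RING_FIT_ATOMS = {k: v[1:] for k, v in _FRAME_FIT_ATOMS.items()}

# 180-degree rotation about x: maps a base frame onto its Watson-Crick
# partner's frame on the antiparallel strand.
_FLIP = np.diag([1.0, -1.0, -1.0])


def _clean(seq: str) -> str:
    s = str(seq).strip().upper().replace("U", "T")
    if not s:
        raise ValueError("empty sequence")
    bad = sorted(set(s) - set("ACGT"))
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    return s


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(_clean(seq)))


def at_content(seq: str) -> float:
    """(A+T) fraction of a sequence, in [0, 1].

    For a Watson-Crick duplex this equals the AT fraction of either strand.
    """
    s = _clean(seq)
    return (s.count("A") + s.count("T")) / len(s)


@dataclass(frozen=True)
class DuplexSequence:
    """A duplex given by its top strand 5'→3'; bottom strand is derived."""

    top: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "top", _clean(self.top))

    @property
    def bottom(self) -> str:
        return reverse_complement(self.top)

    def __len__(self) -> int:
        return len(self.top)

    @classmethod
    def from_fasta(cls, path) -> "DuplexSequence":
        return cls(read_fasta_sequence(path))


def read_fasta_sequence(path) -> str:
    """First record of a FASTA file, as an uppercase string."""
    from Bio import SeqIO

    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise ValueError(f"no FASTA records in {path}") from None
    return str(record.seq).upper()


@dataclass(frozen=True)
class HelicalParameters:
    """Regular-helix geometry: rise (Å/bp), twist (deg/bp), axis and anchor."""

    rise: float = 3.38
    twist: float = 36.0
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    anchor: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if not self.rise > 0:
            raise ValueError(f"rise must be positive, got {self.rise}")
        if not 0 < self.twist <= 45:
            raise ValueError(f"twist must be in (0, 45] degrees, got {self.twist}")
        u = np.asarray(self.axis, dtype=float).reshape(3)
        norm = np.linalg.norm(u)
        if norm == 0:
            raise ValueError("axis must be a non-zero vector")
        object.__setattr__(self, "axis", u / norm)
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float).reshape(3))

    @property
    def bp_per_turn(self) -> float:
        return 360.0 / self.twist


def helical_step(params: HelicalParameters, n_bp: float) -> RigidTransform:
    """Screw transform advancing `n_bp` base-pair steps along the helix.

    Rotation by ``n_bp * twist`` about the axis (through the anchor point)
    plus translation ``n_bp * rise`` along it.  These transforms form a
    one-parameter group: steps add, step(0) is the identity.
    """
    from scipy.spatial.transform import Rotation

    u, a = params.axis, params.anchor
    angle = np.deg2rad(n_bp * params.twist)
    R = Rotation.from_rotvec(angle * u).as_matrix()
    t = a - R @ a + n_bp * params.rise * u
    return RigidTransform(R, t)


@lru_cache(maxsize=8)
def _ideal_nucleotide(letter: str):
    """Idealized full-atom nucleotide (names, elements, coords) from the CCD."""
    from biotite.structure.info import residue as ccd_residue

    arr = ccd_residue("D" + letter)
    keep = (arr.element != "H") & (arr.atom_name != "OP3")
    arr = arr[keep]
    return (tuple(str(n) for n in arr.atom_name),
            tuple(str(e) for e in arr.element),
            np.asarray(arr.coord, dtype=float).copy())


def _std_coords(letter: str, names) -> np.ndarray:
    return np.array([_STD_BASE[letter][n] for n in names], dtype=float)


def _place_ideal_nucleotide(letter: str, frame: RigidTransform,
                            seq_id: int, with_phosphate: bool) -> Residue:
    """Rigidly place the idealized nucleotide so its base sits on `frame`."""
    names, elements, coords = _ideal_nucleotide(letter)
    fit_names = _FRAME_FIT_ATOMS[letter]
    idx = [names.index(n) for n in fit_names]
    target = frame.apply(_std_coords(letter, fit_names))
    t, _ = superpose(coords[idx], target)
    placed = t.apply(coords)
    atoms = []
    for name, element, xyz in zip(names, elements, placed):
        if not with_phosphate and name in ("P", "OP1", "OP2"):
            continue
        atoms.append(Atom(name, element, xyz))
    return Residue("D" + letter, seq_id, "", atoms)


def build_bdna(seq: DuplexSequence | str,
               params: HelicalParameters | None = None,
               chain_ids: tuple[str, str] = ("A", "B")) -> Structure:
    """Build an ideal straight-axis B-DNA duplex from a sequence.

    Returns a two-chain structure (top strand then bottom strand, both
    ordered 5'→3').  Base-pair frame origins lie exactly on the helix axis,
    spaced by the rise and rotated by the twist; 5'-terminal nucleotides
    lack the phosphate group.
    """
    duplex = seq if isinstance(seq, DuplexSequence) else DuplexSequence(seq)
    params = params or HelicalParameters()
    n = len(duplex)
    top_res: list[Residue] = []
    bottom_res: list[Residue] = []
    flip = RigidTransform(_FLIP)
    for i, letter in enumerate(duplex.top):
        step = helical_step(params, i)
        top_res.append(_place_ideal_nucleotide(letter, step, i + 1, with_phosphate=i > 0))
        comp = _COMPLEMENT[letter]
        # bottom-strand 5' end sits at the last base pair
        bottom_res.append(_place_ideal_nucleotide(
            comp, step.compose(flip), n - i, with_phosphate=i < n - 1))
    bottom_res.reverse()  # store bottom strand 5'→3'
    s = Structure(
        name="bdna",
        chains=[Chain(chain_ids[0], top_res), Chain(chain_ids[1], bottom_res)],
        provenance={"builder": "wingdock.bdna", "rise": params.rise,
                    "twist": params.twist, "transforms": []},
    )
    return s


def _dna_chain_pair(structure: Structure, chain_ids=None) -> tuple[Chain, Chain]:
    if chain_ids is None:
        dna = [c for c in structure.chains if c.kind == "dna"]
        if len(dna) != 2:
            raise ValueError(
                f"expected exactly 2 DNA chains, found {[c.id for c in dna]}; "
                "pass chain_ids explicitly")
        return dna[0], dna[1]
    return structure.chain(chain_ids[0]), structure.chain(chain_ids[1])


def _letter(residue: Residue) -> str:
    name = residue.name.strip().upper()
    if name.startswith("D") and len(name) == 2:
        name = name[1]
    if name not in "ACGT":
        raise ValueError(f"residue {residue.name} {residue.seq_id} is not a standard "
                         "DNA nucleotide")
    return name


def duplex_sequence_of(structure: Structure, chain_ids=None) -> DuplexSequence:
    """Top-strand sequence of a duplex, read off residue names."""
    top, _ = _dna_chain_pair(structure, chain_ids)
    return DuplexSequence("".join(_letter(r) for r in top.residues))


def base_frame_transform(residue: Residue) -> RigidTransform:
    """Transform mapping the standard base frame onto this nucleotide's base.

    Least-squares fit of the standard base-ring coordinates onto the
    observed ring atoms; the image of the frame origin is the base's
    reference point and the image of +z its base-normal direction.  The
    glycosidic C1' must be present (it anchors the rebuilt base to the
    backbone) but is not part of the fit.
    """
    letter = _letter(residue)
    if not residue.has_atom("C1'"):
        raise ValueError(f"residue {residue.name} {residue.seq_id} lacks C1'")
    names = [n for n in _RING_FIT_ATOMS[letter] if residue.has_atom(n)]
    if len(names) < 4:
        raise ValueError(f"residue {residue.name} {residue.seq_id} lacks base ring atoms")
    observed = np.array([residue.atom(n).coords for n in names])
    t, _ = superpose(_std_coords(letter, names), observed)
    return t


def base_pair_centers(structure: Structure, chain_ids=None) -> np.ndarray:
    """(N, 3) base-pair reference-frame origins, one per pair.

    Pair i couples top-strand residue i with bottom-strand residue
    ``L - 1 - i`` (both strands stored 5'→3').  Each origin is the image of
    the standard-frame origin under a joint fit over both paired bases; for
    duplexes from :func:`build_bdna` the origins lie exactly on the axis.
    """
    top, bottom = _dna_chain_pair(structure, chain_ids)
    if len(top.residues) != len(bottom.residues):
        raise ValueError("strands have different lengths; not a blunt duplex")
    n = len(top.residues)
    centers = np.empty((n, 3))
    for i in range(n):
        r1, r2 = top.residues[i], bottom.residues[n - 1 - i]
        l1, l2 = _letter(r1), _letter(r2)
        ref, obs = [], []
        for res, letter, flip in ((r1, l1, False), (r2, l2, True)):
            names = [nm for nm in _FRAME_FIT_ATOMS[letter] if res.has_atom(nm)]
            coords = _std_coords(letter, names)
            if flip:
                coords = coords @ _FLIP.T
            ref.append(coords)
            obs.append(np.array([res.atom(nm).coords for nm in names]))
        t, _ = superpose(np.vstack(ref), np.vstack(obs))
        centers[i] = t.apply(np.zeros(3))
    return centers


def helix_axis(structure: Structure, chain_ids=None,
               rise: float = 3.38, twist: float = 36.0) -> HelicalParameters:
    """Estimate the helix axis as the best-fit line through base-pair centers.

    Returns :class:`HelicalParameters` carrying the fitted axis (oriented
    5'→3' along the top strand) and the first base-pair center as anchor,
    with the given rise/twist.
    """
    centers = base_pair_centers(structure, chain_ids)
    if len(centers) < 2:
        raise ValueError("need at least 2 base pairs to define an axis")
    mean = centers.mean(axis=0)
    _, _, vt = np.linalg.svd(centers - mean)
    u = vt[0]
    if np.dot(centers[-1] - centers[0], u) < 0:
        u = -u
    return HelicalParameters(rise=rise, twist=twist, axis=u, anchor=centers[0])


def thread_sequence(complex: Structure, dna_chain_ids, new_seq) -> Structure:
    """Rewrite the duplex bases to `new_seq`, keeping the backbone fixed.

    Every sugar-phosphate atom (P, OP1, OP2, O5', C5', C4', O4', C3', O3',
    C2', C1') keeps its exact template coordinates; base atoms are rebuilt
    from idealized base geometry placed on the template nucleotide's
    glycosidic frame.  The bottom strand receives the complement.  Threading
    the same sequence twice is idempotent.
    """
    duplex = new_seq if isinstance(new_seq, DuplexSequence) else DuplexSequence(new_seq)
    out = complex.copy()
    top, bottom = _dna_chain_pair(out, dna_chain_ids)
    n = len(top.residues)
    if len(bottom.residues) != n:
        raise ValueError("template strands have different lengths")
    if len(duplex) != n:
        raise ValueError(
            f"sequence length {len(duplex)} does not match template duplex length {n}")
    for i in range(n):
        _thread_residue(top.residues[i], duplex.top[i])
        _thread_residue(bottom.residues[n - 1 - i], _COMPLEMENT[duplex.top[i]])
    return out


def _thread_residue(residue: Residue, new_letter: str) -> None:
    frame = base_frame_transform(residue)  # raises if C1'/ring missing
    backbone = [a for a in residue.atoms if a.name in BACKBONE_ATOMS]
    base_names = [n for n in _STD_BASE[new_letter] if n != "C1'"]
    placed = frame.apply(_std_coords(new_letter, base_names))
    new_atoms = backbone + [
        Atom(name, name[0], xyz) for name, xyz in zip(base_names, placed)
    ]
    residue.name = "D" + new_letter
    residue.atoms = new_atoms
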