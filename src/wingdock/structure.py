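"""Hierarchical structure model (chains → residues → atoms) and PDB I/O.

The in-memory model is deliberately small: enough to carry protein/DNA
complexes through superposition, rigid placement and surface calculations.
Parsing and serialisation of the PDB format are delegated to gemmi; this
module only converts between gemmi's hierarchy and ours, applying two
normalisations on input:

* only the first model of multi-model files is kept (templates are X-ray
  structures);
* for alternate locations, the highest-occupancy conformer is kept.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .geometry import RigidTransform

__all__ = [
    "Atom", "Residue", "Chain", "Structure",
    "read_structure", "write_structure", "apply_transform", "PDBParseError",
]

# Residue names recognised as nucleotides (PDB v3 and legacy one-letter).
_DNA_NAMES = {"DA", "DC", "DG", "DT", "DI", "DU", "A", "C", "G", "T", "U", "I"}
_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


class PDBParseError(ValueError):
    """Malformed PDB input; carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")
        self.element = self.element.upper()

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(),
                    self.occupancy, self.bfactor, self.is_hetero)


@dataclass
class Residue:
    name: str
    seq_id: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"residue {self.name} {self.seq_id}: duplicate atom names {dup}")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name} {self.seq_id} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def is_nucleotide(self) -> bool:
        return self.name.strip() in _DNA_NAMES

    @property
    def is_amino_acid(self) -> bool:
        return self.name.strip() in _AA3

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq_id, self.icode,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def kind(self) -> str:
        """'protein', 'dna' or 'other', from a majority vote over residues."""
        n_aa = sum(r.is_amino_acid for r in self.residues)
        n_nt = sum(r.is_nucleotide for r in self.residues)
        if n_aa == 0 and n_nt == 0:
            return "other"
        return "protein" if n_aa >= n_nt else "dna"

    def sequence(self) -> tuple[str, ...]:
        """Residue names in order (polymer residues only)."""
        return tuple(r.name for r in self.residues if r.is_amino_acid or r.is_nucleotide)

    def atoms(self):
        for r in self.residues:
            yield from r.atoms

    def residue(self, seq_id: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.seq_id == seq_id and r.icode == icode:
                return r
        raise KeyError(f"chain {self.id}: no residue {seq_id}{icode}")

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    name: str = ""
    chains: list[Chain] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"structure {self.name!r}: no chain {chain_id!r}")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.id == chain_id for c in self.chains)

    def atoms(self):
        for c in self.chains:
            yield from c.atoms()

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array over all atoms in hierarchy order."""
        arr = [a.coords for a in self.atoms()]
        return np.array(arr, dtype=float).reshape(-1, 3)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        atoms = list(self.atoms())
        if coords.shape != (len(atoms), 3):
            raise ValueError(f"expected {(len(atoms), 3)} coords, got {coords.shape}")
        for a, xyz in zip(atoms, coords):
            a.coords = xyz.copy()

    def subset(self, chain_ids) -> "Structure":
        """New structure holding deep copies of the named chains, in order."""
        return Structure(self.name, [self.chain(cid).copy() for cid in chain_ids],
                         dict(self.provenance))

    def copy(self) -> "Structure":
        return Structure(self.name, [c.copy() for c in self.chains], dict(self.provenance))


# --------------------------------------------------------------------------
# PDB I/O (gemmi-backed)

def _validate_coordinate_fields(text: str) -> None:
    # gemmi is forgiving about malformed numeric fields; reject them up front
    # so errors carry a line number.
    for i, line in enumerate(text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBParseError(
                        f"non-numeric {what}-coordinate field {fieldtxt!r}", i) from None


def _best_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: keep the highest-occupancy conformer."""
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for at in residue:
        prev = by_name.get(at.name)
        if prev is None:
            by_name[at.name] = at
            order.append(at.name)
        elif at.occ > prev.occ:
            by_name[at.name] = at
    return [by_name[n] for n in order]


def read_structure(source: str | os.PathLike) -> Structure:
    """Read a PDB-format file or string of ATOM/HETATM records.

    `source` may be a path or raw PDB text.  Only the first model is read;
    alternate locations resolve to the highest-occupancy conformer; metal and
    water heteroatoms are retained and flagged ``is_hetero``.
    """
    if isinstance(source, os.PathLike) or (
            isinstance(source, str) and "\n" not in source and os.path.exists(source)):
        path = os.fspath(source)
        with open(path) as fh:
            text = fh.read()
        name = os.path.splitext(os.path.basename(path))[0]
        origin = path
    else:
        text = str(source)
        name = ""
        origin = "<string>"
    if not text.strip():
        raise PDBParseError("empty PDB input")
    _validate_coordinate_fields(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("no coordinate records found")
    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            atoms = [
                Atom(
                    name=gat.name,
                    element=gat.element.name or gat.name[:1],
                    coords=np.array([gat.pos.x, gat.pos.y, gat.pos.z]),
                    occupancy=gat.occ,
                    bfactor=gat.b_iso,
                    is_hetero=(gres.het_flag == "H"),
                )
                for gat in _best_altloc(gres)
            ]
            residues.append(Residue(gres.name, gres.seqid.num,
                                    gres.seqid.icode.strip(), atoms))
        chains.append(Chain(gchain.name, residues))
    return Structure(name=name, chains=chains,
                     provenance={"source": origin, "transforms": []})


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.name or "wingdock"
    model = gemmi.Model("1")
    for chain in s.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            gres.het_flag = "H" if all(a.is_hetero for a in res.atoms) and res.atoms else "A"
            for atom in res.atoms:
                if len(atom.name) > 4:
                    raise ValueError(
                        f"atom name {atom.name!r} exceeds the 4-character PDB field")
                gat = gemmi.Atom()
                gat.name = atom.name
                gat.element = gemmi.Element(atom.element)
                gat.pos = gemmi.Position(*atom.coords)
                gat.occ = atom.occupancy
                gat.b_iso = atom.bfactor
                gres.add_atom(gat)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, dest: str | os.PathLike | None = None) -> str:
    """Serialise to PDB format; returns the text, optionally writing `dest`.

    Output is deterministic for identical input (chains TER-terminated,
    atoms in hierarchy order).
    """
    if not s.chains or s.n_atoms() == 0:
        raise ValueError("refusing to write an empty structure")
    st = _to_gemmi(s)
    opts = gemmi.PdbWriteOptions()
    opts.minimal_file = True
    opts.cryst1_record = False
    opts.end_record = True
    text = st.make_pdb_string(opts)
    if dest is not None:
        with open(dest, "w") as fh:
            fh.write(text)
    return text


def apply_transform(s: Structure, t: RigidTransform) -> Structure:
    """Return a rigidly transformed deep copy; the input is untouched.

    Rigidity: all pairwise interatomic distances are preserved to numerical
    precision (the transform is proper orthonormal by construction).
    """
    out = s.copy()
    out.set_coords(t.apply(out.coords()))
    out.provenance.setdefault("transforms", []).append(
        {"rotation": t.rotation.tolist(), "translation": t.translation.tolist()})
    return out
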