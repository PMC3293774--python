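"""Multimer placement along DNA: spacing scans, assembly, and the switch model.

A bound dimer is treated as a rigid building block.  Copies are slid along
the duplex in 1-bp increments using the helix's screw transform, so a copy
at offset ``s`` sits ``s * rise`` further along the axis and is rotated by
``s * twist`` around it — after a full turn the copy is a pure translation.
Each spacing is classified:

* ``clash``     — at least one heavy-atom pair of the two dimers overlaps
                  by more than the tolerance (sterically impossible);
* ``contact``   — no clash, and the dimer-dimer contact surface reaches the
                  minimum (a candidate cooperative tetramer);
* ``separated`` — no clash and no appreciable contact surface.

Hexamers/polymers are assembled from explicit offset lists (e.g. 0-3-6 or
0-6-12), and the protected promoter interval of a multimer follows the
exact arithmetic ``span = dimer_footprint + (max_offset - min_offset)``.
The switch report intersects a protected interval with each divergent
gene's −10/−35 boxes to say whether sigma-factor recruitment is blocked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import bdna
from .bdna import HelicalParameters, helical_step
from .promoter import GenePromoter
from .structure import Structure, apply_transform
from .surface import DEFAULT_RADII, RadiiSet, clash_score, sasa
from .templates import DockModel

__all__ = [
    "ScanThresholds", "OffsetRecord", "SpacingScanResult", "MultimerModel",
    "SwitchReport", "place_dimer_at_offset", "scan_spacings", "build_multimer",
    "multimer_footprint_span", "switch_report",
]

_CHAIN_POOL = "CDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


@dataclass(frozen=True)
class ScanThresholds:
    """Classification thresholds: clash overlap tolerance and minimum CS."""

    overlap_tol: float = 0.5   # Å of allowed vdW interpenetration
    cs_min: float = 1.0        # Å² of dimer-dimer contact surface


@dataclass(frozen=True)
class OffsetRecord:
    offset_bp: int
    cs_dd: float               # dimer-dimer contact surface, Å²
    n_clash: int
    worst_overlap: float       # Å
    dna_overlapped_surface: float | None   # Å² DNA area buried by both copies
    label: str                 # 'clash' | 'contact' | 'separated'


@dataclass(frozen=True)
class SpacingScanResult:
    records: tuple[OffsetRecord, ...]
    thresholds: ScanThresholds

    def record(self, offset_bp: int) -> OffsetRecord:
        for r in self.records:
            if r.offset_bp == offset_bp:
                return r
        raise KeyError(f"offset {offset_bp} not scanned")

    def offsets_with_label(self, label: str) -> tuple[int, ...]:
        return tuple(r.offset_bp for r in self.records if r.label == label)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([
            {"offset_bp": r.offset_bp, "cs_dd": r.cs_dd, "n_clash": r.n_clash,
             "worst_overlap": r.worst_overlap,
             "dna_overlapped_surface": r.dna_overlapped_surface,
             "class": r.label}
            for r in self.records
        ])


@dataclass
class MultimerModel:
    structure: Structure
    offsets: tuple[int, ...]
    copy_chains: tuple[tuple[str, ...], ...]   # chain ids per dimer copy
    dna_chains: tuple[str, str]
    adjacent_cs: tuple[float, ...] = ()
    dna_overlapped_surface: float | None = None


def _helical_params_for(model: DockModel,
                        params: HelicalParameters | None) -> HelicalParameters:
    """Helix geometry for sliding copies.

    When `params` is given it is used verbatim (the caller controls axis and
    anchor, e.g. a curved-axis fit).  Otherwise the axis is the best-fit
    line through the duplex's base-pair centers with canonical rise/twist.
    """
    if params is not None:
        return params
    dna = model.structure.subset(model.dna_chains)
    return bdna.helix_axis(dna, model.dna_chains)


def _duplex_length(model: DockModel) -> int:
    return len(model.structure.chain(model.dna_chains[0]).residues)


def place_dimer_at_offset(ref_complex: DockModel, offset_bp: int,
                          params: HelicalParameters | None = None) -> Structure:
    """A copy of the bound dimer advanced `offset_bp` steps along the helix.

    The DNA is not moved; only the transformed protein copy is returned.
    Offsets compose: stepping by a then b equals stepping by a + b.
    """
    if offset_bp < 0:
        raise ValueError(f"offset must be non-negative, got {offset_bp}")
    n_bp = _duplex_length(ref_complex)
    if offset_bp >= n_bp:
        raise ValueError(
            f"offset {offset_bp} bp exceeds the {n_bp} bp duplex")
    hp = _helical_params_for(ref_complex, params)
    step = helical_step(hp, offset_bp)
    dimer = ref_complex.structure.subset(ref_complex.protein_chains)
    return apply_transform(dimer, step)


def scan_spacings(ref_complex: DockModel, max_offset: int,
                  thresholds: ScanThresholds | None = None,
                  params: HelicalParameters | None = None,
                  probe: float = 1.4, radii: RadiiSet = DEFAULT_RADII,
                  n_points: int = 240,
                  include_dna_buried: bool = True) -> SpacingScanResult:
    """Slide a second dimer copy 1 bp at a time and classify every spacing.

    For each offset ``s`` in ``1..max_offset``: clash pairs and worst
    overlap between the fixed and the moved copy, the dimer-dimer contact
    surface CS_dd, and (optionally) the total DNA area buried by the two
    copies together.  The isolated-dimer SASA is computed once and reused —
    a rigid copy has the same isolated area.
    """
    if max_offset < 1:
        raise ValueError("max_offset must be >= 1")
    n_bp = _duplex_length(ref_complex)
    if max_offset >= n_bp:
        raise ValueError(f"max_offset {max_offset} exceeds the {n_bp} bp duplex")
    thresholds = thresholds or ScanThresholds()
    hp = _helical_params_for(ref_complex, params)
    dimer = ref_complex.structure.subset(ref_complex.protein_chains)
    dimer_atoms = list(dimer.atoms())
    s_dimer = sasa(dimer_atoms, radii, probe, n_points).total
    dna = ref_complex.structure.subset(ref_complex.dna_chains)
    dna_atoms = list(dna.atoms())
    s_dna_free = sasa(dna_atoms, radii, probe, n_points).total if include_dna_buried \
        else None
    records = []
    for s in range(1, max_offset + 1):
        moved = apply_transform(dimer, helical_step(hp, s))
        moved_atoms = list(moved.atoms())
        n_clash, worst = clash_score(dimer_atoms, moved_atoms, radii,
                                     thresholds.overlap_tol)
        s_pair = sasa(dimer_atoms + moved_atoms, radii, probe, n_points).total
        cs_dd = (2.0 * s_dimer - s_pair) / 2.0
        dna_buried = None
        if include_dna_buried:
            s_all = sasa(dna_atoms + dimer_atoms + moved_atoms, radii, probe,
                         n_points).per_atom[: len(dna_atoms)].sum()
            dna_buried = float(s_dna_free - s_all)
        if n_clash > 0:
            label = "clash"
        elif cs_dd >= thresholds.cs_min:
            label = "contact"
        else:
            label = "separated"
        records.append(OffsetRecord(s, float(cs_dd), n_clash, worst,
                                    dna_buried, label))
    return SpacingScanResult(tuple(records), thresholds)


def build_multimer(ref_complex: DockModel, offsets,
                   params: HelicalParameters | None = None,
                   force: bool = False,
                   probe: float = 1.4, radii: RadiiSet = DEFAULT_RADII,
                   n_points: int = 240,
                   compute_surfaces: bool = True) -> MultimerModel:
    """Assemble dimer copies at the given offsets on one duplex.

    `offsets` must be strictly increasing integers starting at 0.  Unless
    `force` is set, any clashing pair of copies aborts assembly with an
    error naming the offending offsets.  Reports adjacent-copy contact
    surfaces and the total DNA area buried by all copies.
    """
    offsets = tuple(int(o) for o in offsets)
    if not offsets:
        raise ValueError("need at least one offset")
    if offsets[0] != 0:
        raise ValueError(f"first offset must be 0, got {offsets[0]}")
    if any(b <= a for a, b in zip(offsets, offsets[1:])):
        raise ValueError(f"offsets must be strictly increasing, got {offsets}")
    n_bp = _duplex_length(ref_complex)
    if offsets[-1] >= n_bp:
        raise ValueError(f"offset {offsets[-1]} exceeds the {n_bp} bp duplex")
    hp = _helical_params_for(ref_complex, params)
    dimer = ref_complex.structure.subset(ref_complex.protein_chains)
    copies = [apply_transform(dimer, helical_step(hp, s)) for s in offsets]
    copy_atoms = [list(c.atoms()) for c in copies]
    thresholds = ScanThresholds()
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            n_clash, worst = clash_score(copy_atoms[i], copy_atoms[j], radii,
                                         thresholds.overlap_tol)
            if n_clash > 0 and not force:
                raise ValueError(
                    f"copies at offsets {offsets[i]} and {offsets[j]} bp clash "
                    f"({n_clash} pairs, worst overlap {worst:.2f} Å); "
                    "use force=True to assemble anyway")
    # reassign chain ids so the assembly has a unique id per chain
    used = set(ref_complex.dna_chains)
    pool = iter(c for c in _CHAIN_POOL if c not in used)
    chains = []
    copy_chain_ids = []
    for copy in copies:
        ids = []
        for chain in copy.chains:
            new = chain.copy()
            new.id = next(pool)
            ids.append(new.id)
            chains.append(new)
        copy_chain_ids.append(tuple(ids))
    dna = ref_complex.structure.subset(ref_complex.dna_chains)
    structure = Structure(name="multimer", chains=chains + [c for c in dna.chains],
                          provenance={"offsets": list(offsets), "transforms": []})
    adjacent_cs: tuple[float, ...] = ()
    dna_buried = None
    if compute_surfaces:
        s_dimer = sasa(copy_atoms[0], radii, probe, n_points).total
        adj = []
        for a, b in zip(copy_atoms, copy_atoms[1:]):
            s_pair = sasa(a + b, radii, probe, n_points).total
            adj.append((2.0 * s_dimer - s_pair) / 2.0)
        adjacent_cs = tuple(adj)
        dna_atoms = list(dna.atoms())
        s_free = sasa(dna_atoms, radii, probe, n_points).total
        all_atoms = dna_atoms + [a for atoms in copy_atoms for a in atoms]
        s_bound = sasa(all_atoms, radii, probe, n_points).per_atom[: len(dna_atoms)].sum()
        dna_buried = float(s_free - s_bound)
    return MultimerModel(structure=structure, offsets=offsets,
                         copy_chains=tuple(copy_chain_ids),
                         dna_chains=ref_complex.dna_chains,
                         adjacent_cs=adjacent_cs,
                         dna_overlapped_surface=dna_buried)


def multimer_footprint_span(offsets, dimer_footprint_bp: int) -> int:
    """Protected span of a multimer: dimer footprint plus the offset range.

    Exact integer arithmetic: three dimers at 0/3/6 bp with a 21 bp dimer
    footprint protect 27 bp; at 0/6/12 bp they protect 33 bp.
    """
    offsets = [int(o) for o in offsets]
    if not offsets:
        raise ValueError("need at least one offset")
    if int(dimer_footprint_bp) < 1:
        raise ValueError("dimer footprint must be >= 1 bp")
    if offsets != sorted(offsets):
        raise ValueError(f"offsets must be sorted ascending, got {offsets}")
    if offsets[0] != 0:
        raise ValueError(f"offsets must start at 0, got {offsets}")
    return int(dimer_footprint_bp) + (max(offsets) - min(offsets))


@dataclass(frozen=True)
class SwitchReport:
    """Which divergent genes a protected interval silences.

    A gene is 'blocked' when the protected interval overlaps its −10 or −35
    box (sigma factor can no longer engage the promoter); otherwise 'free'.
    """

    protected_interval: tuple[int, int]
    genes: dict[str, dict] = field(default_factory=dict)

    def verdict(self, gene: str) -> str:
        return self.genes[gene]["verdict"]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def switch_report(protected_interval, genes) -> SwitchReport:
    """Intersect a protected DNA interval with each gene's promoter boxes.

    `protected_interval` is an inclusive (start, end) pair of 0-based
    top-strand coordinates; `genes` maps names to :class:`GenePromoter`
    annotations carrying −10 (and optionally −35) intervals in the same
    coordinates.  Re-run with a shorter interval (e.g. after removing an
    end dimer from the multimer) to model the transcriptional switch.
    """
    lo, hi = int(protected_interval[0]), int(protected_interval[1])
    if lo > hi:
        raise ValueError(f"inverted protected interval {protected_interval}")
    out = {}
    for name, gene in genes.items():
        if not isinstance(gene, GenePromoter):
            raise TypeError(f"gene {name!r}: expected GenePromoter")
        if gene.minus10 is None:
            raise ValueError(f"gene {name!r} has no −10 box annotation")
        hits10 = _overlap((lo, hi), gene.minus10)
        hits35 = gene.minus35 is not None and _overlap((lo, hi), gene.minus35)
        out[name] = {
            "strand": gene.strand,
            "overlaps_minus10": hits10,
            "overlaps_minus35": hits35,
            "verdict": "blocked" if (hits10 or hits35) else "free",
        }
    return SwitchReport(protected_interval=(lo, hi), genes=out)
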