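"""Promoter-sequence analysis for a divergently transcribed gene pair.

Coordinates follow the bacterial promoter convention: the transcription
start site (TSS) is position +1, upstream positions are negative, and there
is no position 0.  Internally everything is 0-based half-open on the top
strand, with explicit converters.  A minus-strand gene is scanned on the
reverse complement of the region, with hits reported in that gene's own
promoter frame.

The analyses cover the elements a sigma-70 promoter dissection needs:
AT-only runs (the kind of long AT tract FUR-family repressors sit on),
central (dyad) symmetry of a window, −10/−35 box scanning with IUPAC
wildcards relative to a TSS, and FUR-box style repeat arrays — tandem
hexamer repeats (GATAAT) or the 7-1-7 inverted-repeat reading of the
19 bp operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenePromoter", "PromoterAnnotation", "MotifHit", "RepeatArray",
    "find_at_runs", "symmetry_score", "scan_box", "find_repeat_array",
    "promoter_to_index", "index_to_promoter", "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# IUPAC nucleotide codes; 'n' (any) positions are wildcards in consensus.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenePromoter:
    """One gene's promoter frame within the shared region.

    `tss_index` is the 0-based top-strand index of the +1 nucleotide.
    Optional box intervals are inclusive 0-based top-strand (start, end)
    pairs, annotation only.
    """

    name: str
    strand: str                      # '+' (reads rightward on top strand) or '-'
    tss_index: int
    minus10: tuple[int, int] | None = None
    minus35: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for box in (self.minus10, self.minus35):
            if box is not None and box[0] > box[1]:
                raise ValueError(f"inverted box interval {box}")


@dataclass(frozen=True)
class PromoterAnnotation:
    """A promoter-region sequence plus the frames of the genes it serves."""

    sequence: str
    genes: dict[str, GenePromoter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        for g in self.genes.values():
            if not 0 <= g.tss_index < len(seq):
                raise ValueError(f"gene {g.name}: TSS index {g.tss_index} outside sequence")

    def gene(self, name: str) -> GenePromoter:
        try:
            return self.genes[name]
        except KeyError:
            raise KeyError(f"no gene {name!r}; have {sorted(self.genes)}") from None

    def gene_strand_sequence(self, name: str) -> str:
        """The full region as read by this gene (reverse complement for '-')."""
        g = self.gene(name)
        return self.sequence if g.strand == "+" else reverse_complement(self.sequence)

    def gene_tss_offset(self, name: str) -> int:
        """0-based index of the TSS within :meth:`gene_strand_sequence`."""
        g = self.gene(name)
        return g.tss_index if g.strand == "+" else len(self.sequence) - 1 - g.tss_index


def promoter_to_index(pos: int, tss_offset: int) -> int:
    """Promoter coordinate (+1 = TSS, no 0) → 0-based index on the gene strand."""
    if pos == 0:
        raise ValueError("promoter coordinates have no position 0")
    return tss_offset + pos - 1 if pos > 0 else tss_offset + pos


def index_to_promoter(idx: int, tss_offset: int) -> int:
    """0-based gene-strand index → promoter coordinate (no 0)."""
    d = idx - tss_offset
    return d + 1 if d >= 0 else d


@dataclass(frozen=True)
class MotifHit:
    start: int                     # promoter coordinate of the 5'-most base
    end: int                       # promoter coordinate of the 3'-most base
    strand: str
    matched: str
    consensus: str
    n_mismatch: int
    mismatch_positions: tuple[int, ...]   # 1-based positions within the element


@dataclass(frozen=True)
class RepeatArray:
    start: int                     # 0-based index in the scanned sequence
    n_repeats: int
    unit: str
    total_mismatches: int
    kind: str = "tandem"           # 'tandem' or 'inverted-7-1-7'


def find_at_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of A/T of length ≥ `min_len`, as (0-based start, length)."""
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    s = seq.upper()
    runs = []
    i = 0
    while i < len(s):
        if s[i] in "AT":
            j = i
            while j < len(s) and s[j] in "AT":
                j += 1
            if j - i >= min_len:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def symmetry_score(window: str) -> float:
    """Fraction of positions at which a window equals its reverse complement.

    1.0 for a perfect dyad (the window reads the same on both strands), the
    feature that suits a site for a symmetric dimer.  Invariant under
    reverse complementation of the window.
    """
    if not window:
        raise ValueError("empty window")
    w = window.upper()
    rc = reverse_complement(w)
    return sum(a == b for a, b in zip(w, rc)) / len(w)


def _mismatches(word: str, consensus: str) -> tuple[int, tuple[int, ...]]:
    positions = []
    for k, (base, cons) in enumerate(zip(word, consensus), start=1):
        if cons in "Nn":
            continue
        allowed = _IUPAC.get(cons.upper())
        if allowed is None:
            raise ValueError(f"invalid consensus symbol {cons!r}")
        if base not in allowed:
            positions.append(k)
    return len(positions), tuple(positions)


def scan_box(annotation: PromoterAnnotation, gene: str, consensus: str,
             position_window, max_mismatch: int = 0) -> list[MotifHit]:
    """Scan for a promoter box near a gene's TSS.

    `consensus` is an IUPAC string; lowercase/'n' positions are wildcards.
    `position_window` is an iterable of candidate promoter coordinates for
    the element's 5'-most base (e.g. ``range(-14, -9)`` to let a hexamer
    start anywhere from −14 to −10).  Hits are on the gene's own strand and
    are reported in its promoter frame, ordered by position then mismatch
    count.
    """
    g = annotation.gene(gene)
    seq = annotation.gene_strand_sequence(gene)
    tss = annotation.gene_tss_offset(gene)
    L = len(consensus)
    hits = []
    for pos in position_window:
        idx = promoter_to_index(pos, tss)
        if idx < 0 or idx + L > len(seq):
            raise ValueError(
                f"window position {pos} places the element outside the sequence")
        word = seq[idx:idx + L]
        n_mm, where = _mismatches(word, consensus)
        if n_mm <= max_mismatch:
            hits.append(MotifHit(
                start=index_to_promoter(idx, tss),
                end=index_to_promoter(idx + L - 1, tss),
                strand=g.strand, matched=word, consensus=consensus,
                n_mismatch=n_mm, mismatch_positions=where))
    hits.sort(key=lambda h: (h.start, h.n_mismatch))
    return hits


def find_repeat_array(seq: str, unit: str = "GATAAT", min_repeats: int = 2,
                      max_mismatch_per_unit: int = 0,
                      mode: str = "tandem") -> list[RepeatArray]:
    """Find repeat arrays in a sequence.

    ``mode='tandem'``: maximal arrays of ≥ `min_repeats` consecutive copies
    of `unit`, each copy allowed `max_mismatch_per_unit` mismatches.

    ``mode='inverted-7-1-7'``: 15 bp windows whose last 7 bases are the
    reverse complement of the first 7 (with the per-unit tolerance applied
    to the second heptamer); `unit` and `min_repeats` are ignored beyond
    validation.
    """
    s = seq.upper()
    if mode == "inverted-7-1-7":
        out = []
        for i in range(len(s) - 14):
            left, right = s[i:i + 7], s[i + 8:i + 15]
            n_mm, _ = _mismatches(right, reverse_complement(left))
            if n_mm <= max_mismatch_per_unit:
                out.append(RepeatArray(start=i, n_repeats=2, unit=left,
                                       total_mismatches=n_mm, kind="inverted-7-1-7"))
        return out
    if mode != "tandem":
        raise ValueError(f"unknown mode {mode!r}")
    if len(unit) < 2:
        raise ValueError("repeat unit must be at least 2 bases")
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    u = len(unit)
    out = []
    i = 0
    while i + u <= len(s):
        n, mm_total, j = 0, 0, i
        while j + u <= len(s):
            n_mm, _ = _mismatches(s[j:j + u], unit)
            if n_mm > max_mismatch_per_unit:
                break
            n += 1
            mm_total += n_mm
            j += u
        if n >= min_repeats:
            out.append(RepeatArray(start=i, n_repeats=n, unit=unit,
                                   total_mismatches=mm_total))
            i = j  # maximal, non-overlapping
        else:
            i += 1
    return out
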