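# Methods

`wingdock` models how a winged helix-turn-helix (wHTH) transcription-factor
dimer — a FUR/PerR-family metalloregulator is the motivating case — binds
its operator DNA, and what happens when several such dimers assemble on the
same duplex.  Everything is rigid-body and surface-based: no force field,
no flexibility, no energies.  This note records the model, the defaults,
and the choices made where the design was genuinely open.

## Template-analogy docking

No experimental structure of the dimer-DNA complex is assumed.  Instead a
solved complex of a structurally analogous protein serves as template, and
the target protein inherits the template's protein-DNA geometry:

1. **Admissibility** (`templates.check_template_criteria`).  A template
   must bind a duplex of ≥ 20 bp, be homodimeric, carry a recognition
   helix followed by two antiparallel β-strands (the wing), and have
   resolution ≤ `max_resolution` (default 3.0 Å — "good" X-ray resolution,
   a deliberately conventional cut since no sharper criterion is defined).
   The wing-topology criterion is evaluated from the user-supplied
   `MotifSpec` annotation, not from a secondary-structure predictor:
   annotation is an input of this protocol, prediction is not its job.
2. **Fitting** (`templates.fit_monomer`).  The monomer is superposed onto
   the template's bound protein over the backbone atoms (N, CA, C, O) of a
   superposition motif — the recognition helix plus the wing strands
   (`H4S1S2`), optionally with the preceding helix (`H3H4S1S2`).  Backbone
   atoms only, because side chains differ between template and target.
   Superposition is closed-form least squares (Kabsch via SVD) with a
   reflection guard; degenerate (collinear, < 3 points) inputs are errors.
3. **Threading** (`bdna.thread_sequence`).  The template's nucleotides are
   rewritten to the target site sequence while every sugar-phosphate atom
   keeps its exact template coordinates — the backbone conformation at the
   interface is what the template contributes.  New bases are idealized
   planar bases placed on the old base's ring frame.  The frame is fitted
   on the ring atoms alone (a planar set still determines a unique proper
   rotation); including the preserved C1' in the fit would make repeated
   threading drift, whereas the ring-only fit is exactly idempotent.
4. **Closure** (`templates.close_dimer`).  The intact dimer is matched
   onto the placed monomer (step 1), then a single rigid transform of the
   whole dimer is refined against ≥ 3 distance restraints between motif
   atoms and DNA phosphates (step 2).  Default restraints are measured
   from the template between recognition-helix CA atoms and their nearest
   phosphate — they encode the template's wHTH/DNA pattern and must be
   overridable because no universal values exist.  The optimiser is
   derivative-free (Powell) over 6 rigid parameters, deterministically
   multi-started from the unperturbed pose plus eight fixed axis-angle
   perturbations (body diagonals, 0.1 rad); best objective wins, ties by
   smaller parameter norm.  A best-so-far objective trace is kept
   (monotone by construction) and non-convergence is flagged on the
   result, never silent.  Rigid refinement deliberately replaces any kind
   of restrained flexible minimisation: it is reproducible to the bit and
   preserves the dimer interface exactly.

Candidate models are ranked by contact surface (below), ties by restraint
RMS.  Binding free energies are out of scope.

## Ideal B-DNA and the screw algebra

`bdna.build_bdna` constructs canonical, straight-axis B-DNA: each base
pair sits on a standard reference frame (origin on the helix axis, pair
long axis along x) and successive frames are related by the screw
transform — rotation by the twist about the axis plus translation by the
rise along it.  Defaults are **rise 3.38 Å/bp** and **twist 36.0°/bp**
(10.0 bp/turn), both configurable (10.5 bp/turn is a selectable
alternative); the protocol itself never depends on a particular choice,
only the bp↔Å conversion does.  Full-atom nucleotides come from idealized
chemical-component geometry placed rigidly on each base frame, so the
backbone is a regular helix; 5'-terminal residues lack the phosphate.
Sequence-dependent fine structure (roll, propeller, bending, A/Z forms)
is deliberately not modelled — the protocol explicitly keeps the
template's backbone where conformation matters.

For experimental (non-ideal) duplexes the axis is estimated as the
best-fit line through base-pair frame origins (`bdna.helix_axis`); for
built DNA the origins lie exactly on the axis.  Frame origins, not atom
centroids, are the right "base-pair centers": centroids of the atoms do
not sit on the axis, the frame origins do.

## Surfaces, contacts, clashes, footprints

SASA (`surface.sasa`) is numerical sphere sampling in the Shrake-Rupley
spirit on a **deterministic Fibonacci lattice** — the module contains no
randomness, so every derived quantity is bit-reproducible.  Defaults:
probe 1.4 Å, 960 points/atom (isolated-sphere error < 1%; scans use
coarser lattices, see below), Bondi-style heavy-atom radii with a 1.7 Å
fallback for united-atom or pseudo-atom content.

The contact surface of an interface is half the accessible area lost on
complexation, `CS = (SASA_rec + SASA_lig − SASA_cplx)/2` — symmetric,
non-negative up to sampling noise, zero for separated bodies.

Clashes (`surface.clash_score`) count atom pairs with
`dist < r_i + r_j − tol`, default tolerance 0.5 Å of allowed vdW
interpenetration.

The DNA footprint (`surface.dna_footprint`) is the per-nucleotide
accessible area lost when the protein is present; a base pair is
protected when either paired nucleotide buries more than 1.0 Å²
(default), and the reported span is first-to-last protected pair — a
single contiguous length, the way a nuclease-protection gel is read.  The
threshold is a documented convention, not a reproduction guarantee for
any particular published footprint; the raw protected set and per-bp
areas are also returned.

## Multimer spacing scan and the switch model

A bound dimer is a rigid building block.  `multimer.scan_spacings` fixes
one copy and places a second at every offset 1..max in 1-bp helical
increments, classifying each spacing as

* `clash` — any heavy-atom pair overlaps by > 0.5 Å;
* `contact` — no clash and dimer-dimer CS ≥ 1 Å²;
* `separated` — otherwise.

Both cutoffs are configurable; they reproduce the qualitative three-way
grouping the scan is meant to produce, since no published numeric cutoffs
exist.  The scan also reports the total DNA area buried by the two copies
("DNA overlapped surface").  Two caveats discovered with the toy models
and true of any such scan: the buried area oscillates with the copy's
azimuth (offsets a full turn apart are directly comparable; at exactly
one turn the copy is a pure translation and the burial is exactly twice
the single-dimer value), and offsets that push a copy near the duplex end
bury less.  The isolated-dimer SASA is computed once and reused — a rigid
copy has the same isolated area.

`multimer.build_multimer` assembles explicit offset lists (0-3-6 and
0-6-12 hexamers, longer polymers) with an all-pairs clash gate
(overridable with `force`), and the protected span of a multimer is exact
integer arithmetic: `span = dimer_footprint + (max_offset − min_offset)`.
`multimer.switch_report` intersects a protected interval with each
divergent gene's −10/−35 boxes: a gene is `blocked` when either box is
covered; re-running with an end dimer removed models the transcriptional
switch in which releasing one border dimer frees one gene.

## Promoter analysis

Coordinates follow the bacterial convention (+1 = TSS, no position 0);
minus-strand genes are scanned on the reverse complement and reported in
their own frame.  `scan_box` scores IUPAC consensus matches (n =
wildcard) by Hamming distance over non-wildcard positions within a
position window near the TSS; −35/−10 spacing can be checked at 17 bp
(canonical) or 30 bp.  `find_at_runs` returns maximal A/T-only runs,
`symmetry_score` the fraction of positions at which a window equals its
own reverse complement (1.0 = perfect dyad, the feature suiting a site
for a symmetric dimer), and `find_repeat_array` finds tandem GATAAT-style
arrays or 7-1-7 inverted repeats (7-mer, 1 spacer, reverse-complement
7-mer).  Where a published element's lowercase casing disagrees with the
computed Hamming distance, the scanner reports the computed distance.

## Synthetic fixtures: what they do and do not show

The generators in `wingdock.fixtures` make the pipeline testable without
downloads:

* **Sphere-pair toy dimer** — two fat pseudo-atoms on opposite faces of
  the duplex.  Its clash/contact boundaries have closed forms (sphere-cap
  geometry), so the spacing scan can be checked offset-by-offset against
  an independent analytic oracle.  The custom lobe radius travels in a
  `RadiiSet` returned with the model; multi-atom envelopes use carbon
  radii so the surface code needs no special cases.
* **Helix-bundle toy dimer** — lobes of carbon-radius rods hugging the
  duplex, calibrated at construction: the lobe extent is bisected until
  the measured footprint span equals the requested value (the span is
  integer-valued and monotone in the extent), and construction fails
  rather than deliver a mis-calibrated fixture.
* **Pseudo-protein template** — ideal α-helix/β-strand backbone traces
  for H1…H5/S1…S5 arranged as a homodimer on a symmetric 25 bp AT-rich
  duplex, with its `MotifSpec`; it passes all four admissibility criteria
  by construction and supports exact self-fit and closure-recovery tests.
* **Promoter fixture** — a seeded random background with exactly planted
  boxes and AT runs, ground truth recorded.

These fixtures validate the *machinery* — superposition, screw algebra,
surface numerics, classification logic, coordinate conventions.  They do
not show that any particular biological complex is modelled correctly:
real proteins have irregular envelopes, real DNA is not ideal, and real
footprints depend on the chemistry of the probe.  Quantities that depend
on a specific published model's minimised coordinates (absolute contact
surfaces in Å², per-spacing surface tables) are outside what passing
tests establish.

## Numerical choices and problem sizes

* Superposition tolerance: rotations proper to 1e-9; collinearity cut at
  a relative singular-value threshold of 1e-8.
* SASA lattices: 960 points/atom for headline numbers, 240-480 for scans
  and footprints (isolated-sphere error at 240 points is ~0.5%, far below
  the 1 Å²-scale thresholds involved); all deterministic.
* Test problem sizes: duplexes of 25-60 bp, toy dimers of 2-300 pseudo
  atoms, spacing scans to offset 30, footprints of 5/11/21 bp — chosen so
  the whole suite and the analytic cross-checks run comfortably on one
  CPU while still exercising every code path at realistic geometry.
* Alternate locations resolve to the highest-occupancy conformer; only
  the first model of multi-model files is read; author residue numbering
  is preserved.
* Chain selection for templates is explicit everywhere (an assembly may
  contain more chains than the biological unit; the caller names the
  duplex and protein chains).

## Known limitations

Rigid bodies only — no induced fit, no DNA bending, no refinement beyond
the 6-parameter restraint fit.  The B-DNA builder's inter-residue
backbone connectivity is approximate (each nucleotide carries idealized
internal geometry; O3'-P linkage distances are not regularised).  The
footprint span is a contiguous first-to-last measure and can exceed the
size of a patchy protected set.  Association energetics, solvation and
metal-site chemistry are explicitly out of scope.
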