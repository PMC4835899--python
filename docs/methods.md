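# Methods

`hemebarrel` analyzes ferredoxin α+β barrels: closed eight-stranded
antiparallel barrels built from two ferredoxin-like domains
(β1-α1-β2-β3-α2-β4, a two-layer α+β sandwich), the architecture of the
"dimeric α+β barrel" superfamily that hosts heme-degrading (IsdG/MhuD),
heme-cofactor (chlorite dismutase, DyP peroxidases, aldoxime dehydratase)
and siroheme-decarboxylating enzymes.  This note documents the models,
conventions and numerical choices behind each stage.

## Secondary structure

Backbone amide hydrogens are placed geometrically when absent (1.0 Å from
N along the bisector opposite the N's two heavy-atom neighbours), and
donor–acceptor energies use the classic dipole–dipole form

    E = 0.084 · 332 · (1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN)  kcal/mol,

with bonds kept below a cutoff of −0.5 kcal/mol and at most the two best
bonds per donor.  Amides cannot bond their own or an adjacent residue's
carbonyl (|i−j| ≥ 2 within a chain): sterically impossible, and in
idealized uniform-φ/ψ fixtures the naive formula would otherwise produce
spurious strong i→i−1 contacts.

Assignment is two-state by design.  Helix: two consecutive i+4→i turns
mark residues i+1…i+4.  Strand: ladders of ≥2 consecutive parallel or
antiparallel bridges (the standard bridge patterns), with single gaps
inside a run filled.  Runs shorter than 3 (strand) or 4 (helix) residues
are dropped, and strand wins on overlap.  3₁₀/π helices, isolated
bridges, turns and accessibility are deliberately out of scope: the
topology analysis only consumes the helix/strand distinction.  Cα-only
models bypass geometry entirely through `accept_annotation` (per-chain
H/E/- strings); no Cα-trace inference is attempted, avoiding a second,
weaker assignment algorithm.

## Strand pairing and the barrel sheet

Strand pairs are supported by ≥2 inter-strand backbone hydrogen bonds or,
in annotation mode (no backbone), by ≥3 Cα–Cα contacts under 5.5 Å —
thresholds chosen so contact-mode pairing reproduces hydrogen-bond-mode
pairing on the idealized fixtures; all are configurable.  Orientation is
the sign of the dot product of least-squares strand direction vectors.
The barrel is the largest cycle of the pairing graph; `closed` requires
exactly eight strands in one cycle.  A missing cycle is a diagnosis, not
an exception — open sheets are legitimate outcomes for damaged input.

The axis is chosen among the singular directions of the centered strand
midpoints as the one best aligned with the strand directions themselves
(for untilted strands on a cylinder the midpoints are nearly coplanar, so
the smallest-spread direction coincides with it; the alignment criterion
keeps the choice stable under noise).  Axis sign is fixed so the first
chain's N-terminus projects negative.

## Domain mapping

Per chain, the element subsequence matching E-H-E-E-H-E with all four
strands in the core cycle is selected, maximizing core membership first
and total element length second — this skips peripheral decorations.
One missing helix per domain is tolerated (degraded-helix cases occur in
the family) and flagged.  Two matches on one chain ⇒ fused barrel, with
continuous barrel-level labels (the second half's α1 is barrel α3, its
β1 barrel β5, …).  Two chains ⇒ homodimer when residue-name identity
exceeds 0.95 (difflib ratio), else heterodimer; the families distinguish
these biologically but no numeric threshold exists in the literature, so
0.95 ("same gene product up to point changes") is a configuration
default.

## Packing classification

A closed 8-cycle with two contiguous 4-strand domains has exactly two
inter-domain seams.  Type-1 ⇔ seams {β2ᴬ–β4ᴮ, β4ᴬ–β2ᴮ}; Type-2 ⇔
{β2ᴬ–β2ᴮ, β4ᴬ–β4ᴮ}.  Anything else is `unclassified` with diagnostics —
never a silent guess.  The strand-order string is reported in arrow
notation starting at domain A's β2, proceeding toward its β3.  Termini
orientation (all four termini on one barrel end for Type-1; the two
domains' termini on opposite ends for Type-2) is computed as axial
projections and reported as corroboration only: strand pairing defines
the type, termini orientation is its geometric corollary.

Note one deliberate consequence of sequence-defined labels: circularly
permuting one domain of a Type-1 barrel relabels its strands so the
seams read as Type-2.  That is not a bug — it is precisely the
label-relative equivalence that the rotation/permutation analysis of the
superfamily exploits.

## Domain superposition and correspondence kinds

The ferredoxin-like fold carries an internal pseudo-two-fold exchanging
its two β-α-β units (β1↔β3, α1↔α2, β2↔β4).  Two domains are therefore
equivalenced under two label maps: identity and half-swap.  For each
map, initial residue pairs are built center-anchored within mapped
elements, fitted by the closed-form least-squares rotation (SVD with
determinant correction to exclude reflections), then refined by
mutually-nearest Cα re-pairing within 4.5 Å (order-preserving within
each element) until stable, at most 10 iterations.  The winner has the
most pairs within 4.0 Å, ties broken by RMSD.  The 4.5/4.0 Å thresholds
follow common structure-alignment practice.

A mathematical point governs the naming.  For an exactly symmetric
domain, a circular permutant (units swapped in sequence, coordinates
unchanged) is rigid-motion-indistinguishable from a 180°-rotated copy:
symmetry∘relabel is an automorphism, so no intrinsic invariant separates
"rotated" from "permuted".  The distinction is real only relative to how
the domains actually sit — e.g. in their barrels.  The four reported
kinds therefore combine the label map with the fitted rotation angle
between the inputs *as given*:

| kind             | label map | fitted angle |
|------------------|-----------|--------------|
| direct           | identity  | < 90°        |
| permuted         | half-swap | < 90°        |
| rotated          | half-swap | ≥ 90°        |
| rotated+permuted | identity  | ≥ 90°        |

RMSD and pair count are rigid-invariant; the kind label is
frame-relative by necessity and is meaningful when the inputs share a
frame (domains of one barrel, or barrels pre-aligned on their axes).
Reports always list all candidates with RMSD, pair count and angle so
the evidence is auditable.

## Heme-site analysis

Proximal residue: nearest candidate coordinating atom (His NE2/ND1, Tyr
OH, Cys SG, Met SD) within 3.5 Å of the iron — standard axial
coordination distance.  Distal: nearest functional side chain (His, Arg,
Asn, Ser atoms) within 6.0 Å of Fe on the opposite side of the
least-squares macrocycle plane; absence is recorded, not an error (the
family includes structures with disordered proximal helices).

Binding mode: Fe inside the β-cylinder (radial distance < 0.75 × mean
core-strand radius) ⇒ barrel cavity (siroheme-decarboxylase-like);
otherwise the proximal residue's host element decides — α2 of a domain ⇒
IsdG/OxdA-like cleft, α1 ⇒ Cld/DyP-like, β2 with cavity placement ⇒
cavity.  The 0.75 margin quantifies a dichotomy ("domain cleft" vs
"barrel cavity") that is qualitative in the literature; conflicting
signals are reported with both pieces of evidence.

Ruffling is the RMS out-of-plane deviation of the macrocycle heavy atoms
(pyrrole N/C plus meso carbons; propionates excluded) about their
least-squares plane, with a ruffled/planar threshold of 0.25 Å chosen so
that idealized planar and meso-displaced fixtures separate cleanly; it
is configurable because published ruffled/planar assignments are
qualitative.

## Synthetic data

The generator emulates the study conditions, not physics:

* **Barrels** are Cα-level: eight strands on a cylinder of radius 6.0 Å
  (adjacent-strand spacing 4.6 Å, the cross-strand Cα–Cα distance of a
  hydrogen-bonded sheet; idealized untilted strands lack the shear that
  widens real barrels), 3.4 Å rise, alternating up/down, slotted per
  packing type; domain B is an exact rigid image of domain A under the
  dimer operator (180° about the barrel axis for Type-1, an in-plane
  two-fold for Type-2), so homodimer protomers are congruent and the
  termini ground truth holds by construction.  Helices are Cα spirals
  outside the sheet; loops are straight interpolations.  Secondary
  structure is injected as annotation.  The two β-α-β units have
  deliberately different element lengths (7/8/7 vs 5/6/5 residues) so
  the internal pseudo-symmetry does not make correspondence hypotheses
  degenerate.
* **Ladders and helices** are full-backbone ideal-geometry fixtures
  (internal-coordinate chain building; the ladder partner strand is
  placed by a deterministic grid search maximizing inter-strand hydrogen
  bonds) and exercise the geometric secondary-structure path.
* **Pseudo-hemes** are planar Fe+N₄+C₂₀ macrocycles placed 2.1 Å from a
  designated histidine's NE2 (cleft placements outside the sheet next to
  α1/α2; cavity placement toward the axis), after noise, so axial
  geometry is exact by construction.
* All randomness flows through one seeded generator; equal seeds give
  byte-identical output files.

What passing on these fixtures does **not** show: robustness to real
sheet twist/shear, strand bulges, alternative conformations, missing
density, or non-ideal coordination geometry.  The pipeline reads real
PDB/mmCIF files, but its quantitative validation here is against
idealized ground truth.

## Problem sizes and determinism

The validation study uses 100 barrels (50 per type, σ = 0.3 Å), 80
domain pairs (4 kinds × 20 seeds, σ = 0.5 Å), 30 heme sites (3 modes ×
10 seeds, σ = 0.3 Å) and 20 random 10-point Kabsch instances checked
against a derivative-free numeric rotation search.  All sizes are fixed
in `scripts/acceptance.py`; the script's `--seed` drives every random
stream, and reruns with the same seed are bit-identical.

## Known limitations

* One barrel at a time; higher oligomers and biological-assembly
  expansion are out of scope (chains are selected by the caller).
* Two-state secondary structure only; bulged strands may fragment and
  break the 8-cycle on difficult real structures.
* The rotated/permuted kind label is frame-relative (see above).
* Heterodimer detection relies on residue-name identity, not alignment.
* No shear-number or barrel-radius modelling.
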