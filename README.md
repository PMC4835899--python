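# hemebarrel

Topology, internal-symmetry and heme-site analysis of **ferredoxin α+β
barrels** — the "dimeric α+β barrel" superfamily whose members include
heme-degrading monooxygenases (IsdG/IsdI, MhuD, HmoB), chlorite
dismutase, DyP-type peroxidases, EfeB, HemQ, aldoxime dehydratase and
siroheme decarboxylase.

These barrels are built from two ferredoxin-like domains
(β1-α1-β2-β3-α2-β4), either as separate chains or fused in tandem, whose
antiparallel sheets close into an eight-stranded barrel.  The package
answers, per structure, the questions a comparative analysis of this
superfamily turns on:

* **How do the two domains pack?**  Reading the two inter-domain strand
  seams off the hydrogen-bonded 8-cycle distinguishes two modes:
  *Type-1* (β2—β4 / β4—β2, all four domain termini on one barrel end,
  strand order `β2↑ β3↓ β1↑ β4↓ β2↑ β3↓ β1↑ β4↓`) and *Type-2*
  (β2—β2 / β4—β4, domain termini on opposite ends,
  `β2↑ β3↓ β1↑ β4↓ β4↑ β1↓ β3↑ β2↓`).
* **How do two domains superpose?**  The ferredoxin-like fold has an
  internal pseudo-two-fold exchanging its β-α-β units (β1↔β3, α1↔α2,
  β2↔β4), so two domains can be equivalenced label-to-label or across
  the symmetry — the latter realizing either a 180° rotation or a
  circular permutation.  All candidate correspondences are fitted by a
  least-squares (Kabsch) superposition with iterative re-pairing and
  reported with RMSD, pair count and rotation angle.
* **Where is the heme?**  Axial proximal/distal residues from
  coordination geometry, the host element (α2 cleft: IsdG/OxdA-like;
  α1: Cld/DyP-like; barrel cavity: siroheme-decarboxylase-like), iron
  radial position, and macrocycle ruffling as RMS out-of-plane
  deviation.

A deterministic synthetic-data module generates idealized barrels,
ladders, helices, circular permutants and pseudo-hemes with exact ground
truth, so the entire pipeline is testable without downloading
structures.  Real PDB/mmCIF files are read with gemmi through the same
interface.

## Worked example

Generate a noisy Type-2 barrel with a heme in the α2 cleft, classify it,
and superpose its two domains:

```sh
hemebarrel synth demo.pdb --packing Type-2 --heme cleft_alpha2 --noise 0.3 --seed 17
hemebarrel classify demo.pdb --annotation demo.pdb.json --json demo_report.json
```

prints

```
structure : demo  chains A,B
arrangement: homodimer
packing    : Type-2
order      : β2↑ β3↓ β1↑ β4↓ β4↑ β1↓ β3↑ β2↓
termini ok : True
hemes      : 1
  HEM: mode=SITE_CLEFT_ISDG_OXDA proximal=A/HIS44:NE2 @2.10A host=('A', 'alpha2') ruffling=0.000A
  map  direct           rmsd= 0.64A pairs= 38 angle=179.5
  map  rotated          rmsd= 0.99A pairs= 23 angle=179.9
  map  permuted         rmsd= 0.99A pairs= 23 angle=179.9
  map *rotated+permuted rmsd= 0.64A pairs= 38 angle=179.5
```

Reading this: the strand-pairing graph closed into an 8-cycle whose two
inter-domain seams are β2—β2 and β4—β4, hence Type-2 packing, with the
two domains' termini on opposite barrel ends as that packing implies.
The heme iron is coordinated by His44 NE2 at 2.10 Å, hosted on the α2
helix of domain A — the IsdG/OxdA-like cleft mode — and the macrocycle
is planar (ruffling RMS 0.000 Å).  The domain-correspondence table shows
both domains of this homodimer superpose label-to-label with 38 Cα pairs
at 0.64 Å under a ~180° relative rotation (the dimer two-fold of a
Type-2 barrel), while the half-swap (rotation/permutation) hypothesis
aligns fewer pairs — the starred row is the winner.

The same questions are available as library calls (`load_structure`,
`assign_ss`/`accept_annotation`, `pair_strands`, `build_barrel_sheet`,
`map_domains`, `classify_packing`, `align_domains`,
`analyze_heme_site`); `hemebarrel compare` superposes domains from two
different files.

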