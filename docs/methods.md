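# Methods

This note documents the models, parameters and numerical choices behind
`varstruct`, and what its synthetic fixtures do and do not demonstrate.

## Coordinate conventions

All positions are *precursor* numbering: residue 1 is the initiator of the
translated chain, the signal peptide occupies residues 1–23 by default
(configurable). Structure files in mature-chain numbering are shifted by a
user-supplied offset at read time (`file number + offset = precursor
number`); the offset is subtracted again on writing. Only PDB is read and
written; the first MODEL of an ensemble is used, HETATM records, waters,
hydrogens and alternate locations other than A are dropped. Input
hydrogens are discarded deliberately: all polar hydrogens are rebuilt
geometrically so wild-type and mutant models are treated identically.

## Secondary structure

A Kabsch–Sander-style assignment on the reduced alphabet {H, G, E, T, C}.
The backbone amide hydrogen sits 1.0 Å from N opposite the bisector of the
N–CA and N–C(prev) bonds (none for proline or chain-leading residues). The
electrostatic H-bond energy

    E = 0.084 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332  kcal/mol

defines a bond when E < −0.5 kcal/mol. Two consecutive i→i+4 turns make a
4-helix (H), two consecutive i→i+3 turns a 3₁₀ helix (G), the standard
parallel/antiparallel bridge patterns make strands (E, isolated bridges
included), residues bracketed by isolated turns are T, the rest C, with
priority H > E > G > T. Chain breaks (missing backbone atoms,
non-consecutive numbering, or CA–CA > 4.5 Å) split the assignment windows.
On ideal-helix and β-hairpin fixtures the assignment agrees exactly, at
the reduced-alphabet level, with an independent DSSP implementation
(mdtraj's), which the test suite uses as an external oracle. Exact parity
with DSSP's full output on arbitrary real structures (π-helices, bends,
chirality flags) is out of scope.

## Solvent accessibility

Shrake–Rupley sphere sampling with a deterministic golden-spiral point set
— SASA is therefore seed-free and bitwise reproducible; doubling the
density changes totals by well under 0.5%. Defaults: 960 points per atom,
probe 1.4 Å, Chothia van-der-Waals radii (C 1.87, N 1.65, O 1.40, S 1.85 Å;
unknown elements get 1.8 Å with a warning). Relative accessibility divides
residue SASA by theoretical Gly-X-Gly maxima (Tien et al. theoretical
set), so extended conformations can exceed 100% (values are capped at
200%). Burial classes follow common RSA conventions — buried < 20%,
partially exposed 20–50%, exposed > 50% — with boundaries assigned to the
more exposed class. The thresholds are arguments, not constants, because
the class names matter more than the exact cutoffs for diff purposes.

## Interaction detection

* **H-bonds** (HBPLUS-style geometric criteria): donor–acceptor ≤ 3.9 Å,
  hydrogen–acceptor ≤ 2.5 Å, donor–H–acceptor angle ≥ 90°. Polar
  hydrogens are placed by idealized geometry: sp2 N–H fixed in the group
  plane; rotatable donors (Lys NZ, Ser/Thr/Tyr hydroxyls) constrained to
  the tetrahedral cone about the antecedent bond with the azimuth oriented
  toward the nearest acceptor outside the residue. Histidine is treated as
  doubly protonated, so ND1/NE2 act as both donors and acceptors.
  Same-residue and covalently adjacent backbone pairs are excluded; one
  bond is reported per donor-atom/acceptor-atom pair.
* **Salt bridges**: any basic side-chain nitrogen (Lys NZ; Arg NE, NH1,
  NH2; His ND1, NE2) within 4.0 Å of any acidic side-chain oxygen (Asp
  OD1/OD2; Glu OE1/OE2); the minimum-distance atom pair is reported per
  residue pair. Histidine counts as positive — charge-reversal variants
  next to histidines are exactly the interesting case.
* **Disulfides**: SG–SG ≤ 2.5 Å with greedy closest-first matching, so
  each cysteine joins at most one bond.
* **Hydrophobic contacts**: apolar side-chain carbons (carbons whose
  bonded heavy neighbours are all C or S, tabulated per residue type)
  of distinct residues within 3.9 Å.

Every detector is validated against an independent brute-force all-pairs
scan on random fixtures; the acceptance script re-measures that agreement
(expected: 100%).

## Mutant construction

Rigid-backbone side-chain replacement: backbone atoms of every residue are
bitwise unchanged; the side chain at the variant position is rebuilt from
idealized internal coordinates (standard bond lengths/angles encoded as
per-residue Z-matrices; CB placed at the L-configuration improper
torsion). A compact backbone-independent rotamer library (3–5 χ-tuples
per type with prior weights) is searched exhaustively; the clash score

    Σ max(0, r_vdw_sum − d)²   over side-chain/environment atom pairs,
                               1-2 and 1-3 bonded pairs excluded

selects the rotamer, ties broken by prior weight then library order.
Because 1-4 intra-residue contacts are included, ideal geometry carries a
small irreducible baseline (up to ~2.7 for the proline ring); the
`strained` flag therefore fires above a documented threshold of 3.0 rather
than above zero. Glycine targets simply drop the side chain. The builder
is fully deterministic; the `seed` argument exists for interface stability
and a future stochastic-jitter mode, and is recorded in output REMARKs.

This is the main modelling divergence from restraint-based mutant builders
that relax neighbouring side chains: here all geometric change is confined
to the substituted side chain, so profile diffs are site-centric by
construction, and interaction diffs should be read at the level of
detected partner sets, not exact geometry.

## Profile diffing

Gains and losses per interaction kind are the set differences of
residue-pair sets between mutant and wild type (hence exactly
antisymmetric under swapping the two profiles). Secondary-structure change
and burial-class change are evaluated at the variant position; ΔRSA is
reported alongside because no universally agreed percentage threshold
defines "accessibility changed" — the class change is the binary
criterion, the ΔRSA the quantitative one. `disulfide_lost` fires when a
wild-type disulfide involving the position disappears; `cys_introduced`
when the new residue is a cysteine (a potential ectopic disulfide). The
headline `any_structural_change` flag is the OR of these fields and is
re-derivable from the report itself.

## Consensus stability

Five predictor ΔΔG values per variant, normalized at ingestion to
negative = destabilizing (per-method sign flips are declared in the read
call). A method votes when |ΔΔG| ≥ its significance cutoff — cutoffs are
per-method and default to 0.5 kcal/mol, a common significance convention;
published per-server cutoffs can be supplied instead. Three agreeing
significant votes give `less_stable`/`more_stable`, anything else
`uncertain`; missing values abstain and are noted. With five votes a
double majority is impossible, and mixed significant votes without a
triple resolve to `uncertain`. The voting logic is independent of the
cutoff values; the exhaustive 3^5 truth table is checked in tests.

## Conservation

The grade scale is ConSurf-compatible (1 variable … 9 invariant), and
precomputed grades can be ingested directly. The built-in computation is
deliberately simple: per-column Shannon entropy, gaps excluded, normalized
by ln 20, binned as grade = 9 − floor(9h) and clipped to [1, 9]. This is a
desk-scale stand-in for phylogeny-aware rate estimation — adequate for
flagging clearly conserved columns, not for reproducing ConSurf's
per-residue values, which depend on tree inference and the MSA used.
The "highly conserved" flag is grade ≥ 7 either way.

## Regions

Chemokine-fold regions are derived from the model's own SS segmentation:
strands are E-runs after the signal peptide (three expected; a different
count warns and names loops by order), the C-helix is the last H-run after
the strands, loops between the named elements get the conventional
30s/40s/50s names, uncovered residues become `other`. Exact loop
boundaries are not standardized, so every interval is user-overridable;
overrides win over derived intervals position-by-position. Cohort
summaries count variants per region (always a partition, so counts sum to
the cohort size), per changed parameter, stability calls, the overlap of
stability loss with interaction loss, and conserved positions with and
without structural change.

## Synthetic fixtures: what they show

Fixture generators build structures from ideal internal coordinates with
ground truth recorded at generation: helices at (φ, ψ) = (−57°, −47°);
a β-hairpin whose near-type-I′ turn (55°, 45°)/(90°, 0°) was chosen so the
two strands actually form the cross-strand ladder; salt-bridge, disulfide
and two-chain fixtures with exact constructed pair distances (boundary
cases resolve from the placed coordinates, not the nominal parameter);
seeded random coils; a precursor-numbered cysteine scaffold with the
(33,57)/(34,73) pairing; and a charge-reversal site where a Lys→Glu
substitution gains a salt bridge with a nearby His. Cohort generators
draw distinct random missense variants and predictor tables whose 3-of-5
outcome is preset per variant.

These fixtures emulate local geometry, not evolved proteins: there is no
tertiary packing, no solvation physics, no realistic rotamer statistics.
Passing tests therefore demonstrate the correctness of the geometric
operators, the mutation builder's invariants and the pipeline's
book-keeping — not predictive accuracy on real variant cohorts, which
additionally depends on model quality and on the external ΔΔG predictors.

## Problem sizes and determinism

The cohort-scale checks run 105 variants on a 94-residue model — the size
of a typical chemokine precursor — which keeps a full acceptance run
around two minutes on one core. All randomness flows from explicit seeds;
SASA, mutation and the pipeline are bitwise deterministic given identical
inputs, and every output file embeds the package version and a hash of the
configuration (excluding the output directory, which cannot influence
results).

## Known limitations

* No backbone relaxation or neighbour repacking — H-bond/contact diffs for
  bulky substitutions in tight cores are lower bounds on the real
  rearrangement.
* Single substitutions only; co-occurring variants are out of scope.
* No π-stacking or cation-π detection; sulfur atoms are not H-bond
  acceptors.
* The coarse φ/ψ classifier (documented rectangles for favored/allowed
  regions) is a sanity check, not a Ramachandran validation tool.
* mmCIF, ligands and multi-chain assemblies (beyond two-chain interface
  mapping) are unsupported.
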