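# varstruct

Structural-impact profiling of missense variants on protein structures.

Given a single-chain protein model (PDB), a table of missense variants and,
optionally, per-variant ΔΔG predictions from external stability predictors,
a multiple sequence alignment and complex structures, `varstruct`:

1. builds a point-mutant model for every variant (rigid backbone,
   idealized side-chain geometry, clash-minimizing discrete rotamer choice);
2. computes wild-type and mutant per-residue structural profiles from first
   principles — Kabsch–Sander secondary structure, Shrake–Rupley solvent
   accessibility with buried / partially-exposed / exposed classes,
   geometric H-bonds, salt bridges, disulfides and hydrophobic contacts;
3. diffs the profiles at and around the mutated site;
4. classifies the stability change by a 3-of-5 predictor consensus
   (a method votes *less stable* when ΔΔG ≤ −cutoff, *more stable* when
   ΔΔG ≥ +cutoff, else abstains; three agreeing significant votes decide,
   anything else is *uncertain*);
5. flags evolutionarily conserved positions (ConSurf-style 1–9 grades,
   grade ≥ 7 = highly conserved) and maps each variant onto chemokine-fold
   regions (signal peptide, N-loop, β1–β3, 30s/40s/50s loops, C-helix);
6. aggregates cohort-level counts and renders TSV/JSON/HTML reports.

It was written for secreted chemokine precursors — all reporting uses
*precursor* numbering (signal peptide = residues 1–23 by default; files in
mature numbering are shifted with `--offset`) — but accepts any
single-chain PDB.

## The core quantities

* **Secondary structure.** Backbone amide hydrogens are placed
  geometrically and the Kabsch–Sander electrostatic energy
  `E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol`
  defines an H-bond when `E < −0.5`. Two consecutive i→i+4 turns give H,
  i→i+3 turns give G, bridge/ladder patterns give E, isolated turns T,
  everything else C.
* **Accessibility.** Shrake–Rupley sampling with a deterministic
  golden-spiral point set (960 points/atom, probe 1.4 Å, Chothia radii).
  RSA = SASA / max-SASA(Gly-X-Gly) · 100; classes: buried < 20 ≤ partially
  exposed < 50 ≤ exposed (boundaries go to the more exposed class).
* **Interactions.** H-bond: donor–acceptor ≤ 3.9 Å, H–acceptor ≤ 2.5 Å,
  D–H–A angle ≥ 90° after idealized polar-hydrogen placement. Salt bridge:
  basic side-chain N (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2) within 4.0 Å of
  acidic side-chain O (Asp OD1/OD2; Glu OE1/OE2). Disulfide: SG–SG ≤ 2.5 Å,
  greedy closest matching. Hydrophobic contact: apolar side-chain carbons
  ≤ 3.9 Å.
* **Consensus stability.** `less_stable` / `more_stable` when ≥ 3 of 5
  predictors agree beyond their per-method significance cutoffs
  (default 0.5 kcal/mol; negative ΔΔG = destabilizing), else `uncertain`.

## Worked example

A synthetic helix site carries a lysine at precursor position 78 with a
histidine placed nearby at position 39 — the classic charge-reversal
scenario where replacing the positive lysine with a negative glutamate
creates a brand-new salt bridge:

```python
import varstruct as vs
from varstruct.fixtures import make_charge_reversal_site

structure, _ = make_charge_reversal_site()
mutant, info = vs.build_mutant(structure, vs.VariantSpec.parse("p.Lys78Glu"))
wt  = vs.build_profile(structure)
mut = vs.build_profile(mutant)
report = vs.diff_profiles(wt, mut, vs.VariantSpec.parse("p.Lys78Glu"))
print("salt bridges gained:", report.salt_bridges_gained)
print("H-bonds lost:       ", report.hbonds_lost)
print("delta RSA:           %.1f%%" % report.delta_rsa)
print("any change:         ", report.any_structural_change)
```

prints

```
salt bridges gained: [(39, 78)]
H-bonds lost:        [(39, 78)]
delta RSA:           9.5%
any change:          True
```

i.e. the Glu78 carboxylate forms a salt bridge with His39, the H-bond the
wild-type lysine ammonium donated to the histidine is gone, and the
shorter glutamate side chain is 9.5 RSA points more exposed.

The same analysis runs from the shell over whole cohorts:

```bash
varstruct pipeline --structure model.pdb --offset 23 \
    --variants variants.tsv --predictors predictors.tsv \
    --msa family_alignment.fasta --out results/
```

which writes `impact_reports.tsv` (one row per variant), `summary.json`
(cohort counts: variants per region, per changed parameter, stability
calls, conserved-with-change overlaps), a per-residue wild-type profile,
the derived region table and a static HTML report with side-by-side
wild-type/mutant values. Subcommands `profile`, `mutate`, `diff`,
`consensus`, `regions` and `fixtures` expose the individual steps.

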