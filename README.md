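# poisedfrag

Design tools for **poised fragment libraries** in fragment-based drug
discovery (FBDD).  A fragment is *poised* when it can be made in one step
by a robust, general reaction (amide coupling, sulfonamide formation,
Suzuki coupling, Hantzsch thiazole synthesis, ...) from commercially
common building blocks.  Screening only poised fragments means every hit
comes with a built-in elaboration plan: deconstruct the hit at its poised
bond into synthons, buy commercial analogues of those synthons, and run
the same reaction in parallel to get a follow-up library within days —
crucial when hits are too weak for solution assays and only visible in
high-concentration crystallographic soaking, as for the atypical
bromodomain PHIP(2) that motivated this methodology.

The package provides, for computational chemists and screening librarians:

* a curated, configurable library of **21 poised reactions** (8 linking +
  13 heterocycle-forming) as paired retro/forward reaction SMARTS with a
  round-trip identity guarantee (`forward(retro(x)) == x`);
* **classification** of catalog molecules as poised, with synthon
  deconstruction under purchasing-friendly leaving-group conventions
  (amide → acyl chloride + amine);
* the **filter cascade** for library design: Rule-of-Three-flavoured
  property bounds, reaction-compatibility checks (no cross-reactive
  groups outside the poised bond), synthon availability against a vendor
  catalog;
* **diversity selection** via USRCAT shape-pharmacophore descriptors (60
  distance-distribution moments over 5 pharmacophoric atom subsets),
  Butina fingerprint clustering, and greedy max-min picking;
* **one-step follow-up enumeration** around a hit by synthon swapping;
* **SAR metrics**: pIC50 ↔ IC50 and Hopkins ligand efficiency
  `LE = 1.4 × pIC50 / heavy_atoms` (kcal/mol per heavy atom), plus the 22
  reconstructed PHIP(2) reference compounds with their assay results;
* a **synthetic catalog generator** that forward-synthesizes a labelled
  vendor-like catalog so every pipeline stage is testable without
  downloads, and a `dspl` command line over all of it.

## Worked example

Classify the N-benzylacetamide fragment hit and deconstruct it:

```sh
$ dspl classify --smiles "CC(=O)NCc1c(Cl)cccc1Cl"
amide	atoms=0,1,2,3	synthons=CC(=O)Cl + NCc1c(Cl)cccc1Cl
```

The fragment is amide-poised: acetyl chloride + 2,6-dichlorobenzylamine
remake it in one step, so analogues of either synthon give a follow-up
library.  Enumerate those follow-ups and score one of them — the
2,6-dimethoxy analogue, which the PHIP(2) campaign measured at
pIC50 3.72:

```sh
$ dspl le --pic50 3.72 --smiles "COc1cccc(OC)c1CNC(C)=O"
0.35
IC50 = 191 uM
```

That is a ligand efficiency of 0.35 kcal/mol per heavy atom at an IC50 of
~190 μM — a textbook fragment-to-lead improvement from an originally
assay-inactive hit.  The same operations are plain functions:

```python
from poisedfrag import (builtin_reaction_library, classify_poised,
                        deconstruct, forward_synthesize, ligand_efficiency)

lib = builtin_reaction_library()
deconstruct("CC(=O)NCc1c(Cl)cccc1Cl", "amide", lib)
# [['CC(=O)Cl', 'NCc1c(Cl)cccc1Cl']]
forward_synthesize("thiourea", ["Cc1ccccc1N", "N"], lib)
# 'Cc1ccccc1NC(N)=S'
ligand_efficiency(3.11, 11)
# 0.4
```

End-to-end library design (`dspl design`) runs catalog → property filters
→ poised classification → compatibility → availability → greedy diversity
pick, writing `selected.smi`, `annotations.csv` and a `report.json` with
per-stage counts, composition statistics and a config-hash provenance
block.  Stage counts describe the catalog you feed in: the historical
counts of the original Diamond/SGC libraries depended on 2015 vendor
snapshots and are not expected from other catalogs.

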