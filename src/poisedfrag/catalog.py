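"""Catalog readers/writers and the synthetic vendor-catalog generator.

The generator stands in for vendor fragment space at desk scale: it builds
randomized synthon pools per functional class (ring systems decorated with
small substituents plus the class's required functional group), forward-
synthesizes products with a controlled per-reaction composition, mixes in
hydrocarbon decoys that contain no poised bond at all, and emits the
ground-truth labels alongside - so classifier recall, false-positive rate
and composition recovery can all be scored against a known truth.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import SmilesError, canonical_smiles, mol_from_smiles
from .records import FragmentRecord, SynthonRecord
from .reactions import builtin_reaction_library, forward_synthesize, get_reaction

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def _iter_smi(path):
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if ln == 1 and parts[0].lower() in ("smiles", "structure"):
                continue  # optional header
            smiles = parts[0]
            ident = parts[1] if len(parts) > 1 else f"mol{ln}"
            yield ident, smiles


def read_catalog(path, fmt: Optional[str] = None) -> list:
    """Read a fragment catalog (.smi, .sdf or .csv) into FragmentRecords.

    Unparsable entries are skipped with a logged warning; if more than half
    of the file fails to parse the format is assumed wrong and a hard error
    is raised.  SMILES are canonicalized on ingest, order is preserved.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("smi", "sdf", "csv"):
        raise ValueError(f"unknown catalog format {fmt!r}")
    entries = []
    if fmt == "smi":
        entries = list(_iter_smi(path))
    elif fmt == "csv":
        df = pd.read_csv(path, dtype=str)
        cols = {c.lower(): c for c in df.columns}
        if "smiles" not in cols:
            raise ValueError(f"{path}: no 'smiles' column")
        id_col = cols.get("id")
        for i, row in df.iterrows():
            ident = str(row[id_col]) if id_col else f"mol{i + 1}"
            entries.append((ident, str(row[cols["smiles"]])))
    else:  # sdf (V2000)
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                entries.append((f"mol{i + 1}", None))
                continue
            ident = mol.GetProp("_Name") if mol.GetProp("_Name") else f"mol{i + 1}"
            entries.append((ident, Chem.MolToSmiles(mol)))

    records, skipped = [], 0
    for ident, smiles in entries:
        if smiles is None:
            skipped += 1
            continue
        try:
            records.append(FragmentRecord.from_smiles(ident, smiles, source=str(path)))
        except SmilesError:
            skipped += 1
            log.warning("skipping unparsable entry %r in %s", ident, path)
    if entries and skipped > len(entries) / 2:
        raise ValueError(
            f"{path}: {skipped}/{len(entries)} entries unparsable - wrong format?"
        )
    if skipped:
        log.warning("%s: skipped %d unparsable entries", path, skipped)
    read_catalog.last_skipped = skipped
    return records


def write_catalog(records: Sequence[FragmentRecord], path) -> None:
    """Write records as a two-column .smi file (SMILES, id)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")


def read_synthon_catalog(path) -> list:
    """Read a synthon catalog CSV: id, smiles, functional_class, available."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            out.append(
                SynthonRecord(
                    id=row["id"],
                    smiles=row["smiles"],
                    functional_class=row["functional_class"],
                    available=str(row.get("available", "1")).strip() in ("1", "true", "True"),
                )
            )
    return out


def write_synthon_catalog(synthons: Sequence[SynthonRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "functional_class", "available"])
        for s in synthons:
            writer.writerow([s.id, s.smiles, s.functional_class, int(s.available)])


# --------------------------------------------------------------------------
# Synthetic catalog generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCatalogSpec:
    """Recipe for a synthetic vendor catalog with ground-truth labels."""

    n: int = 1000
    composition: dict = field(
        default_factory=lambda: {"amide": 0.6, "ether": 0.2, "sulfonamide": 0.1}
    )
    decoy_fraction: float = 0.1
    pool_size: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        total = sum(self.composition.values()) + self.decoy_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition + decoy_fraction sums to {total}, not 1")


@dataclass
class GeneratedCatalog:
    fragments: list
    labels: pd.DataFrame  # columns: id, reaction
    synthons: list


# Decorated-core templates per functional class.  "{X}" is replaced by a
# small substituent; all pure-hydrocarbon or single-function designs so a
# product's poised bonds come only from the reaction that made it.
_SUBSTITUENTS = ["", "C", "CC", "F", "Cl", "C(C)C"]

_CLASS_TEMPLATES = {
    "amine": [
        "NCc1ccc({X})cc1", "NCc1cccc({X})c1", "Nc1ccc({X})cc1",
        "NCC1CCC1", "NC1CCCC1", "NCCC1CCCCC1", "NCCc1ccc({X})cc1",
    ],
    "acyl-halide": [
        "O=C(Cl)c1ccc({X})cc1", "CC(=O)Cl", "CCC(=O)Cl", "CC(C)C(=O)Cl",
        "O=C(Cl)C1CC1", "O=C(Cl)C1CCCC1", "O=C(Cl)Cc1ccc({X})cc1",
    ],
    "sulfonyl-halide": [
        "O=S(=O)(Cl)c1ccc({X})cc1", "CS(=O)(=O)Cl", "CCS(=O)(=O)Cl",
        "O=S(=O)(Cl)C1CCC1",
    ],
    "phenol": ["Oc1ccc({X})cc1", "Oc1cccc({X})c1", "Oc1ccc({X})cn1"],
    "alkyl-halide": ["BrCC{X}C", "BrCCC1CCC1", "BrCc1ccc({X})cc1", "BrC"],
    "aldehyde": ["O=Cc1ccc({X})cc1", "O=CCC{X}C", "O=CC1CCC1"],
    "aryl-bromide": ["Brc1ccc({X})cc1", "Brc1cccc({X})c1", "Brc1ccc({X})cn1"],
    "arylboronic-acid": ["OB(O)c1ccc({X})cc1", "OB(O)c1cccc({X})c1"],
    "aryl-fluoride": ["Fc1ccc({X})cn1", "Fc1ncc({X})cn1"],
    "terminal-alkyne": ["C#CC{X}C", "C#CC1CCC1", "C#CCC1CCCCC1"],
    "thioamide": ["CC(N)=S", "CCC(N)=S", "NC(=S)C1CC1", "NC(=S)c1ccc({X})cc1"],
    "thiourea": ["NC(N)=S"],
    "alpha-bromoketone": ["CC(=O)CBr", "O=C(CBr)c1ccc({X})cc1", "O=C(CBr)C1CCC1"],
    "hydrazine": ["NN"],
    "1,3-diketone": ["CC(=O)CC(C)=O", "CC(=O)CC(=O)c1ccc({X})cc1"],
    "1,4-diketone": ["CC(=O)CCC(C)=O"],
    "azide": ["CCN=[N+]=[N-]", "[N-]=[N+]=NCc1ccc({X})cc1", "[N-]=[N+]=NC1CCC1"],
    "amidoxime": ["CC(N)=NO", "ON=C(N)c1ccc({X})cc1"],
    "amidine": ["CC(=N)N", "N=C(N)c1ccc({X})cc1"],
    "nitrile": ["CC#N", "N#Cc1ccc({X})cc1", "N#CCC1CCC1"],
    "ortho-diamine": ["Nc1ccc({X})cc1N", "Nc1ccccc1N"],
    "ortho-aminophenol": ["Nc1ccc({X})cc1O", "Nc1ccccc1O"],
    "ortho-aminothiophenol": ["Nc1ccc({X})cc1S", "Nc1ccccc1S"],
}

_DECOYS = [
    "Cc1ccc({X})cc1", "CCc1cccc({X})c1", "C{X}C1CCCCC1", "Cc1ccc2ccccc2c1",
    "C1CCC2CCCCC2C1", "CC(C)Cc1ccc({X})cc1", "C1CCCCCC1", "CCC{X}CC",
]


def _expand_pool(templates, rng, size) -> list:
    """Expand templates x substituents into up to `size` unique SMILES."""
    combos = []
    for tpl in templates:
        if "{X}" in tpl:
            for x in _SUBSTITUENTS:
                s = tpl.replace("({X})", f"({x})" if x else "")
                combos.append(s.replace("{X}", x))
        else:
            combos.append(tpl)
    uniq = []
    seen = set()
    for smi in combos:
        try:
            c = canonical_smiles(smi)
        except SmilesError:
            continue
        if c not in seen:
            seen.add(c)
            uniq.append(c)
    idx = rng.permutation(len(uniq))[: size]
    return [uniq[i] for i in sorted(idx)]


def generate_synthetic_catalog(
    spec: SyntheticCatalogSpec, library=None
) -> GeneratedCatalog:
    """Forward-synthesize a labelled catalog per the composition recipe.

    Deterministic for a fixed spec (all randomness flows from ``spec.seed``).
    """
    library = library if library is not None else builtin_reaction_library()
    rng = np.random.default_rng(spec.seed)
    for name in spec.composition:
        get_reaction(library, name)  # KeyError -> infeasible composition

    pools = {}

    def pool(cls: str) -> list:
        if cls not in pools:
            if cls not in _CLASS_TEMPLATES:
                raise ValueError(f"no synthon templates for class {cls!r}")
            pools[cls] = _expand_pool(_CLASS_TEMPLATES[cls], rng, spec.pool_size)
        return pools[cls]

    names = sorted(spec.composition) + ["__decoy__"]
    probs = [spec.composition[n] for n in sorted(spec.composition)] + [
        spec.decoy_fraction
    ]
    decoy_pool = _expand_pool(_DECOYS, rng, spec.pool_size)

    fragments, label_rows = [], []
    used_synthons = {}
    for i in range(spec.n):
        choice = names[rng.choice(len(names), p=probs)]
        ident = f"syn{i + 1:05d}"
        if choice == "__decoy__":
            smi = decoy_pool[rng.integers(len(decoy_pool))]
            fragments.append(FragmentRecord.from_smiles(ident, smi, source="decoy"))
            label_rows.append({"id": ident, "reaction": ""})
            continue
        reaction = get_reaction(library, choice)
        product = None
        for _ in range(20):  # resample on role mismatch
            picks = [pool(cls)[rng.integers(len(pool(cls)))]
                     for cls in reaction.synthon_classes]
            product = forward_synthesize(choice, picks, library)
            if product is not None:
                break
        if product is None:
            raise RuntimeError(
                f"could not synthesize a {choice} product after 20 attempts"
            )
        for cls, smi in zip(reaction.synthon_classes, picks):
            used_synthons.setdefault((cls, smi), None)
        fragments.append(FragmentRecord.from_smiles(ident, product, source=choice))
        label_rows.append({"id": ident, "reaction": choice})

    synthons = [
        SynthonRecord(id=f"bb{j + 1:04d}", smiles=smi, functional_class=cls)
        for j, (cls, smi) in enumerate(sorted(used_synthons))
    ]
    labels = pd.DataFrame(label_rows, columns=["id", "reaction"])
    return GeneratedCatalog(fragments=fragments, labels=labels, synthons=synthons)
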