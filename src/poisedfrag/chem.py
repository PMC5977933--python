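"""Shared low-level chemistry helpers.

One canonical-SMILES dialect (RDKit default canonicalization) is fixed
package-wide and applied at ingest; all structure-equality tests in the
package compare canonical forms.  Stereochemistry is stripped on ingest
because the poised-bond chemistry handled here is achiral; the loss is
surfaced as a warning by the catalog readers.
"""

from __future__ import annotations

import warnings

from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator
from rdkit.Chem import rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

#: Elements tolerated in drug-like fragments (plus implicit H).
ALLOWED_ELEMENTS = frozenset(
    ["H", "C", "N", "O", "S", "F", "Cl", "Br", "I", "B"]
)

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


class SmilesError(ValueError):
    """Raised when a SMILES string does not parse."""


def mol_from_smiles(smiles: str, strip_stereo: bool = True) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`SmilesError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    if strip_stereo:
        if any(b.GetStereo() != Chem.BondStereo.STEREONONE for b in mol.GetBonds()) or any(
            a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED for a in mol.GetAtoms()
        ):
            warnings.warn(
                f"stereochemistry stripped on ingest: {smiles!r}", stacklevel=2
            )
        Chem.RemoveStereochemistry(mol)
    return mol


def canonical_smiles(smiles: str, strip_stereo: bool = True) -> str:
    """Canonicalize a SMILES string (package-wide dialect)."""
    return Chem.MolToSmiles(mol_from_smiles(smiles, strip_stereo=strip_stereo))


def canonical_smiles_of_mol(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def heavy_atom_count(smiles: str) -> int:
    return mol_from_smiles(smiles).GetNumHeavyAtoms()


def compute_properties(mol: Chem.Mol) -> dict:
    """Physicochemical profile used by the fragment-likeness filters."""
    return {
        "mw": round(Descriptors.MolWt(mol), 2),
        "heavy_atoms": mol.GetNumHeavyAtoms(),
        "clogp": round(Crippen.MolLogP(mol), 3),
        "hbd": Lipinski.NumHDonors(mol),
        "hba": Lipinski.NumHAcceptors(mol),
        "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds(mol),
        "rings": rdMolDescriptors.CalcNumRings(mol),
    }


def morgan_fp(mol: Chem.Mol):
    """Circular (Morgan) fingerprint, radius 2, 2048 bits."""
    return _MORGAN.GetFingerprint(mol)


def morgan_fp_from_smiles(smiles: str):
    return morgan_fp(mol_from_smiles(smiles))


def tanimoto(fp_a, fp_b) -> float:
    return DataStructs.TanimotoSimilarity(fp_a, fp_b)


def tanimoto_smiles(a: str, b: str) -> float:
    return tanimoto(morgan_fp_from_smiles(a), morgan_fp_from_smiles(b))
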