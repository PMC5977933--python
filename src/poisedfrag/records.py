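"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .chem import canonical_smiles, compute_properties, mol_from_smiles


@dataclass(frozen=True)
class FragmentRecord:
    """One catalog molecule with its computed physchem properties.

    Properties are deterministic functions of the canonical SMILES; use
    :meth:`from_smiles` so they can never drift out of sync.
    """

    id: str
    smiles: str
    mw: float
    heavy_atoms: int
    clogp: float
    hbd: int
    hba: int
    rotatable_bonds: int
    rings: int
    source: str = ""

    @classmethod
    def from_smiles(cls, id: str, smiles: str, source: str = "") -> "FragmentRecord":
        mol = mol_from_smiles(smiles)
        props = compute_properties(mol)
        from rdkit import Chem

        return cls(id=id, smiles=Chem.MolToSmiles(mol), source=source, **props)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SynthonRecord:
    """One building block in a vendor-style synthon catalog."""

    id: str
    smiles: str
    functional_class: str
    available: bool = True

    def __post_init__(self):
        if not self.functional_class:
            raise ValueError(f"synthon {self.id!r}: empty functional_class")
        object.__setattr__(self, "smiles", canonical_smiles(self.smiles))


@dataclass(frozen=True)
class PoisedAnnotation:
    """One (fragment, reaction, matched substructure) poised assignment."""

    fragment_id: str
    reaction_name: str
    matched_atoms: tuple
    synthons: tuple  # canonical SMILES, one per synthon role

    def __post_init__(self):
        if not self.synthons:
            raise ValueError("annotation with empty synthon list")
        object.__setattr__(self, "matched_atoms", tuple(self.matched_atoms))
        object.__setattr__(self, "synthons", tuple(self.synthons))
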