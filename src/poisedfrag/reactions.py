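"""The curated poised-reaction library and its forward/retro transform engine.

A fragment is *poised* when it can be made in one step by a robust, general
reaction from commercially common building blocks, so that a screening hit
can be elaborated by parallel synthesis with analogues of its synthons.  The
built-in roster holds 21 reactions: 8 bond-linking couplings drawn from the
most-used medicinal-chemistry reactions (amide coupling, sulfonamide
formation, reductive amination, Suzuki biaryl coupling, Sonogashira
coupling, aryl ether alkylation, SNAr/Buchwald-type aryl amination and
thiourea formation) and 13 robust heterocycle-forming reactions
(benzimidazole/benzoxazole/benzothiazole condensations, Hantzsch thiazoles,
Knorr pyrazoles, azide-alkyne triazoles, Paal-Knorr pyrroles,
1,2,4-oxadiazoles, tetrazoles, Pinner pyrimidines, Van Leusen oxazoles and
the 5-aminooxazole-4-carbonitrile route from aminomalononitrile).

Each definition carries a *retro* reaction SMARTS (product substructure ->
synthons, with the leaving groups a purchasing chemist expects: acyl
chlorides for amides, sulfonyl chlorides for sulfonamides, boronic acid +
aryl bromide for biaryls, phenol + alkyl bromide for ethers) and a *forward*
reaction SMARTS that rebuilds the product from those synthons.  Forward
applied to the retro output regenerates the input molecule - the round-trip
identity every definition must satisfy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import SmilesError, mol_from_smiles
from .records import FragmentRecord, PoisedAnnotation

LINKING = "linking"
HETEROCYCLE = "heterocycle"


class ReactionDefinitionError(ValueError):
    """A reaction definition is malformed (bad SMARTS, duplicate name...)."""


@dataclass(frozen=True)
class ReactionDefinition:
    """One poised reaction: category, transforms, roles, incompatibilities."""

    name: str
    category: str
    retro_transform: str
    forward_transform: str
    synthon_classes: tuple
    incompatibility_patterns: tuple = ()  # of {"smarts":..., "reason":...}
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "synthon_classes", tuple(self.synthon_classes))
        object.__setattr__(
            self,
            "incompatibility_patterns",
            tuple(dict(p) for p in self.incompatibility_patterns),
        )
        if self.category not in (LINKING, HETEROCYCLE):
            raise ReactionDefinitionError(
                f"{self.name}: unknown category {self.category!r}"
            )
        minimum = 2 if self.category == LINKING else 1
        if len(self.synthon_classes) < minimum:
            raise ReactionDefinitionError(
                f"{self.name}: {self.category} reactions need >= {minimum} synthon roles"
            )
        # fail early on malformed SMARTS
        for label, smarts in (
            ("retro", self.retro_transform),
            ("forward", self.forward_transform),
        ):
            try:
                rxn = AllChem.ReactionFromSmarts(smarts)
            except Exception as exc:  # rdkit raises bare ValueError
                raise ReactionDefinitionError(
                    f"{self.name}: malformed {label} SMARTS: {exc}"
                ) from exc
            if rxn is None:
                raise ReactionDefinitionError(f"{self.name}: malformed {label} SMARTS")
        if self.retro_rxn.GetNumProductTemplates() != len(self.synthon_classes):
            raise ReactionDefinitionError(
                f"{self.name}: retro transform emits "
                f"{self.retro_rxn.GetNumProductTemplates()} synthons but "
                f"{len(self.synthon_classes)} roles are declared"
            )
        if self.forward_rxn.GetNumReactantTemplates() != len(self.synthon_classes):
            raise ReactionDefinitionError(
                f"{self.name}: forward transform takes "
                f"{self.forward_rxn.GetNumReactantTemplates()} synthons but "
                f"{len(self.synthon_classes)} roles are declared"
            )
        for pat in self.incompatibility_patterns:
            if Chem.MolFromSmarts(pat["smarts"]) is None:
                raise ReactionDefinitionError(
                    f"{self.name}: malformed incompatibility SMARTS {pat['smarts']!r}"
                )

    @property
    def retro_rxn(self):
        return _rxn_from_smarts(self.retro_transform)

    @property
    def forward_rxn(self):
        return _rxn_from_smarts(self.forward_transform)

    @property
    def product_pattern(self):
        """Query molecule for the poised-product substructure."""
        return _patt_from_smarts(self.retro_transform.split(">>")[0])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "category": self.category,
            "retro_transform": self.retro_transform,
            "forward_transform": self.forward_transform,
            "synthon_classes": list(self.synthon_classes),
            "incompatibility_patterns": [dict(p) for p in self.incompatibility_patterns],
            "provenance": self.provenance,
        }


@lru_cache(maxsize=256)
def _rxn_from_smarts(smarts: str):
    rxn = AllChem.ReactionFromSmarts(smarts)
    rxn.Initialize()
    return rxn


@lru_cache(maxsize=256)
def _patt_from_smarts(smarts: str):
    return Chem.MolFromSmarts(smarts)


# --------------------------------------------------------------------------
# Built-in roster.
#
# Shared incompatibility vocabularies: a fragment poised for an acylation
# must not carry a second free amine (an asymmetric diamine synthon would
# give a mixture of products); fragments whose synthons include an amine
# must not carry free acylating groups or aldehydes; cross-coupling
# substrates must not carry a second aryl halide.
# --------------------------------------------------------------------------

_FREE_AMINE = {
    "smarts": "[NX3;H2,H1;!$(N[C,S]=[O,S,N]);!$(N=*);!$(N(S(=O)=O))]",
    "reason": "cross-reactive amine",
}
_FREE_ACYL = {
    "smarts": "[CX3](=[OX1])[OX2H1,Cl,Br]",
    "reason": "cross-reactive acid/acyl halide",
}
_ALDEHYDE = {"smarts": "[CX3;H1]=[OX1]", "reason": "cross-reactive aldehyde"}
_ARYL_HALIDE = {"smarts": "[c][Cl,Br,I]", "reason": "cross-reactive aryl halide"}
_ALKYL_HALIDE = {"smarts": "[CX4][Br,I]", "reason": "cross-reactive alkyl halide"}

_ACYLATION = (_FREE_AMINE, _FREE_ACYL, _ALDEHYDE)
_AMINATION = (_FREE_AMINE, _FREE_ACYL, _ALDEHYDE)

_AMINE_FWD = "[NX3;H3,H2,H1;!$(N[C,S]=[O,S,N]);!$(N=*):{m}]"

_BUILTIN_SPECS = [
    # ---- linking ----
    dict(
        name="amide",
        category=LINKING,
        retro_transform=(
            "[#6:4][C:1](=[O:2])!@[NX3;!$(N(C=O)C=O);!$(N(C=O)S(=O)=O):3]"
            ">>[#6:4][C:1](=[O:2])Cl.[N:3]"
        ),
        forward_transform=(
            "[#6:4][CX3:1](=[O:2])[Cl]." + _AMINE_FWD.format(m=3)
            + ">>[#6:4][C:1](=[O:2])[N:3]"
        ),
        synthon_classes=("acyl-halide", "amine"),
        incompatibility_patterns=_ACYLATION,
        provenance="amine acylation with acid chlorides; the canonical poised bond",
    ),
    dict(
        name="sulfonamide",
        category=LINKING,
        retro_transform=(
            "[#6:4][S:1](=[O:2])(=[O:3])!@[NX3;!$(N(S(=O)=O)S(=O)=O):5]"
            ">>[#6:4][S:1](=[O:2])(=[O:3])Cl.[N:5]"
        ),
        forward_transform=(
            "[#6:4][S:1](=[O:2])(=[O:3])[Cl]." + _AMINE_FWD.format(m=5)
            + ">>[#6:4][S:1](=[O:2])(=[O:3])[N:5]"
        ),
        synthon_classes=("sulfonyl-halide", "amine"),
        incompatibility_patterns=_ACYLATION,
        provenance="sulfonylation of amines with sulfonyl chlorides",
    ),
    dict(
        name="reductive_amination",
        category=LINKING,
        retro_transform=(
            "[NX3;!$(N[C,S]=[O,S,N]);!$(N=*);!$(N[O,N]);!$(Nc):1]!@[CH2:2][#6:3]"
            ">>[N:1].[#6:3][CH1:2]=O"
        ),
        forward_transform=(
            "[NX3;H3,H2,H1;!$(N[C,S]=[O,S,N]);!$(N=*);!$(N[O,N]);!$(Nc):1]."
            "[#6:3][CH1:2]=[OX1]>>[N:1][CH2:2][#6:3]"
        ),
        synthon_classes=("amine", "aldehyde"),
        incompatibility_patterns=_AMINATION,
        provenance="reductive amination of aldehydes",
    ),
    dict(
        name="suzuki",
        category=LINKING,
        retro_transform="[c:1]!@[c:2]>>[c:1]B(O)O.[c:2]Br",
        forward_transform="[c:1][B]([OH])[OH].[c:2][Br]>>[c:1][c:2]",
        synthon_classes=("arylboronic-acid", "aryl-bromide"),
        incompatibility_patterns=(_ARYL_HALIDE,),
        provenance="Suzuki-Miyaura biaryl cross-coupling",
    ),
    dict(
        name="sonogashira",
        category=LINKING,
        retro_transform=(
            "[c:1]!@[C:2]#[C:3][#6:4]>>[c:1]Br.[CH1:2]#[C:3][#6:4]"
        ),
        forward_transform=(
            "[c:1][Br].[CX2;H1:2]#[C:3][#6:4]>>[c:1][C:2]#[C:3][#6:4]"
        ),
        synthon_classes=("aryl-bromide", "terminal-alkyne"),
        incompatibility_patterns=(_ARYL_HALIDE,),
        provenance="Sonogashira aryl-alkyne coupling",
    ),
    dict(
        name="ether",
        category=LINKING,
        retro_transform=(
            "[c:1][OX2;!$(OC=O):2]!@[CX4;H2,H3;!$(C([OX2])[#7,#8,#16,F,Cl,Br,I]):3]"
            ">>[c:1][O:2].[C:3]Br"
        ),
        forward_transform=(
            "[c:1][OX2;H1:2].[CX4;H2,H3;!$(C([Br])[#7,#8,#16,F,Cl,Br,I]):3][Br]"
            ">>[c:1][O:2][C:3]"
        ),
        synthon_classes=("phenol", "alkyl-halide"),
        incompatibility_patterns=(_ALKYL_HALIDE, _FREE_ACYL),
        provenance=(
            "Williamson O-alkylation of phenols; methyl and primary alkyl aryl "
            "ethers both count as poised, ester O-C bonds are excluded"
        ),
    ),
    dict(
        name="snar_amination",
        category=LINKING,
        retro_transform=(
            "[c:1]!@[NX3;H0,H1;$(N(c)[#6]);!$(N(c)c);"
            "!$(N[C,S]=[O,S,N]);!$(N=*):2]>>[c:1]F.[N:2]"
        ),
        forward_transform=(
            "[c:1][F].[NX3;H2,H1;!$(N[C,S]=[O,S,N]);!$(N=*);!$(Nc):2]>>[c:1][N:2]"
        ),
        synthon_classes=("aryl-fluoride", "amine"),
        incompatibility_patterns=(_FREE_ACYL, _ALDEHYDE),
        provenance="SNAr / Buchwald-type aryl amination",
    ),
    dict(
        name="thiourea",
        category=LINKING,
        retro_transform=(
            "[NX3;!$(N(C=S)C=O):1]!@[C:2](=[S:3])!@[NX3:4]>>[N:1].[N:4]"
        ),
        forward_transform=(
            _AMINE_FWD.format(m=1) + "." + _AMINE_FWD.format(m=4)
            + ">>[N:1][C](=[S])[N:4]"
        ),
        synthon_classes=("amine", "amine"),
        incompatibility_patterns=(_FREE_ACYL, _ALDEHYDE),
        provenance=(
            "sequential amine addition to thiocarbonyldiimidazole (thio-CDI); "
            "the thiocarbonyl comes from the reagent, both synthons are amines"
        ),
    ),
    # ---- heterocycle-forming ----
    dict(
        name="benzimidazole",
        category=HETEROCYCLE,
        retro_transform=(
            "[#6:6]-[c:1]1[n;H1:2][c:3]2[c:7][c:8][c:9][c:10][c:4]2[n:5]1"
            ">>[#6:6][C:1](=O)Cl.[NH2:2][c:3]1[c:7][c:8][c:9][c:10][c:4]1[NH2:5]"
        ),
        forward_transform=(
            "[#6:6][C:1](=[OX1])[Cl].[NX3;H2:2][c:3]1[c:7][c:8][c:9][c:10][c:4]1[NX3;H2:5]"
            ">>[#6:6]-[c:1]1[n;H1:2][c:3]2[c:7][c:8][c:9][c:10][c:4]2[n:5]1"
        ),
        synthon_classes=("acyl-halide", "ortho-diamine"),
        incompatibility_patterns=_ACYLATION,
        provenance="2-substituted benzimidazole from benzene-1,2-diamine + acyl chloride",
    ),
    dict(
        name="benzoxazole",
        category=HETEROCYCLE,
        retro_transform=(
            "[#6:6]-[c:1]1[o:2][c:3]2[c:7][c:8][c:9][c:10][c:4]2[n:5]1"
            ">>[#6:6][C:1](=O)Cl.[OH:2][c:3]1[c:7][c:8][c:9][c:10][c:4]1[NH2:5]"
        ),
        forward_transform=(
            "[#6:6][C:1](=[OX1])[Cl].[OX2;H1:2][c:3]1[c:7][c:8][c:9][c:10][c:4]1[NX3;H2:5]"
            ">>[#6:6]-[c:1]1[o:2][c:3]2[c:7][c:8][c:9][c:10][c:4]2[n:5]1"
        ),
        synthon_classes=("acyl-halide", "ortho-aminophenol"),
        incompatibility_patterns=_ACYLATION,
        provenance="2-substituted benzoxazole from 2-aminophenol + acyl chloride",
    ),
    dict(
        name="benzothiazole",
        category=HETEROCYCLE,
        retro_transform=(
            "[#6:6]-[c:1]1[s:2][c:3]2[c:7][c:8][c:9][c:10][c:4]2[n:5]1"
            ">>[#6:6][C:1](=O)Cl.[SH:2][c:3]1[c:7][c:8][c:9][c:10][c:4]1[NH2:5]"
        ),
        forward_transform=(
            "[#6:6][C:1](=[OX1])[Cl].[SX2;H1:2][c:3]1[c:7][c:8][c:9][c:10][c:4]1[NX3;H2:5]"
            ">>[#6:6]-[c:1]1[s:2][c:3]2[c:7][c:8][c:9][c:10][c:4]2[n:5]1"
        ),
        synthon_classes=("acyl-halide", "ortho-aminothiophenol"),
        incompatibility_patterns=_ACYLATION,
        provenance="2-substituted benzothiazole from 2-aminothiophenol + acyl chloride",
    ),
    dict(
        name="thiazole_hantzsch",
        category=HETEROCYCLE,
        retro_transform=(
            "[#6:6]-[c:1]1[n:2][c:3](-[#6:7])[c:4][s:5]1"
            ">>[#6:6][C:1](=[S:5])[N:2].[#6:7][C:3](=O)[C:4]Br"
        ),
        forward_transform=(
            "[#6:6][C:1](=[SX1:5])[NX3;H2:2].[#6:7][C:3](=[OX1])[CX4;H2:4][Br]"
            ">>[#6:6]-[c:1]1[n:2][c:3](-[#6:7])[c:4][s:5]1"
        ),
        synthon_classes=("thioamide", "alpha-bromoketone"),
        incompatibility_patterns=(_FREE_AMINE, _ALKYL_HALIDE),
        provenance="Hantzsch thiazole from thioamide + alpha-bromoketone",
    ),
    dict(
        name="aminothiazole",
        category=HETEROCYCLE,
        retro_transform=(
            "[NX3;H2:6]-[c:1]1[n:2][c:3](-[#6:7])[c:4][s:5]1"
            ">>[N:6][C:1](=[S:5])[N:2].[#6:7][C:3](=O)[C:4]Br"
        ),
        forward_transform=(
            "[NX3;H2:6][C:1](=[SX1:5])[NX3;H2:2].[#6:7][C:3](=[OX1])[CX4;H2:4][Br]"
            ">>[N:6]-[c:1]1[n:2][c:3](-[#6:7])[c:4][s:5]1"
        ),
        synthon_classes=("thiourea", "alpha-bromoketone"),
        incompatibility_patterns=(_ALKYL_HALIDE,),
        provenance="Hantzsch 2-aminothiazole from thiourea + alpha-bromoketone",
    ),
    dict(
        name="pyrazole",
        category=HETEROCYCLE,
        retro_transform=(
            "[#6:6]-[c:1]1[cH:2][c:3](-[#6:7])[n;H1:4][n:5]1"
            ">>[#6:6][C:1](=O)[CH2:2][C:3](=O)[#6:7].[NH2:4][NH2:5]"
        ),
        forward_transform=(
            "[#6:6][C:1](=[OX1])[CX4;H2:2][C:3](=[OX1])[#6:7].[NX3;H2:4][NX3;H2:5]"
            ">>[#6:6]-[c:1]1[cH:2][c:3](-[#6:7])[n;H1:4][n:5]1"
        ),
        synthon_classes=("1,3-diketone", "hydrazine"),
        incompatibility_patterns=(_FREE_ACYL, _ALDEHYDE),
        provenance="Knorr pyrazole from 1,3-diketone + hydrazine",
    ),
    dict(
        name="triazole_click",
        category=HETEROCYCLE,
        retro_transform=(
            "[#6:6]-[n:1]1[cH:2][c:3](-[#6:7])[n:4][n:5]1"
            ">>[#6:6][N:1]=[N+1:5]=[N-1:4].[#6:7][C:3]#[CH1:2]"
        ),
        forward_transform=(
            "[#6:6][NX2:1]=[N+1:5]=[N-1:4].[#6:7][CX2:3]#[CX2;H1:2]"
            ">>[#6:6]-[n:1]1[cH:2][c:3](-[#6:7])[n+0:4][n+0:5]1"
        ),
        synthon_classes=("azide", "terminal-alkyne"),
        incompatibility_patterns=(_ALKYL_HALIDE,),
        provenance="Cu-catalysed azide-alkyne cycloaddition, 1,4-regiochemistry",
    ),
    dict(
        name="pyrrole_paal_knorr",
        category=HETEROCYCLE,
        retro_transform=(
            "[#6:8]-[n:1]1[c:2](-[#6:6])[cH:3][cH:4][c:5]1-[#6:7]"
            ">>[#6:8][NH2:1].[#6:6][C:2](=O)[CH2:3][CH2:4][C:5](=O)[#6:7]"
        ),
        forward_transform=(
            "[#6:8][NX3;H2:1].[#6:6][C:2](=[OX1])[CX4;H2:3][CX4;H2:4][C:5](=[OX1])[#6:7]"
            ">>[#6:8]-[n:1]1[c:2](-[#6:6])[cH:3][cH:4][c:5]1-[#6:7]"
        ),
        synthon_classes=("amine", "1,4-diketone"),
        incompatibility_patterns=(_FREE_ACYL, _ALDEHYDE),
        provenance="Paal-Knorr pyrrole from primary amine + 1,4-diketone",
    ),
    dict(
        name="oxadiazole_124",
        category=HETEROCYCLE,
        retro_transform=(
            "[#6:6]-[c:1]1[n:2][o:3][c:4](-[#6:7])[n:5]1"
            ">>[#6:6][C:1](=[N:2][OH:3])[NH2:5].[#6:7][C:4](=O)Cl"
        ),
        forward_transform=(
            "[#6:6][C:1](=[NX2:2][OX2;H1:3])[NX3;H2:5].[#6:7][C:4](=[OX1])[Cl]"
            ">>[#6:6]-[c:1]1[n:2][o:3][c:4](-[#6:7])[n:5]1"
        ),
        synthon_classes=("amidoxime", "acyl-halide"),
        incompatibility_patterns=(_FREE_AMINE,),
        provenance="1,2,4-oxadiazole from amidoxime + acyl chloride",
    ),
    dict(
        name="tetrazole",
        category=HETEROCYCLE,
        retro_transform=(
            "[#6:6]-[c:1]1[n;H1:2][n:3][n:4][n:5]1>>[#6:6][C:1]#[N:2]"
        ),
        forward_transform=(
            "[#6:6][CX2:1]#[NX1:2]>>[#6:6]-[c:1]1[n;H1:2][n][n][n]1"
        ),
        synthon_classes=("nitrile",),
        incompatibility_patterns=(),
        provenance="5-substituted 1H-tetrazole from nitrile + azide reagent",
    ),
    dict(
        name="pyrimidine",
        category=HETEROCYCLE,
        retro_transform=(
            "[#6:6]-[c:1]1[n:2][c:3](-[#6:7])[cH:4][c:5](-[#6:8])[n:9]1"
            ">>[#6:6][C:1](=[NH:2])[NH2:9].[#6:7][C:3](=O)[CH2:4][C:5](=O)[#6:8]"
        ),
        forward_transform=(
            "[#6:6][C:1](=[NX2;H1:2])[NX3;H2:9].[#6:7][C:3](=[OX1])[CX4;H2:4][C:5](=[OX1])[#6:8]"
            ">>[#6:6]-[c:1]1[n:2][c:3](-[#6:7])[cH:4][c:5](-[#6:8])[n:9]1"
        ),
        synthon_classes=("amidine", "1,3-diketone"),
        incompatibility_patterns=(_FREE_ACYL, _ALDEHYDE),
        provenance="Pinner pyrimidine from amidine + 1,3-diketone",
    ),
    dict(
        name="oxazole_van_leusen",
        category=HETEROCYCLE,
        retro_transform=(
            "[#6:6]-[c:1]1[o:2][cH:3][n:4][cH:5]1>>[#6:6][CH1:1]=[O:2]"
        ),
        forward_transform=(
            "[#6:6][CX3;H1:1]=[OX1:2]>>[#6:6]-[c:1]1[o:2][cH][n][cH]1"
        ),
        synthon_classes=("aldehyde",),
        incompatibility_patterns=(_FREE_AMINE,),
        provenance="Van Leusen 5-substituted oxazole from aldehyde + TosMIC reagent",
    ),
    dict(
        name="aminooxazole_carbonitrile",
        category=HETEROCYCLE,
        retro_transform=(
            "[NX3;H2:6]-[c:1]1[o:2][c:3](-[#6:7])[n:4][c:5]1[C:8]#[N:9]"
            ">>[#6:7][C:3](=[O:2])Cl"
        ),
        forward_transform=(
            "[#6:7][C:3](=[OX1:2])[Cl]>>[N;H2]-[c]1[o:2][c:3](-[#6:7])[n][c]1-C#N"
        ),
        synthon_classes=("acyl-halide",),
        incompatibility_patterns=(_FREE_AMINE,),
        provenance=(
            "5-amino-2-substituted-oxazole-4-carbonitrile from acyl chloride + "
            "aminomalononitrile tosylate"
        ),
    ),
]


def builtin_reaction_library() -> list:
    """The 21 built-in poised-reaction definitions (8 linking + 13 heterocycle)."""
    return [ReactionDefinition(**spec) for spec in _BUILTIN_SPECS]


def load_reaction_library(config_path: Optional[str] = None) -> list:
    """Load reaction definitions from a JSON file, or the built-in roster.

    The file holds a JSON list of records with the fields of
    :class:`ReactionDefinition`.  Malformed SMARTS raise a
    :class:`ReactionDefinitionError` naming the reaction; duplicate names are
    a load error.
    """
    if config_path is None:
        defs = builtin_reaction_library()
    else:
        with open(config_path) as fh:
            raw = json.load(fh)
        defs = [ReactionDefinition(**record) for record in raw]
    names = [d.name for d in defs]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ReactionDefinitionError(f"duplicate reaction names: {dupes}")
    return defs


def export_reaction_library(library: Sequence[ReactionDefinition], path: str) -> None:
    """Write a reaction library in the same JSON format ``load`` reads."""
    with open(path, "w") as fh:
        json.dump([d.to_dict() for d in library], fh, indent=1)
        fh.write("\n")


def get_reaction(library: Iterable[ReactionDefinition], name: str) -> ReactionDefinition:
    for d in library:
        if d.name == name:
            return d
    raise KeyError(f"unknown reaction {name!r}")


# --------------------------------------------------------------------------
# Transform engine
# --------------------------------------------------------------------------

def _as_mol(fragment) -> tuple:
    """Accept a FragmentRecord or a bare SMILES; return (id, mol)."""
    if isinstance(fragment, FragmentRecord):
        frag_id, smiles = fragment.id, fragment.smiles
    else:
        frag_id, smiles = str(fragment), str(fragment)
    try:
        mol = mol_from_smiles(smiles)
    except SmilesError as exc:
        raise SmilesError(f"fragment {frag_id!r}: {exc}") from exc
    return frag_id, mol


def _sanitized_smiles(product) -> Optional[str]:
    try:
        Chem.SanitizeMol(product)
    except Exception:
        return None
    return Chem.MolToSmiles(product)


def _matched_deconstructions(mol, reaction: ReactionDefinition) -> list:
    """Symmetry-unique (matched_atoms, synthons) pairs for one reaction.

    RunReactants enumerates substructure matches in the same order as
    GetSubstructMatches(uniquify=False), so the two can be zipped; matches
    covering the same atom set (query automorphisms, e.g. the two
    orientations of a thiourea) collapse to the first-seen deconstruction.
    """
    matches = mol.GetSubstructMatches(
        reaction.product_pattern, uniquify=False, maxMatches=5000
    )
    if not matches:
        return []
    product_sets = reaction.retro_rxn.RunReactants((mol,), maxProducts=5000)
    out = []
    seen = set()
    for match, pset in zip(matches, product_sets):
        synthons = [_sanitized_smiles(p) for p in pset]
        if any(s is None for s in synthons):
            continue
        key = frozenset(match)
        if key in seen:
            continue
        seen.add(key)
        out.append((tuple(sorted(set(match))), tuple(synthons)))
    out.sort(key=lambda pair: pair[0])
    return out


def classify_poised(fragment, library: Sequence[ReactionDefinition]) -> list:
    """Annotate every poised bond of a fragment against a reaction library.

    Returns one :class:`PoisedAnnotation` per (reaction, symmetry-unique
    substructure match), ordered by reaction name then matched-atom tuple.
    An empty list means the fragment is not poised.
    """
    frag_id, mol = _as_mol(fragment)
    annotations = []
    for reaction in sorted(library, key=lambda d: d.name):
        for atoms, synthons in _matched_deconstructions(mol, reaction):
            annotations.append(
                PoisedAnnotation(
                    fragment_id=frag_id,
                    reaction_name=reaction.name,
                    matched_atoms=atoms,
                    synthons=synthons,
                )
            )
    return annotations


def deconstruct(fragment, reaction_name: str, library: Sequence[ReactionDefinition]) -> list:
    """Break a fragment at its poised bond(s) for one reaction.

    Returns one synthon-set (list of canonical SMILES in role order, with
    the forward reaction's leaving-group convention) per symmetry-unique
    match; an empty list when the fragment does not match.
    """
    _, mol = _as_mol(fragment)
    reaction = get_reaction(library, reaction_name)
    return [list(synthons) for _, synthons in _matched_deconstructions(mol, reaction)]


def forward_products(
    reaction_name: str, synthons: Sequence[str], library: Sequence[ReactionDefinition]
) -> list:
    """All canonical products of the forward transform (sorted, unique)."""
    reaction = get_reaction(library, reaction_name)
    if len(synthons) != len(reaction.synthon_classes):
        raise ValueError(
            f"{reaction_name} takes {len(reaction.synthon_classes)} synthons, "
            f"got {len(synthons)}"
        )
    mols = tuple(mol_from_smiles(s) for s in synthons)
    outputs = reaction.forward_rxn.RunReactants(mols, maxProducts=5000)
    products = set()
    for pset in outputs:
        smi = _sanitized_smiles(pset[0])
        if smi is not None:
            products.add(smi)
    return sorted(products)


def forward_synthesize(
    reaction_name: str, synthons: Sequence[str], library: Sequence[ReactionDefinition]
) -> Optional[str]:
    """Virtually run one poised reaction on a synthon tuple.

    Returns the canonical product SMILES (the lexicographically first when
    the transform admits several regiochemical outcomes), or ``None`` when a
    synthon fails its role pattern.  Pure function: no randomness.
    """
    products = forward_products(reaction_name, synthons, library)
    return products[0] if products else None


def round_trip_ok(
    smiles: str, reaction_name: str, library: Sequence[ReactionDefinition]
) -> bool:
    """Check forward(retro(x)) regenerates x for every retro deconstruction."""
    target = Chem.MolToSmiles(mol_from_smiles(smiles))
    synthon_sets = deconstruct(smiles, reaction_name, library)
    if not synthon_sets:
        return False
    for synthons in synthon_sets:
        if target not in forward_products(reaction_name, synthons, library):
            return False
    return True
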