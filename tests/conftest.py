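import pytest

from poisedfrag import builtin_reaction_library, phip2_compounds
from poisedfrag.followup import phip2_synthon_catalog

# Three hand-built substrates per built-in reaction, used by the
# forward(retro(x)) == x round-trip checks.
ROUND_TRIP_SUBSTRATES = {
    "amide": ["CC(=O)NCc1c(Cl)cccc1Cl", "CC(=O)Nc1ccccc1", "O=C(NC1CC1)c1ccccc1"],
    "sulfonamide": [
        "CS(=O)(=O)NCc1ccccc1",
        "O=S(=O)(NC)c1ccccc1",
        "O=S(=O)(N1CCCC1)c1ccc(F)cc1",
    ],
    "reductive_amination": ["C1CCCCC1NCc1ccccc1", "CCNCC(C)C", "C1CCN(Cc2ccncc2)CC1"],
    "suzuki": ["c1ccc(-c2ccncc2)cc1", "Cc1ccc(-c2ccccc2)cc1", "c1ccc(-c2cccs2)cc1"],
    "sonogashira": ["CCC#Cc1ccccc1", "c1ccc(C#CC2CC2)cc1", "Cc1ccc(C#CCO)cc1"],
    "ether": ["COc1ccccc1", "c1ccc(OCC2CC2)cc1", "CCOc1ccncc1"],
    "snar_amination": [
        "CNc1ccncc1",
        "c1ccc(N2CCCCC2)nc1",
        "CN(C)c1ccc([N+](=O)[O-])cc1",
    ],
    "thiourea": ["Cc1ccccc1NC(N)=S", "CNC(=S)Nc1ccccc1Cl", "S=C(NC1CC1)NCc1ccccc1"],
    "benzimidazole": [
        "Cc1nc2ccccc2[nH]1",
        "c1ccc(-c2nc3ccccc3[nH]2)cc1",
        "Cc1ccc2[nH]c(CC)nc2c1",
    ],
    "benzoxazole": ["Cc1nc2ccccc2o1", "c1ccc(-c2nc3ccccc3o2)cc1", "CCc1nc2ccc(C)cc2o1"],
    "benzothiazole": ["Cc1nc2ccccc2s1", "c1ccc(-c2nc3ccccc3s2)cc1", "CCc1nc2ccc(F)cc2s1"],
    "thiazole_hantzsch": [
        "Cc1nc(-c2ccccc2)cs1",
        "CCc1nc(C)cs1",
        "c1ccc(-c2csc(C3CC3)n2)cc1",
    ],
    "aminothiazole": ["Nc1nc(-c2ccccc2)cs1", "Nc1nc(C)cs1", "Nc1nc(-c2ccc(Cl)cc2)cs1"],
    "pyrazole": ["Cc1cc(C)[nH]n1", "Cc1cc(-c2ccccc2)[nH]n1", "CCc1cc(CC)[nH]n1"],
    "triazole_click": [
        "Cn1cc(-c2ccccc2)nn1",
        "CCn1cc(C3CC3)nn1",
        "c1ccc(Cn2cc(CO)nn2)cc1",
    ],
    "pyrrole_paal_knorr": ["Cc1ccc(C)n1C", "Cc1ccc(C)n1-c1ccccc1", "Cc1ccc(C)n1CC1CC1"],
    "oxadiazole_124": [
        "Cc1noc(C)n1",
        "Cc1noc(-c2ccccc2)n1",
        "c1ccc(-c2noc(C3CC3)n2)cc1",
    ],
    "tetrazole": ["Cc1nnn[nH]1", "c1ccc(-c2nnn[nH]2)cc1", "C(c1ccccc1)c1nnn[nH]1"],
    "pyrimidine": ["Cc1cc(C)nc(C)n1", "Cc1cc(C)nc(-c2ccccc2)n1", "CCc1nc(C)cc(C)n1"],
    "oxazole_van_leusen": ["c1ccc(-c2cnco2)cc1", "CCCc1cnco1", "C1CCCCC1c1cnco1"],
    "aminooxazole_carbonitrile": [
        "Nc1oc(CC(C)C)nc1C#N",
        "Nc1oc(Cc2ccccc2)nc1C#N",
        "Nc1oc(C2CC2)nc1C#N",
    ],
}


@pytest.fixture(scope="session")
def library():
    return builtin_reaction_library()


@pytest.fixture(scope="session")
def reference_compounds():
    return {r.compound_id: r for r in phip2_compounds()}


@pytest.fixture(scope="session")
def fixture_synthons():
    return phip2_synthon_catalog()
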