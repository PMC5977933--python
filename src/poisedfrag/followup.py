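"""One-step follow-up enumeration around a poised hit.

The elaboration loop: deconstruct the hit at its poised bond, rank catalog
synthons of each role's functional class by circular-fingerprint similarity
to the hit's own synthon, and forward-synthesize analogues with one role
varied at a time (the parallel-chemistry setting; double variation is
opt-in).  Products are canonicalized, de-duplicated, stripped of the hit
itself and flagged against the fragment property filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .chem import canonical_smiles, morgan_fp_from_smiles, tanimoto
from .filters import PropertyThresholds, apply_property_filters
from .records import FragmentRecord, SynthonRecord
from .reactions import deconstruct, forward_synthesize, get_reaction

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FollowUpConfig:
    similarity_threshold: float = 0.3
    max_per_role: int = 50
    vary_roles: Optional[tuple] = None  # None = each role in turn
    thresholds: PropertyThresholds = field(default_factory=PropertyThresholds)


@dataclass(frozen=True)
class FollowUpProposal:
    product_smiles: str
    reaction_name: str
    replaced_role: int
    synthon_used: str
    similarity_to_original: float
    passes_filters: bool
    synthons: tuple  # full role-ordered synthon tuple that regenerates product


def propose_analogues(
    hit,
    reaction_name: str,
    synthon_catalog: Sequence[SynthonRecord],
    config: Optional[FollowUpConfig] = None,
    library=None,
) -> list:
    """Enumerate one-step analogues of a poised hit from a synthon catalog.

    For each varied role, catalog synthons of the matching functional class
    are ranked by Morgan-Tanimoto similarity to the hit's own synthon and
    kept above ``similarity_threshold`` (capped at ``max_per_role``); other
    roles stay fixed.  Deterministic ordering: (role, similarity desc, id).
    """
    from .reactions import builtin_reaction_library

    config = config or FollowUpConfig()
    library = library if library is not None else builtin_reaction_library()
    reaction = get_reaction(library, reaction_name)

    hit_smiles = hit.smiles if isinstance(hit, FragmentRecord) else canonical_smiles(hit)
    synthon_sets = deconstruct(hit_smiles, reaction_name, library)
    if not synthon_sets:
        raise ValueError(f"hit is not poised for reaction {reaction_name!r}")
    original = synthon_sets[0]

    roles = (
        tuple(config.vary_roles)
        if config.vary_roles is not None
        else tuple(range(len(reaction.synthon_classes)))
    )
    proposals = []
    seen = {hit_smiles}
    for role in roles:
        cls = reaction.synthon_classes[role]
        candidates = [
            s for s in synthon_catalog if s.available and s.functional_class == cls
        ]
        if not candidates:
            log.warning("no catalog synthons of class %r for role %d", cls, role)
            continue
        ref_fp = morgan_fp_from_smiles(original[role])
        ranked = sorted(
            (
                (tanimoto(ref_fp, morgan_fp_from_smiles(s.smiles)), s)
                for s in candidates
            ),
            key=lambda pair: (-pair[0], pair[1].id),
        )
        kept = [
            (sim, s)
            for sim, s in ranked
            if sim >= config.similarity_threshold
        ][: config.max_per_role]
        for sim, synthon in kept:
            replaced = list(original)
            replaced[role] = synthon.smiles
            product = forward_synthesize(reaction_name, replaced, library)
            if product is None or product in seen:
                continue
            seen.add(product)
            rec = FragmentRecord.from_smiles(f"prop_{len(proposals)}", product)
            passes = not apply_property_filters([rec], config.thresholds).rejected
            proposals.append(
                FollowUpProposal(
                    product_smiles=product,
                    reaction_name=reaction_name,
                    replaced_role=role,
                    synthon_used=synthon.smiles,
                    similarity_to_original=round(sim, 4),
                    passes_filters=passes,
                    synthons=tuple(replaced),
                )
            )
    return proposals


def annotate_with_assay(
    proposals: Sequence[FollowUpProposal], assay_table: pd.DataFrame
) -> pd.DataFrame:
    """Left-join proposals with assay results keyed by canonical SMILES
    (or compound id when no smiles column is present).

    Censored pIC50 bounds stay as (value, censored-flag) pairs; unmatched
    proposals carry empty assay fields.  Duplicate assay keys are an error.
    """
    rows = [
        {
            "product_smiles": p.product_smiles,
            "reaction_name": p.reaction_name,
            "replaced_role": p.replaced_role,
            "synthon_used": p.synthon_used,
            "similarity_to_original": p.similarity_to_original,
            "passes_filters": p.passes_filters,
        }
        for p in proposals
    ]
    left = pd.DataFrame(
        rows,
        columns=[
            "product_smiles",
            "reaction_name",
            "replaced_role",
            "synthon_used",
            "similarity_to_original",
            "passes_filters",
        ],
    )
    if assay_table.empty:
        right = pd.DataFrame(columns=["product_smiles"])
    elif "smiles" in assay_table.columns:
        right = assay_table.copy()
        right["product_smiles"] = [canonical_smiles(s) for s in right["smiles"]]
        right = right.drop(columns=["smiles"])
    elif "compound_id" in assay_table.columns:
        right = assay_table.rename(columns={"compound_id": "product_smiles"})
    else:
        raise ValueError("assay table needs a 'smiles' or 'compound_id' column")
    if not right.empty and right["product_smiles"].duplicated().any():
        dupes = sorted(right.loc[right["product_smiles"].duplicated(), "product_smiles"])
        raise ValueError(f"duplicate assay keys: {dupes}")
    return left.merge(right, on="product_smiles", how="left")


# --------------------------------------------------------------------------
# Fixture synthon catalog for the PHIP(2) reference compounds
# --------------------------------------------------------------------------

_PHIP2_SYNTHONS = [
    # anilines (thiourea role 0 analogues of o-toluidine)
    ("an01", "Cc1ccccc1N", "amine"),
    ("an02", "COc1cccc(N)c1C", "amine"),        # 2-Me-3-OMe
    ("an03", "Cc1cccc(N)c1C", "amine"),         # 2,3-Me2
    ("an04", "Cc1c(N)cccc1C(F)(F)F", "amine"),  # 2-Me-3-CF3
    ("an05", "Cc1c(Cl)cccc1N", "amine"),        # 2-Me-3-Cl
    ("an06", "Cc1cccc(C)c1N", "amine"),         # 2,6-Me2
    ("an07", "Nc1ccccc1Cl", "amine"),           # 2-Cl
    # small amines (thiourea role 1)
    ("am01", "N", "amine"),                     # ammonia equivalent
    ("am02", "CN", "amine"),                    # methylamine
    # benzylamines (amide role 1)
    ("ba01", "NCc1c(Cl)cccc1Cl", "amine"),
    ("ba02", "COc1cccc(OC)c1CN", "amine"),      # 2,6-(OMe)2
    ("ba03", "CNCc1c(Cl)cccc1Cl", "amine"),     # N-methyl
    # acyl chlorides (amide role 0 / oxazole role 0)
    ("ac01", "CC(=O)Cl", "acyl-halide"),
    ("ac02", "OCC(=O)Cl", "acyl-halide"),       # hydroxyacetyl
    ("ac03", "O=C(Cl)Cc1ccccc1", "acyl-halide"),
    ("ac04", "O=C(Cl)Cc1ccc(Cl)cc1", "acyl-halide"),
    ("ac05", "CC(C)CC(=O)Cl", "acyl-halide"),   # isovaleryl
    ("ac06", "CC(C)C(=O)Cl", "acyl-halide"),    # isobutyryl
    ("ac07", "O=C(Cl)C1CC1", "acyl-halide"),    # cyclopropanecarbonyl
    ("ac08", "O=C(Cl)C1CCCCC1", "acyl-halide"), # cyclohexanecarbonyl
]


def phip2_synthon_catalog() -> list:
    """Commercial-analogue synthon catalog around the PHIP(2) hits."""
    return [
        SynthonRecord(id=i, smiles=s, functional_class=c)
        for i, s, c in _PHIP2_SYNTHONS
    ]
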