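"""The filter cascade: drug-like properties, reaction compatibility,
synthon availability.

Property bounds default to Rule-of-Three-flavoured fragment limits
(MW 100-300 Da, cLogP <= 3, HBD <= 3, HBA <= 6, <= 3 rotatable bonds,
7-22 heavy atoms, organic elements only).  Absolute survivor counts always
depend on the catalog snapshot being filtered, so reports carry their own
stage counts rather than promising any historical number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .chem import ALLOWED_ELEMENTS, mol_from_smiles, morgan_fp_from_smiles, tanimoto
from .records import FragmentRecord, PoisedAnnotation, SynthonRecord
from .reactions import ReactionDefinition, get_reaction, _patt_from_smarts

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropertyThresholds:
    """Fragment-likeness bounds; every rule can be relaxed in config."""

    mw_min: float = 100.0
    mw_max: float = 300.0
    clogp_max: float = 3.0
    hbd_max: int = 3
    hba_max: int = 6
    rotatable_max: int = 3
    heavy_min: int = 7
    heavy_max: int = 22
    allowed_elements: frozenset = ALLOWED_ELEMENTS

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allowed_elements"] = sorted(self.allowed_elements)
        return d


@dataclass
class FilterReport:
    """Partition of the input ids into kept and rejected-with-reason."""

    kept: list = field(default_factory=list)
    rejected: list = field(default_factory=list)  # (id, rule, detail)

    @property
    def rejected_ids(self) -> list:
        return [r[0] for r in self.rejected]

    def to_rows(self) -> list:
        rows = [(i, "kept", "", "") for i in self.kept]
        rows += [(i, "rejected", rule, detail) for i, rule, detail in self.rejected]
        return rows


def _first_failing_rule(record: FragmentRecord, t: PropertyThresholds):
    mol = mol_from_smiles(record.smiles)
    bad = sorted(
        {a.GetSymbol() for a in mol.GetAtoms()} - set(t.allowed_elements)
    )
    if bad:
        return "elements", f"disallowed elements {','.join(bad)}"
    checks = [
        ("mw_min", record.mw < t.mw_min, f"MW {record.mw} < {t.mw_min}"),
        ("mw_max", record.mw > t.mw_max, f"MW {record.mw} > {t.mw_max}"),
        ("clogp_max", record.clogp > t.clogp_max, f"cLogP {record.clogp} > {t.clogp_max}"),
        ("hbd_max", record.hbd > t.hbd_max, f"HBD {record.hbd} > {t.hbd_max}"),
        ("hba_max", record.hba > t.hba_max, f"HBA {record.hba} > {t.hba_max}"),
        (
            "rotatable_max",
            record.rotatable_bonds > t.rotatable_max,
            f"rotatable bonds {record.rotatable_bonds} > {t.rotatable_max}",
        ),
        ("heavy_min", record.heavy_atoms < t.heavy_min, f"heavy atoms {record.heavy_atoms} < {t.heavy_min}"),
        ("heavy_max", record.heavy_atoms > t.heavy_max, f"heavy atoms {record.heavy_atoms} > {t.heavy_max}"),
    ]
    for rule, failed, detail in checks:
        if failed:
            return rule, detail
    return None


def apply_property_filters(
    records: Sequence[FragmentRecord], thresholds: Optional[PropertyThresholds] = None
) -> FilterReport:
    """Keep records passing every enabled bound; name the first failing rule."""
    t = thresholds or PropertyThresholds()
    report = FilterReport()
    for rec in records:
        failure = _first_failing_rule(rec, t)
        if failure is None:
            report.kept.append(rec.id)
        else:
            report.rejected.append((rec.id, failure[0], failure[1]))
    return report


def compatibility_filter(
    annotation: PoisedAnnotation,
    fragment: FragmentRecord,
    library: Sequence[ReactionDefinition],
) -> tuple:
    """Reject fragments carrying cross-reactive groups outside the poised bond.

    A poised assignment is only useful when the rest of the molecule would
    survive the reaction: an amide-poised fragment with a second free amine
    would give a product mixture from an asymmetric diamine synthon, so it
    is removed.  Returns ``(True, "")`` or ``(False, reason)``.
    """
    if annotation.fragment_id != fragment.id:
        raise ValueError(
            f"annotation for {annotation.fragment_id!r} checked against "
            f"fragment {fragment.id!r}"
        )
    mol = mol_from_smiles(fragment.smiles)
    inside = set(annotation.matched_atoms)
    reaction = get_reaction(library, annotation.reaction_name)
    for pat in reaction.incompatibility_patterns:
        query = _patt_from_smarts(pat["smarts"])
        for match in mol.GetSubstructMatches(query):
            if not set(match) <= inside:
                return False, pat["reason"]
    return True, ""


def availability_filter(
    annotations: Sequence[PoisedAnnotation],
    synthon_catalog: Sequence[SynthonRecord],
    mode: str = "exact",
    threshold: float = 0.9,
) -> list:
    """Keep annotations whose every synthon has a purchasable catalog match.

    ``exact`` mode requires a canonical-SMILES identity; ``similar`` mode
    accepts a circular-fingerprint Tanimoto >= ``threshold``.  A fragment is
    "available-poised" iff at least one of its annotations survives.
    """
    if mode not in ("exact", "similar"):
        raise ValueError(f"unknown availability mode {mode!r}")
    if mode == "similar" and not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    catalog = [s for s in synthon_catalog if s.available]
    if not catalog:
        log.warning("availability filter: empty synthon catalog, removing all")
        return []
    exact = {s.smiles for s in catalog}
    fps = None
    if mode == "similar":
        fps = [morgan_fp_from_smiles(s.smiles) for s in catalog]

    def has_match(synthon: str) -> bool:
        if synthon in exact:
            return True
        if mode == "similar":
            fp = morgan_fp_from_smiles(synthon)
            return any(tanimoto(fp, other) >= threshold for other in fps)
        return False

    return [a for a in annotations if all(has_match(s) for s in a.synthons)]
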