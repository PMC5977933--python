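"""Library-design orchestration: catalog -> filtered -> poised -> compatible
-> available -> diversity-picked, with per-stage accounting.

Stage counts are always reported for the catalog actually supplied; they
are expected to differ between catalog snapshots, so the report carries its
own provenance (config hash and seeds) and reproduces bit-for-bit when
re-run with them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from .catalog import read_catalog, read_synthon_catalog, write_catalog
from .filters import (
    PropertyThresholds,
    apply_property_filters,
    availability_filter,
    compatibility_filter,
)
from .diversity import select_diverse
from .reactions import builtin_reaction_library, classify_poised, load_reaction_library

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignConfig:
    thresholds: PropertyThresholds = field(default_factory=PropertyThresholds)
    enabled_reactions: Optional[tuple] = None  # None = whole library
    availability_mode: str = "exact"
    availability_threshold: float = 0.9
    k: int = 100
    diversity_metric: str = "fingerprint"
    conformer_seed: int = 7
    selection_seed: int = 7
    reaction_file: Optional[str] = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = self.thresholds.to_dict()
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class DesignReport:
    counts: dict
    composition: dict  # reaction -> % of available-poised compounds
    selected: list
    exhausted_at: Optional[str]
    config_hash: str
    seeds: dict

    def to_dict(self) -> dict:
        return asdict(self)


def composition_stats(annotations, universe: Sequence[str]) -> dict:
    """Per-reaction share of compounds carrying that poised bond, in %.

    A compound counts once per reaction class no matter how many matches it
    has, so fractions can sum past 100% across classes.  Reported to 0.1%.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    per_reaction = {}
    for ann in annotations:
        if ann.fragment_id in set(universe):
            per_reaction.setdefault(ann.reaction_name, set()).add(ann.fragment_id)
    return {
        name: round(100.0 * len(ids) / len(universe), 1)
        for name, ids in sorted(per_reaction.items())
    }


def design_library(
    catalog_path,
    synthon_catalog_path,
    config: Optional[DesignConfig] = None,
    out_dir=None,
) -> DesignReport:
    """Run the full design cascade and (optionally) write library files.

    Stages: ingest -> property filters -> poised classification ->
    compatibility -> synthon availability -> greedy diversity pick of k.
    Deterministic given the config seeds.  If a stage empties the pipeline
    the report is still produced, flagged ``exhausted at <stage>``.
    """
    config = config or DesignConfig()
    library = (
        load_reaction_library(config.reaction_file)
        if config.reaction_file
        else builtin_reaction_library()
    )
    if config.enabled_reactions is not None:
        names = {d.name for d in library}
        missing = set(config.enabled_reactions) - names
        if missing:
            raise ValueError(f"enabled reactions not in library: {sorted(missing)}")
        library = [d for d in library if d.name in set(config.enabled_reactions)]

    records = read_catalog(catalog_path)
    synthons = read_synthon_catalog(synthon_catalog_path)
    counts = {"ingested": len(records)}
    exhausted = None

    prop_report = apply_property_filters(records, config.thresholds)
    by_id = {r.id: r for r in records}
    kept = [by_id[i] for i in prop_report.kept]
    counts["property_kept"] = len(kept)

    annotations = []
    for rec in kept:
        annotations.extend(classify_poised(rec, library))
    poised_ids = sorted({a.fragment_id for a in annotations})
    counts["poised"] = len(poised_ids)

    compatible = []
    for ann in annotations:
        ok, _reason = compatibility_filter(ann, by_id[ann.fragment_id], library)
        if ok:
            compatible.append(ann)
    compatible_ids = sorted({a.fragment_id for a in compatible})
    counts["compatible"] = len(compatible_ids)

    available = availability_filter(
        compatible,
        synthons,
        mode=config.availability_mode,
        threshold=config.availability_threshold,
    )
    available_ids = sorted({a.fragment_id for a in available})
    counts["available"] = len(available_ids)

    composition = (
        composition_stats(available, available_ids) if available_ids else {}
    )

    pool = [by_id[i] for i in available_ids]
    if not pool:
        for stage in ("property_kept", "poised", "compatible", "available"):
            if counts[stage] == 0:
                exhausted = stage
                break
        selected = []
    elif config.k > len(pool):
        exhausted = f"selection (k={config.k} > pool of {len(pool)})"
        selected = [r.id for r in pool]
    else:
        selected = select_diverse(
            pool,
            config.k,
            metric=config.diversity_metric,
            seed=config.conformer_seed,
        )
    counts["selected"] = len(selected)

    report = DesignReport(
        counts=counts,
        composition=composition,
        selected=selected,
        exhausted_at=exhausted,
        config_hash=config.hash(),
        seeds={
            "conformer": config.conformer_seed,
            "selection": config.selection_seed,
        },
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_catalog([by_id[i] for i in selected], out / "selected.smi")
        import csv

        with open(out / "annotations.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fragment_id", "reaction", "matched_atoms", "synthons"])
            for ann in available:
                writer.writerow(
                    [
                        ann.fragment_id,
                        ann.reaction_name,
                        ";".join(map(str, ann.matched_atoms)),
                        ";".join(ann.synthons),
                    ]
                )
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        log.info("design run %s: %s", config.hash(), counts)
    return report
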