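"""Pathway-presence inference from homology hit tables.

Reaction presence: any hit with bitscore >= 50 (150 for the conservative
layer) and query coverage >= 0.75.  Pathway presence: completeness > 75%,
or completeness > 66% with the key enzymes present.  Threshold semantics
follow these operators exactly: bitscore/coverage cutoffs are inclusive,
completeness cutoffs strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .model_io import HitRecord, PathwayDefinition

logger = logging.getLogger("repertoire")

BITSCORE_MIN = 50.0
BITSCORE_CONSERVATIVE = 150.0
COVERAGE_MIN = 0.75
COMPLETENESS_FULL = 0.75   # present if completeness strictly above this
COMPLETENESS_KEY = 0.66    # ... or strictly above this with key enzymes


@dataclass
class PresenceCall:
    genome_id: str
    pathway_id: str
    completeness: float
    key_present: bool
    present: bool
    conservative: bool


def call_reactions(
    hits: list[HitRecord],
    bitscore_min: float = BITSCORE_MIN,
    coverage_min: float = COVERAGE_MIN,
) -> dict[tuple[str, str], bool]:
    """(genome, reaction-probe) -> present, inclusive thresholds on both."""
    present: dict[tuple[str, str], bool] = {}
    for h in hits:
        key = (h.genome_id, h.query_id)
        ok = h.bitscore >= bitscore_min and h.query_coverage >= coverage_min
        present[key] = present.get(key, False) or ok
    return present


def call_pathway(
    reaction_presence: dict[tuple[str, str], bool],
    definition: PathwayDefinition,
    genome_id: str,
    key_mode: str = "all",
    conservative_presence: dict[tuple[str, str], bool] | None = None,
) -> PresenceCall:
    """Presence decision for one genome x pathway.

    ``key_mode`` decides whether *all* key enzymes (default, stricter) or
    *any* key enzyme satisfies the key condition.  When a conservative
    reaction-presence map (bitscore >= 150 calls) is supplied, the same rule
    is evaluated on it for the conservative layer.
    """
    definition.validate()
    if key_mode not in ("all", "any"):
        raise ValueError(f"key_mode must be 'all' or 'any', got {key_mode!r}")

    def decide(presence: dict[tuple[str, str], bool]) -> tuple[float, bool, bool]:
        have = [presence.get((genome_id, r), False) for r in definition.reaction_ids]
        completeness = sum(have) / len(definition.reaction_ids)
        keys = [presence.get((genome_id, r), False)
                for r in definition.key_reaction_ids]
        key_ok = bool(keys) and (all(keys) if key_mode == "all" else any(keys))
        present = completeness > COMPLETENESS_FULL or (
            completeness > COMPLETENESS_KEY and key_ok)
        return completeness, key_ok, present

    completeness, key_ok, present = decide(reaction_presence)
    conservative = False
    if conservative_presence is not None:
        conservative = decide(conservative_presence)[2]
    return PresenceCall(
        genome_id=genome_id, pathway_id=definition.pathway_id,
        completeness=completeness, key_present=key_ok,
        present=present, conservative=conservative,
    )


def call_all_pathways(
    hits: list[HitRecord],
    definitions: list[PathwayDefinition],
    key_mode: str = "all",
    coverage_min: float = COVERAGE_MIN,
) -> list[PresenceCall]:
    """Standard (bitscore >= 50) and conservative (>= 150) calls for every
    genome seen in the hit table, over every pathway definition."""
    standard = call_reactions(hits, BITSCORE_MIN, coverage_min)
    conservative = call_reactions(hits, BITSCORE_CONSERVATIVE, coverage_min)
    genomes = sorted({h.genome_id for h in hits})
    return [
        call_pathway(standard, d, g, key_mode=key_mode,
                     conservative_presence=conservative)
        for g in genomes for d in definitions
    ]


def presence_matrix(calls: list[PresenceCall], layer: str = "present") -> pd.DataFrame:
    """Genome x pathway boolean matrix from calls (layer: present|conservative)."""
    if layer not in ("present", "conservative"):
        raise ValueError(f"unknown layer {layer!r}")
    rows: dict[str, dict[str, bool]] = {}
    for c in calls:
        rows.setdefault(c.genome_id, {})[c.pathway_id] = getattr(c, layer)
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(False)
    return df.sort_index().reindex(sorted(df.columns), axis=1).astype(bool)


def nutrient_provision_matrix(
    calls: list[PresenceCall],
    nutrient_map: dict[str, list[str]],
    layer: str = "present",
) -> pd.DataFrame:
    """Isolate x nutrient boolean matrix plus a ``community`` row.

    A nutrient is provisionable by an isolate iff any pathway mapped to it
    is present; the community row is the OR over all isolates (can the
    community as a whole synthesize the nutrient).
    """
    pm = presence_matrix(calls, layer=layer)
    known = set(pm.columns)
    out = pd.DataFrame(index=pm.index, dtype=bool)
    for nutrient, pathway_ids in nutrient_map.items():
        missing = [p for p in pathway_ids if p not in known]
        if missing:
            logger.warning("nutrient %r: pathways absent from calls: %s",
                           nutrient, missing)
        cols = [p for p in pathway_ids if p in known]
        out[nutrient] = pm[cols].any(axis=1) if cols else False
    out.loc["community"] = out.any(axis=0)
    return out


def pathway_completion_targets(
    calls: list[PresenceCall],
    definitions: list[PathwayDefinition],
    reaction_presence: dict[tuple[str, str], bool],
) -> list[tuple[str, str]]:
    """(genome, reaction) pairs to add: the absent reactions of pathways that
    were nonetheless called present (feeds gap-filling candidate pools)."""
    by_id = {d.pathway_id: d for d in definitions}
    targets = []
    for c in calls:
        if not c.present:
            continue
        d = by_id[c.pathway_id]
        for r in d.reaction_ids:
            if not reaction_presence.get((c.genome_id, r), False):
                targets.append((c.genome_id, r))
    return sorted(set(targets))
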