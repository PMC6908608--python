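"""Core network data model and all file I/O.

The native metabolic-model format is a small JSON document (or a pair of
TSVs, ``metabolites.tsv`` + ``reactions.tsv``); a read-only subset of SBML
core (species, reactions, bounds via parameters) is also accepted.  All flux
units are mmol/gDW/h; biomass flux is read as 1/h.  Exchange convention is
the standard COBRA one: negative flux = uptake, positive = secretion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

logger = logging.getLogger("repertoire")

COMPARTMENTS = ("c", "e")

PLATE_T0_MIN = 0
PLATE_T46_MIN = 2760  # 46 h in minutes
WATER_WELL = "water"


class ParseError(ValueError):
    """Malformed input file (bad record, missing column, unknown value)."""


class ModelValidationError(ValueError):
    """A model invariant is violated."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def validate(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r} "
                f"(expected one of {COMPARTMENTS})"
            )


@dataclass
class Reaction:
    """A reaction with stoichiometry ``{metabolite_id: coefficient}``.

    Negative coefficients are consumed, positive produced.  Exchange
    reactions have exactly one (extracellular) metabolite with coefficient
    -1, so negative flux means uptake into the system.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    is_exchange: bool = False
    is_biomass: bool = False

    def validate(self, metabolite_map: dict[str, Metabolite] | None = None) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if metabolite_map is not None:
            for met in self.stoichiometry:
                if met not in metabolite_map:
                    raise ModelValidationError(
                        f"reaction {self.id!r} references undefined metabolite {met!r}"
                    )
        if self.is_exchange:
            if len(self.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {self.id!r} must have exactly one metabolite"
                )
            (met, coef), = self.stoichiometry.items()
            if coef != -1:
                raise ModelValidationError(
                    f"exchange reaction {self.id!r}: coefficient must be -1, got {coef}"
                )
            if metabolite_map is not None and metabolite_map[met].compartment != "e":
                raise ModelValidationError(
                    f"exchange reaction {self.id!r}: metabolite {met!r} is not "
                    f"extracellular"
                )


@dataclass
class MetabolicModel:
    """Stoichiometric network with bounds, exchanges and one biomass reaction."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_id: str
    annotations: dict = field(default_factory=dict)

    # -- lookups ----------------------------------------------------------
    @property
    def metabolite_map(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reaction_map(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_for(self, metabolite_id: str) -> Reaction | None:
        """Exchange reaction whose single metabolite is ``metabolite_id``."""
        for r in self.reactions:
            if r.is_exchange and metabolite_id in r.stoichiometry:
                return r
        return None

    # -- validation -------------------------------------------------------
    def validate(self) -> "MetabolicModel":
        mets = self.metabolite_map
        if len(mets) != len(self.metabolites):
            seen: set[str] = set()
            dup = next(m.id for m in self.metabolites if m.id in seen or seen.add(m.id))
            raise ModelValidationError(f"model {self.id!r}: duplicate metabolite id {dup!r}")
        rxns = self.reaction_map
        if len(rxns) != len(self.reactions):
            raise ModelValidationError(f"model {self.id!r}: duplicate reaction ids")
        for m in self.metabolites:
            m.validate()
        for r in self.reactions:
            r.validate(mets)
        biomass = [r for r in self.reactions if r.is_biomass]
        if len(biomass) != 1 or biomass[0].id != self.biomass_id:
            raise ModelValidationError(
                f"model {self.id!r}: expected exactly one biomass reaction with id "
                f"{self.biomass_id!r}, found {[r.id for r in biomass]}"
            )
        used = {met for r in self.reactions for met in r.stoichiometry}
        orphan = sorted(set(mets) - used)
        if orphan:
            raise ModelValidationError(
                f"model {self.id!r}: metabolites in no reaction: {orphan}"
            )
        return self

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            biomass_id=self.biomass_id,
            annotations=dict(self.annotations),
        )


@dataclass
class Medium:
    """Named map from extracellular metabolite id to maximum uptake rate (>0)."""

    name: str
    uptake_limits: dict[str, float]

    def validate(self) -> "Medium":
        for met, lim in self.uptake_limits.items():
            if not (lim > 0):
                raise ModelValidationError(
                    f"medium {self.name!r}: uptake limit for {met!r} must be > 0, got {lim}"
                )
        return self

    def with_added(self, metabolite_id: str, limit: float) -> "Medium":
        limits = dict(self.uptake_limits)
        limits[metabolite_id] = limit
        return Medium(name=f"{self.name}+{metabolite_id}", uptake_limits=limits)

    def without(self, metabolite_id: str) -> "Medium":
        limits = {k: v for k, v in self.uptake_limits.items() if k != metabolite_id}
        return Medium(name=f"{self.name}-{metabolite_id}", uptake_limits=limits)


@dataclass
class HitRecord:
    """One homology hit of a reaction/enzyme probe against a genome."""

    genome_id: str
    query_id: str
    bitscore: float
    query_coverage: float

    def validate(self) -> "HitRecord":
        if self.bitscore < 0:
            raise ParseError(f"hit {self.genome_id}/{self.query_id}: negative bitscore")
        if not (0 <= self.query_coverage <= 1):
            raise ParseError(
                f"hit {self.genome_id}/{self.query_id}: coverage {self.query_coverage} "
                f"outside [0, 1]"
            )
        return self


@dataclass
class PathwayDefinition:
    pathway_id: str
    name: str
    reaction_ids: list[str]
    key_reaction_ids: list[str] = field(default_factory=list)
    category: str = ""

    def validate(self) -> "PathwayDefinition":
        if not self.reaction_ids:
            raise ParseError(f"pathway {self.pathway_id!r}: empty reaction list")
        extra = set(self.key_reaction_ids) - set(self.reaction_ids)
        if extra:
            raise ParseError(
                f"pathway {self.pathway_id!r}: key reactions not in pathway: {sorted(extra)}"
            )
        return self


# ---------------------------------------------------------------------------
# Medium application
# ---------------------------------------------------------------------------

def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy with exchange lower bounds set from the medium.

    Exchanges whose metabolite is in the medium get ``lower_bound =
    -uptake_limit``; all other exchanges get ``lower_bound = 0``.  Secretion
    (upper) bounds are untouched.  Medium entries with no matching exchange
    reaction are logged as warnings, not errors.
    """
    medium.validate()
    out = model.copy()
    covered: set[str] = set()
    for r in out.reactions:
        if not r.is_exchange:
            continue
        (met,) = r.stoichiometry
        if met in medium.uptake_limits:
            r.lower_bound = -medium.uptake_limits[met]
            covered.add(met)
        else:
            r.lower_bound = 0.0
    for met in set(medium.uptake_limits) - covered:
        logger.warning(
            "medium %r names metabolite %r with no exchange reaction in model %r",
            medium.name, met, model.id,
        )
    return out


# ---------------------------------------------------------------------------
# Model serialization: JSON, TSV pair, SBML subset
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "biomass_id": model.biomass_id,
        "annotations": model.annotations,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "is_exchange": r.is_exchange,
                "is_biomass": r.is_biomass,
            }
            for r in model.reactions
        ],
    }


def model_from_dict(doc: dict) -> MetabolicModel:
    try:
        model = MetabolicModel(
            id=doc["id"],
            metabolites=[Metabolite(**m) for m in doc["metabolites"]],
            reactions=[Reaction(**r) for r in doc["reactions"]],
            biomass_id=doc["biomass_id"],
            annotations=doc.get("annotations", {}),
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed model document: {exc}") from exc
    return model.validate()


def _parse_stoichiometry(text: str, context: str) -> dict[str, float]:
    """Parse ``met:coef;met:coef`` strings from the tabular format."""
    stoich: dict[str, float] = {}
    for i, item in enumerate(str(text).split(";")):
        item = item.strip()
        if not item:
            continue
        if ":" not in item:
            raise ParseError(f"{context}: bad stoichiometry term {item!r} (term {i + 1})")
        met, _, coef = item.rpartition(":")
        try:
            stoich[met.strip()] = float(coef)
        except ValueError as exc:
            raise ParseError(
                f"{context}: non-numeric coefficient {coef!r} for {met!r}"
            ) from exc
    if not stoich:
        raise ParseError(f"{context}: empty stoichiometry")
    return stoich


def _format_stoichiometry(stoich: dict[str, float]) -> str:
    return ";".join(f"{m}:{c:g}" for m, c in sorted(stoich.items()))


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         True: True, False: False, 1: True, 0: False}


def read_model(path: str | Path, format: str = "auto") -> MetabolicModel:
    """Read a metabolic model (JSON document, TSV pair, or SBML subset).

    ``format`` is one of ``auto``, ``tabular``, ``sbml``.  For the TSV pair,
    ``path`` is the reactions TSV and the metabolites TSV is expected next to
    it with the same stem plus ``.metabolites.tsv`` (see ``write_model``).
    """
    path = Path(path)
    if format == "auto":
        if path.suffix in (".xml", ".sbml"):
            format = "sbml"
        else:
            format = "tabular"
    if format == "sbml":
        return _read_sbml(path)
    if format != "tabular":
        raise ParseError(f"unknown model format {format!r}")
    if path.suffix == ".json":
        with open(path) as fh:
            return model_from_dict(json.load(fh))
    return _read_tsv_pair(path)


def _read_tsv_pair(rxn_path: Path) -> MetabolicModel:
    met_path = rxn_path.with_suffix("").with_suffix(".metabolites.tsv")
    if not met_path.exists():
        raise ParseError(f"metabolites table {met_path} not found next to {rxn_path}")
    mets_df = pd.read_csv(met_path, sep="\t", dtype=str)
    rxns_df = pd.read_csv(rxn_path, sep="\t", dtype=str)
    for col in ("id", "name", "compartment"):
        if col not in mets_df.columns:
            raise ParseError(f"{met_path}: missing column {col!r}")
    for col in ("id", "stoichiometry", "lb", "ub", "is_exchange", "is_biomass"):
        if col not in rxns_df.columns:
            raise ParseError(f"{rxn_path}: missing column {col!r}")
    metabolites = [
        Metabolite(id=row.id, name=row.name if isinstance(row.name, str) else "",
                   compartment=row.compartment)
        for row in mets_df.itertuples(index=False)
    ]
    reactions = []
    biomass_id = None
    for i, row in enumerate(rxns_df.itertuples(index=False)):
        context = f"{rxn_path} record {i + 1} ({row.id})"
        try:
            lb, ub = float(row.lb), float(row.ub)
        except ValueError as exc:
            raise ParseError(f"{context}: non-numeric bound") from exc
        try:
            is_ex = _BOOL[str(row.is_exchange).strip().lower()]
            is_bm = _BOOL[str(row.is_biomass).strip().lower()]
        except KeyError as exc:
            raise ParseError(f"{context}: bad boolean flag {exc}") from exc
        reactions.append(
            Reaction(
                id=row.id,
                stoichiometry=_parse_stoichiometry(row.stoichiometry, context),
                lower_bound=lb, upper_bound=ub,
                is_exchange=is_ex, is_biomass=is_bm,
            )
        )
        if is_bm:
            biomass_id = row.id
    if biomass_id is None:
        raise ParseError(f"{rxn_path}: no biomass reaction flagged")
    model_id = rxn_path.stem.removesuffix(".reactions")
    return MetabolicModel(
        id=model_id, metabolites=metabolites, reactions=reactions,
        biomass_id=biomass_id,
    ).validate()


def write_model(model: MetabolicModel, path: str | Path, format: str = "auto") -> None:
    """Write a model as JSON (``*.json``) or the TSV pair (``*.reactions.tsv``)."""
    path = Path(path)
    if format == "auto":
        format = "json" if path.suffix == ".json" else "tabular"
    if format == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    met_path = path.with_suffix("").with_suffix(".metabolites.tsv")
    pd.DataFrame(
        [{"id": m.id, "name": m.name, "compartment": m.compartment}
         for m in model.metabolites]
    ).to_csv(met_path, sep="\t", index=False)
    pd.DataFrame(
        [{
            "id": r.id,
            "stoichiometry": _format_stoichiometry(r.stoichiometry),
            "lb": r.lower_bound, "ub": r.upper_bound,
            "is_exchange": str(r.is_exchange).lower(),
            "is_biomass": str(r.is_biomass).lower(),
        } for r in model.reactions]
    ).to_csv(path, sep="\t", index=False)


_SBML_NS = "{http://www.sbml.org/sbml/level3/version1/core}"
_FBC_NS = "{http://www.sbml.org/sbml/level3/version1/fbc/version2}"


def _read_sbml(path: Path) -> MetabolicModel:
    """Read a minimal SBML-core subset: species, reactions, bounds via
    parameters (fbc:fluxBounds attributes honoured when present)."""
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    model_el = root.find(f"{_SBML_NS}model")
    if model_el is None:  # tolerate un-namespaced toy files
        model_el = root.find("model")
        ns = fbc = ""
    else:
        ns, fbc = _SBML_NS, _FBC_NS

    def findall(parent, *tags):
        if parent is None:
            return []
        for tag in tags:
            found = parent.findall(tag)
            if found:
                return found
        return []

    params = {
        p.get("id"): float(p.get("value", "nan"))
        for p in findall(model_el.find(f"{ns}listOfParameters"), f"{ns}parameter")
    }
    metabolites = []
    for sp in findall(model_el.find(f"{ns}listOfSpecies"), f"{ns}species"):
        comp = sp.get("compartment", "c")
        metabolites.append(Metabolite(
            id=sp.get("id"), name=sp.get("name", ""),
            compartment="e" if comp.lower().startswith("e") else "c",
        ))
    reactions = []
    biomass_id = None
    for rx in findall(model_el.find(f"{ns}listOfReactions"), f"{ns}reaction"):
        rid = rx.get("id")
        stoich: dict[str, float] = {}
        for ref in findall(rx.find(f"{ns}listOfReactants"), f"{ns}speciesReference"):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0.0) - float(
                ref.get("stoichiometry", "1"))
        for ref in findall(rx.find(f"{ns}listOfProducts"), f"{ns}speciesReference"):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0.0) + float(
                ref.get("stoichiometry", "1"))
        reversible = rx.get("reversible", "true").lower() == "true"
        lb = params.get(rx.get(f"{fbc}lowerFluxBound"),
                        -1000.0 if reversible else 0.0)
        ub = params.get(rx.get(f"{fbc}upperFluxBound"), 1000.0)
        is_bm = "biomass" in rid.lower()
        is_ex = rid.startswith("EX_") or rid.lower().startswith("r_ex_")
        if is_bm:
            biomass_id = rid
        reactions.append(Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            is_exchange=is_ex, is_biomass=is_bm,
        ))
    if biomass_id is None:
        raise ParseError(f"{path}: no reaction with 'biomass' in its id")
    return MetabolicModel(
        id=model_el.get("id", path.stem), metabolites=metabolites,
        reactions=reactions, biomass_id=biomass_id,
    ).validate()


# ---------------------------------------------------------------------------
# Tabular readers: media, hit tables, pathways, plates, traits
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


def read_medium(path: str | Path, name: str | None = None) -> Medium:
    """Medium CSV with columns ``metabolite_id, max_uptake``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("metabolite_id", "max_uptake"), path)
    limits: dict[str, float] = {}
    for row in df.itertuples(index=False):
        try:
            limits[str(row.metabolite_id)] = float(row.max_uptake)
        except ValueError as exc:
            raise ParseError(
                f"{path}: non-numeric max_uptake for {row.metabolite_id!r}"
            ) from exc
    return Medium(name=name or path.stem, uptake_limits=limits).validate()


def write_medium(medium: Medium, path: str | Path) -> None:
    pd.DataFrame(
        sorted(medium.uptake_limits.items()), columns=["metabolite_id", "max_uptake"]
    ).to_csv(path, index=False)


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """BLAST-outfmt6-like TSV: ``genome_id, query_id, bitscore, qcovs``.

    Coverage may be a fraction or a percentage; percent scale is autodetected
    (any value > 1) and logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("genome_id", "query_id", "bitscore", "qcovs"), path)
    if not pd.api.types.is_numeric_dtype(df["bitscore"]) or not \
            pd.api.types.is_numeric_dtype(df["qcovs"]):
        raise ParseError(f"{path}: non-numeric bitscore/qcovs values")
    cov = df["qcovs"].astype(float)
    if (cov > 1).any():
        logger.info("%s: qcovs looks like percent; dividing by 100", path)
        cov = cov / 100.0
    return [
        HitRecord(
            genome_id=str(row.genome_id), query_id=str(row.query_id),
            bitscore=float(row.bitscore), query_coverage=float(c),
        ).validate()
        for row, c in zip(df.itertuples(index=False), cov)
    ]


def write_hit_table(hits: list[HitRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"genome_id": h.genome_id, "query_id": h.query_id,
          "bitscore": h.bitscore, "qcovs": h.query_coverage} for h in hits]
    ).to_csv(path, sep="\t", index=False)


def read_pathways(path: str | Path) -> list[PathwayDefinition]:
    """Pathway TSV: ``pathway_id, name, category, reaction_ids, key_reaction_ids``
    with reaction lists as ``;``-separated ids (key list may be empty)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ("pathway_id", "name", "category", "reaction_ids",
                          "key_reaction_ids"), path)
    out = []
    for row in df.itertuples(index=False):
        rxns = [x for x in row.reaction_ids.split(";") if x]
        keys = [x for x in row.key_reaction_ids.split(";") if x]
        out.append(PathwayDefinition(
            pathway_id=row.pathway_id, name=row.name, category=row.category,
            reaction_ids=rxns, key_reaction_ids=keys,
        ).validate())
    return out


def write_pathways(definitions: list[PathwayDefinition], path: str | Path) -> None:
    pd.DataFrame(
        [{"pathway_id": d.pathway_id, "name": d.name, "category": d.category,
          "reaction_ids": ";".join(d.reaction_ids),
          "key_reaction_ids": ";".join(d.key_reaction_ids)} for d in definitions]
    ).to_csv(path, sep="\t", index=False)


def read_plate(path: str | Path) -> pd.DataFrame:
    """Tidy plate CSV: ``strain, substrate, replicate, time_min, od``.

    Validates that every strain has the water control well and that the
    first (t0) and final (46 h) timepoints are present; OD must be >= 0.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("strain", "substrate", "replicate", "time_min", "od"), path)
    if not pd.api.types.is_numeric_dtype(df["od"]):
        raise ParseError(f"{path}: non-numeric od values")
    if (df["od"] < 0).any():
        raise ParseError(f"{path}: negative OD values")
    for strain, grp in df.groupby("strain"):
        if WATER_WELL not in set(grp["substrate"]):
            raise ParseError(
                f"{path}: strain {strain!r} lacks the required {WATER_WELL!r} "
                f"control well"
            )
        times = set(grp["time_min"])
        for t in (PLATE_T0_MIN, PLATE_T46_MIN):
            if t not in times:
                raise ParseError(
                    f"{path}: strain {strain!r} missing timepoint t={t} min"
                )
    return df


def read_traits(path: str | Path) -> pd.DataFrame:
    """Isolate trait CSV indexed by ``isolate_id``; all trait columns numeric."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("isolate_id",), path)
    df = df.set_index("isolate_id")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ParseError(f"{path}: non-numeric values in column {col!r}")
        if df[col].isna().any():
            raise ParseError(f"{path}: missing values in column {col!r}")
    return df


def read_phenotype(path: str | Path, column: str | None = None) -> pd.Series:
    """Phenotype CSV: ``isolate_id`` plus one numeric phenotype column."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("isolate_id",), path)
    df = df.set_index("isolate_id")
    if column is None:
        if df.shape[1] != 1:
            raise ParseError(f"{path}: expected exactly one phenotype column")
        column = df.columns[0]
    series = df[column]
    if not pd.api.types.is_numeric_dtype(series) or series.isna().any():
        raise ParseError(f"{path}: phenotype column {column!r} must be numeric")
    return series


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file of 16S sequences -> ordered ``{id: sequence}``."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for {rec.id!r}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ParseError(f"{path}: {rec.id!r} has non-ACGTN symbols {sorted(bad)}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
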