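"""Universal adaptive strategy theory (UAST) scoring.

Each isolate is scored against the rest of its cohort for the three
strategies of heterotrophic bacteria — Competitive (C), Stress-tolerant (S)
and Ruderal (R) — from genomic and metabolic traits.  A point is awarded
per criterion when the isolate falls in the strategy-favorable quartile of
the cohort (growth rate uses the cohort mean instead); the score per
strategy is the points divided by the number of criteria for that strategy
(C: 4, S: 4, R: 3).  The assigned strategy is the argmax; a tie of the top
scores is a mixed strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fba_core import scan_auxotrophies
from .model_io import Medium, MetabolicModel
from .pathways import PresenceCall
from .stats import spearman_with_p, wilcoxon_rank_sum

#: pathway categories feeding the trait counts
CATEGORY_ANTIBIOTIC = "Antibiotic-Biosynthesis"
CATEGORY_ENERGY = "Energy-Metabolism"
CATEGORY_SIDEROPHORE = "Siderophores-Biosynthesis"
CATEGORY_EPS = "EPS"

C_CRITERIA = 4
S_CRITERIA = 4
R_CRITERIA = 3

TRAIT_COLUMNS = (
    "genome_size", "antibiotic_pathways", "catabolic_diversity",
    "siderophore_pathways", "auxotrophies", "growth_rate", "rrna_copies",
    "eps_pathways",
)


@dataclass
class IsolateTraits:
    isolate_id: str
    genome_size: int
    antibiotic_pathways: int
    catabolic_diversity: int
    siderophore_pathways: int
    auxotrophies: int
    growth_rate: float  # 1/h in rich medium
    rrna_copies: int
    eps_pathways: int

    def validate(self) -> "IsolateTraits":
        if self.genome_size <= 0:
            raise ValueError(f"isolate {self.isolate_id!r}: genome_size must be > 0")
        for fieldname in ("antibiotic_pathways", "catabolic_diversity",
                          "siderophore_pathways", "auxotrophies",
                          "rrna_copies", "eps_pathways"):
            if getattr(self, fieldname) < 0:
                raise ValueError(
                    f"isolate {self.isolate_id!r}: {fieldname} must be >= 0")
        return self


@dataclass
class StrategyScore:
    isolate_id: str
    c_score: float
    s_score: float
    r_score: float
    assigned: str  # C | S | R | mixed


def compute_traits(
    model: MetabolicModel,
    calls: list[PresenceCall],
    growth_rate: float,
    categories: dict[str, str],
    minimal_medium: Medium | None = None,
    biomass_components: list[str] | None = None,
    auxotrophies: int | None = None,
) -> IsolateTraits:
    """Assemble the trait record for one isolate.

    ``categories`` maps pathway_id -> category (from the pathway
    definitions).  Pathway counts are present pathways per category;
    auxotrophies come from :func:`repertoire.fba_core.scan_auxotrophies`
    unless given directly; genome size and rRNA copy number come from the
    model annotations (missing annotations are an error naming the isolate).
    """
    present = [c.pathway_id for c in calls if c.genome_id == model.id and c.present]

    def count(category: str) -> int:
        return sum(1 for p in present if categories.get(p, "") == category)

    if auxotrophies is None:
        if minimal_medium is None or biomass_components is None:
            raise ValueError(
                "either auxotrophies or (minimal_medium, biomass_components) "
                "must be provided"
            )
        auxotrophies = len(scan_auxotrophies(model, minimal_medium,
                                             biomass_components))
    for key in ("genome_size_bp", "rrna_copies"):
        if key not in model.annotations:
            raise ValueError(
                f"isolate {model.id!r}: missing model annotation {key!r}")
    return IsolateTraits(
        isolate_id=model.id,
        genome_size=int(model.annotations["genome_size_bp"]),
        antibiotic_pathways=count(CATEGORY_ANTIBIOTIC),
        catabolic_diversity=count(CATEGORY_ENERGY),
        siderophore_pathways=count(CATEGORY_SIDEROPHORE),
        auxotrophies=auxotrophies,
        growth_rate=growth_rate,
        rrna_copies=int(model.annotations["rrna_copies"]),
        eps_pathways=count(CATEGORY_EPS),
    ).validate()


def traits_frame(cohort: list[IsolateTraits]) -> pd.DataFrame:
    return pd.DataFrame(
        [{**{"isolate_id": t.isolate_id},
          **{c: getattr(t, c) for c in TRAIT_COLUMNS}} for t in cohort]
    ).set_index("isolate_id")


def score_strategies(cohort: list[IsolateTraits] | pd.DataFrame) -> list[StrategyScore]:
    """C/S/R scores and assigned strategy for every isolate in the cohort.

    Quartile membership is inclusive (value <= Q1 is lower quartile, value
    >= Q3 upper quartile; rank-based, so invariant under positive rescaling
    of any trait).  Growth rate is split at the cohort mean per the stated
    exception.  Any tie among the top scores (two- or three-way) gives
    ``mixed``.
    """
    df = cohort if isinstance(cohort, pd.DataFrame) else traits_frame(cohort)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns {missing}")
    if len(df) < 4:
        raise ValueError("cohort too small for quartile scoring (need >= 4)")

    q1 = df.quantile(0.25)
    q3 = df.quantile(0.75)
    mean_growth = df["growth_rate"].mean()
    upper = {c: df[c] >= q3[c] for c in TRAIT_COLUMNS}
    lower = {c: df[c] <= q1[c] for c in TRAIT_COLUMNS}

    c_pts = (upper["genome_size"].astype(int)
             + upper["antibiotic_pathways"].astype(int)
             + upper["catabolic_diversity"].astype(int)
             + upper["siderophore_pathways"].astype(int))
    s_pts = (upper["auxotrophies"].astype(int)
             + upper["eps_pathways"].astype(int)
             + lower["rrna_copies"].astype(int)
             + (df["growth_rate"] < mean_growth).astype(int))
    r_pts = ((df["growth_rate"] > mean_growth).astype(int)
             + upper["rrna_copies"].astype(int)
             + lower["catabolic_diversity"].astype(int))

    out = []
    for isolate in df.index:
        scores = {
            "C": c_pts[isolate] / C_CRITERIA,
            "S": s_pts[isolate] / S_CRITERIA,
            "R": r_pts[isolate] / R_CRITERIA,
        }
        best = max(scores.values())
        winners = [k for k, v in scores.items() if v == best]
        assigned = winners[0] if len(winners) == 1 else "mixed"
        out.append(StrategyScore(
            isolate_id=str(isolate), c_score=float(scores["C"]),
            s_score=float(scores["S"]), r_score=float(scores["R"]),
            assigned=assigned,
        ))
    return out


def scores_frame(scores: list[StrategyScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"isolate_id": s.isolate_id, "c": s.c_score, "s": s.s_score,
          "r": s.r_score, "assigned": s.assigned} for s in scores]
    ).set_index("isolate_id")


def strategy_phenotype_tests(
    scores: list[StrategyScore], loads: dict[str, float]
) -> dict[str, float]:
    """Colonization statistics across strategies.

    Wilcoxon rank-sum of bacterial load, ruderal vs all other isolates, and
    the Spearman correlation of load with the isolate's own assigned-strategy
    score within the competitive and stress-tolerant isolates (NaN when
    degenerate).
    """
    ruderal = [loads[s.isolate_id] for s in scores if s.assigned == "R"]
    others = [loads[s.isolate_id] for s in scores if s.assigned != "R"]
    if len(ruderal) < 2 or len(others) < 2:
        raise ValueError("need >= 2 isolates per group for the rank-sum test")
    stat, p_wilcoxon = wilcoxon_rank_sum(ruderal, others)
    cs = [s for s in scores if s.assigned in ("C", "S")]
    own = [s.c_score if s.assigned == "C" else s.s_score for s in cs]
    load_cs = [loads[s.isolate_id] for s in cs]
    rho, p_rho = spearman_with_p(own, load_cs) if len(cs) >= 3 else (
        float("nan"), float("nan"))
    return {
        "wilcoxon_statistic": stat,
        "p_ruderal_vs_others": p_wilcoxon,
        "rho_load_vs_score_CS": rho,
        "p_load_vs_score_CS": p_rho,
    }
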