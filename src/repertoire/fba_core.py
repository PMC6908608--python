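"""Linear-programming core: FBA, FVA, utilizability screens, auxotrophy and
futile-cycle scans, and parsimonious gap-filling.

All problems are solved with HiGHS via :func:`scipy.optimize.linprog` over the
steady-state constraint ``S v = 0`` with flux bounds.  Fluxes are mmol/gDW/h;
the biomass flux is the growth rate in 1/h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_io import (
    Medium,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    apply_medium,
)

logger = logging.getLogger("repertoire")

DEFAULT_TOL = 1e-6
#: uptake limit granted to a candidate metabolite during utilizability screens
CANDIDATE_UPTAKE = 10.0


class GapFillError(RuntimeError):
    """No subset of the universal pool restores growth."""


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FvaResult:
    reaction_id: str
    min_flux: float
    max_flux: float


@dataclass
class GapFillResult:
    added_reaction_ids: list[str]
    achieved_growth: float


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def stoichiometric_matrix(
    metabolites: list[Metabolite], reactions: list[Reaction]
) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Sparse S (metabolites x reactions) plus row/column id orderings."""
    met_ids = [m.id for m in metabolites]
    rxn_ids = [r.id for r in reactions]
    met_idx = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, r in enumerate(reactions):
        for met, coef in r.stoichiometry.items():
            rows.append(met_idx[met])
            cols.append(j)
            vals.append(coef)
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    return S, met_ids, rxn_ids


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded",
           4: "numerical"}


def solve_lp(
    c: np.ndarray,
    A_eq: sparse.csr_matrix | None,
    bounds: list[tuple[float, float]],
    maximize: bool = True,
    A_ub: sparse.csr_matrix | None = None,
    b_ub: np.ndarray | None = None,
) -> tuple[str, float, np.ndarray | None]:
    """Solve max/min ``c.v`` s.t. ``A_eq v = 0``, ``A_ub v <= b_ub``, bounds."""
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]) if A_eq is not None else None,
        A_ub=A_ub, b_ub=b_ub,
        bounds=bounds, method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return status, float("nan"), None
    return status, sign * res.fun, res.x


class ModelLP:
    """Reusable LP view of a model (optionally with a medium applied)."""

    def __init__(self, model: MetabolicModel, medium: Medium | None = None):
        self.model = apply_medium(model, medium) if medium is not None else model.copy()
        self.S, self.met_ids, self.rxn_ids = stoichiometric_matrix(
            self.model.metabolites, self.model.reactions
        )
        self.rxn_idx = {r: j for j, r in enumerate(self.rxn_ids)}
        self.bounds = [
            (r.lower_bound, r.upper_bound) for r in self.model.reactions
        ]

    def objective_vector(self, reaction_id: str) -> np.ndarray:
        c = np.zeros(len(self.rxn_ids))
        c[self.rxn_idx[reaction_id]] = 1.0
        return c

    def optimize(self, reaction_id: str, maximize: bool = True) -> FluxSolution:
        status, obj, x = solve_lp(
            self.objective_vector(reaction_id), self.S, self.bounds, maximize
        )
        fluxes = dict(zip(self.rxn_ids, x)) if x is not None else {}
        return FluxSolution(status=status, objective=obj, fluxes=fluxes)

    def set_bound(self, reaction_id: str, lower=None, upper=None) -> None:
        j = self.rxn_idx[reaction_id]
        lb, ub = self.bounds[j]
        self.bounds[j] = (lb if lower is None else lower,
                          ub if upper is None else upper)


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------

def solve_fba(
    model: MetabolicModel, medium: Medium, objective_id: str | None = None
) -> FluxSolution:
    """Maximize the objective flux (biomass by default) on the given medium."""
    objective_id = objective_id or model.biomass_id
    if objective_id not in model.reaction_map:
        raise KeyError(f"objective reaction {objective_id!r} not in model {model.id!r}")
    return ModelLP(model, medium).optimize(objective_id)


def flux_variability(
    model: MetabolicModel,
    medium: Medium,
    reaction_ids: list[str] | None = None,
    objective_fraction: float = 1.0,
) -> list[FvaResult]:
    """Min and max flux per reaction subject to biomass >= fraction * optimum."""
    if not (0.0 <= objective_fraction <= 1.0):
        raise ValueError("objective_fraction must be in [0, 1]")
    lp = ModelLP(model, medium)
    base = lp.optimize(model.biomass_id)
    if not base.optimal:
        raise RuntimeError(
            f"FVA base problem is {base.status} for model {model.id!r}"
        )
    if objective_fraction > 0:
        lp.set_bound(model.biomass_id, lower=objective_fraction * base.objective)
    out = []
    for rid in reaction_ids or lp.rxn_ids:
        c = lp.objective_vector(rid)
        _, lo, _ = solve_lp(c, lp.S, lp.bounds, maximize=False)
        _, hi, _ = solve_lp(c, lp.S, lp.bounds, maximize=True)
        out.append(FvaResult(reaction_id=rid, min_flux=lo, max_flux=hi))
    return out


# ---------------------------------------------------------------------------
# Utilizability screens
# ---------------------------------------------------------------------------

def utilizable_carbon_sources(
    model: MetabolicModel,
    base_medium: Medium,
    candidates: list[str],
    tol: float = DEFAULT_TOL,
    uptake_limit: float = CANDIDATE_UPTAKE,
    growth_fraction: float = 0.0,
) -> dict[str, bool]:
    """A candidate is utilizable iff the minimal flux of its exchange is
    negative (net uptake is forced to be possible).

    By default no growth constraint is applied; ``growth_fraction > 0``
    switches to the growth-coupled variant (biomass >= fraction * optimum).
    Candidates without an exchange reaction are reported non-utilizable and
    logged.
    """
    out: dict[str, bool] = {}
    for cand in candidates:
        ex = model.exchange_for(cand)
        if ex is None:
            logger.warning(
                "model %s: candidate %r has no exchange reaction; not utilizable",
                model.id, cand,
            )
            out[cand] = False
            continue
        medium = base_medium.with_added(cand, uptake_limit)
        lp = ModelLP(model, medium)
        if growth_fraction > 0:
            base = lp.optimize(model.biomass_id)
            if not base.optimal:
                out[cand] = False
                continue
            lp.set_bound(model.biomass_id, lower=growth_fraction * base.objective)
        status, lo, _ = solve_lp(
            lp.objective_vector(ex.id), lp.S, lp.bounds, maximize=False
        )
        out[cand] = status == "optimal" and lo < -tol
    return out


def producible_byproducts(
    model: MetabolicModel,
    medium: Medium,
    candidates: list[str],
    tol: float = DEFAULT_TOL,
    growth_fraction: float = 0.0,
) -> dict[str, bool]:
    """A candidate is a producible byproduct iff the maximal flux of its
    exchange is positive (net secretion is possible)."""
    out: dict[str, bool] = {}
    for cand in candidates:
        ex = model.exchange_for(cand)
        if ex is None:
            logger.warning(
                "model %s: candidate %r has no exchange reaction; not producible",
                model.id, cand,
            )
            out[cand] = False
            continue
        lp = ModelLP(model, medium)
        if growth_fraction > 0:
            base = lp.optimize(model.biomass_id)
            if not base.optimal:
                out[cand] = False
                continue
            lp.set_bound(model.biomass_id, lower=growth_fraction * base.objective)
        status, hi, _ = solve_lp(
            lp.objective_vector(ex.id), lp.S, lp.bounds, maximize=True
        )
        out[cand] = status == "optimal" and hi > tol
    return out


# ---------------------------------------------------------------------------
# Auxotrophy scan
# ---------------------------------------------------------------------------

def _extracellular_counterpart(met_id: str) -> str:
    return met_id[:-2] + "_e" if met_id.endswith("_c") else met_id + "_e"


def scan_auxotrophies(
    model: MetabolicModel,
    minimal_medium: Medium,
    biomass_components: list[str],
    tol: float = DEFAULT_TOL,
) -> list[str]:
    """Biomass components the model cannot synthesize on the minimal medium.

    For each (cytosolic) component a temporary demand reaction is maximized
    on the minimal medium with the component's extracellular counterpart
    removed; components with maximal demand flux <= tol are auxotrophic.
    """
    auxo = []
    for comp in biomass_components:
        if comp not in model.metabolite_map:
            auxo.append(comp)
            continue
        medium = minimal_medium.without(_extracellular_counterpart(comp))
        probe = model.copy()
        demand_id = f"DM__{comp}"
        probe.reactions.append(Reaction(
            id=demand_id, stoichiometry={comp: -1.0},
            lower_bound=0.0, upper_bound=1000.0,
        ))
        sol = ModelLP(probe, medium).optimize(demand_id)
        if not sol.optimal or sol.objective <= tol:
            auxo.append(comp)
    return auxo


# ---------------------------------------------------------------------------
# Futile cycles
# ---------------------------------------------------------------------------

def find_futile_cycles(
    model: MetabolicModel, tol: float = DEFAULT_TOL
) -> list[str]:
    """Reactions able to carry flux with every exchange closed.

    Runs FVA with all exchange bounds fixed at zero and no growth
    constraint; any internal reaction with |min| or |max| above ``tol`` is
    part of a (thermodynamically spurious) futile cycle.  Report-only.
    """
    closed = model.copy()
    for r in closed.reactions:
        if r.is_exchange:
            r.lower_bound = r.upper_bound = 0.0
    lp = ModelLP(closed)
    flagged = []
    for rid in lp.rxn_ids:
        if closed.reaction_map[rid].is_exchange:
            continue
        c = lp.objective_vector(rid)
        _, lo, _ = solve_lp(c, lp.S, lp.bounds, maximize=False)
        _, hi, _ = solve_lp(c, lp.S, lp.bounds, maximize=True)
        if abs(lo) > tol or abs(hi) > tol:
            flagged.append(rid)
    return flagged


# ---------------------------------------------------------------------------
# Parsimonious gap-filling
# ---------------------------------------------------------------------------

def _growth_with(
    model: MetabolicModel, pool: list[Reaction], subset: list[str], medium: Medium
) -> float:
    probe = model.copy()
    chosen = {r.id for r in pool} & set(subset)
    probe.reactions.extend(
        replace(r, stoichiometry=dict(r.stoichiometry))
        for r in pool if r.id in chosen
    )
    for r in probe.reactions:
        for met in r.stoichiometry:
            if met not in probe.metabolite_map:
                raise ModelValidationError(
                    f"pool reaction {r.id!r} references unknown metabolite {met!r}"
                )
    sol = solve_fba(probe, medium)
    return sol.objective if sol.optimal else 0.0


def gap_fill(
    model: MetabolicModel,
    universal_pool: list[Reaction],
    medium: Medium,
    min_growth: float,
    tol: float = DEFAULT_TOL,
) -> GapFillResult:
    """Minimal-cardinality reaction set from the pool restoring growth.

    Strategy: an LP with L1-penalized pool fluxes (biomass fixed at
    ``min_growth``) proposes a candidate set; greedy pruning in lexicographic
    reaction-id order then removes every reaction whose absence still allows
    growth.  Because adding reactions can only increase achievable growth,
    single-removal minimality implies that no proper subset suffices.
    """
    clash = {r.id for r in universal_pool} & set(model.reaction_map)
    if clash:
        raise ValueError(f"pool reaction ids collide with model: {sorted(clash)}")

    base_growth = _growth_with(model, universal_pool, [], medium)
    if base_growth >= min_growth - tol:
        return GapFillResult(added_reaction_ids=[], achieved_growth=base_growth)

    all_ids = sorted(r.id for r in universal_pool)
    full_growth = _growth_with(model, universal_pool, all_ids, medium)
    if full_growth < min_growth - tol:
        raise GapFillError(
            f"model {model.id!r} unfillable: growth {full_growth:.6g} < "
            f"{min_growth} even with the full pool"
        )

    # penalty LP over the extended network with split pool variables
    extended = model.copy()
    pool_sorted = sorted(universal_pool, key=lambda r: r.id)
    extended.reactions.extend(pool_sorted)
    S, _, rxn_ids = stoichiometric_matrix(extended.metabolites, extended.reactions)
    medium_model = apply_medium(extended, medium)
    bounds = []
    for r in medium_model.reactions:
        if r.id == model.biomass_id:
            bounds.append((min_growth, r.upper_bound))
        else:
            bounds.append((r.lower_bound, r.upper_bound))
    n = len(rxn_ids)
    pool_cols = [rxn_ids.index(r.id) for r in pool_sorted]
    # v_j = v+ - v- for pool columns; minimize sum(v+ + v-)
    extra = sparse.lil_matrix((S.shape[0], len(pool_cols)))
    for k, j in enumerate(pool_cols):
        extra[:, k] = -S[:, j]
        lo, hi = bounds[j]
        bounds[j] = (0.0, max(hi, 0.0))
        bounds.append((0.0, max(-lo, 0.0)))
    A = sparse.hstack([S, extra.tocsr()], format="csr")
    c = np.zeros(n + len(pool_cols))
    c[pool_cols] = 1.0
    c[n:] = 1.0
    status, _, x = solve_lp(c, A, bounds, maximize=False)
    if status != "optimal":  # fall back to the whole pool before pruning
        candidate = list(all_ids)
    else:
        candidate = [
            pool_sorted[k].id
            for k, j in enumerate(pool_cols)
            if abs(x[j]) > tol or abs(x[n + k]) > tol
        ]
        if _growth_with(model, universal_pool, candidate, medium) < min_growth - tol:
            candidate = list(all_ids)

    kept = sorted(candidate)
    for rid in sorted(candidate):  # lexicographic pruning order (determinism)
        trial = [r for r in kept if r != rid]
        if _growth_with(model, universal_pool, trial, medium) >= min_growth - tol:
            kept = trial
    achieved = _growth_with(model, universal_pool, kept, medium)
    return GapFillResult(added_reaction_ids=sorted(kept), achieved_growth=achieved)
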