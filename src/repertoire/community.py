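"""Pairwise community growth and ecological-interaction classification.

Two models are joined into one LP sharing a common extracellular pool.
Every internal reaction of a member is linearly coupled to that member's
biomass flux (|v| <= c * mu) so that a member cannot run pathways that only
benefit its partner while it is itself not growing.  Joint growth maximizes
the sum of the two biomass fluxes; a secondary max-min stage resolves
degenerate optima deterministically.  Joint rates (j1, j2) are compared with
monoculture rates (s1, s2) computed on the identical medium with the same
coupling, and the pair is labelled mutualism, competition, parasitism,
commensalism, amensalism or neutral.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .fba_core import DEFAULT_TOL, solve_lp, stoichiometric_matrix
from .model_io import Medium, MetabolicModel, Metabolite, Reaction

logger = logging.getLogger("repertoire")

#: default flux-to-biomass coupling coefficient (the convention of the
#: community-FBA coupling literature; label stability over {100, 400, 1000}
#: is asserted in the test suite)
DEFAULT_COUPLING = 400.0
#: relative tolerance for j == s equality in classification
DEFAULT_EPS = 1e-6
EPS_FLOOR = 1e-9

LABELS = ("mutualism", "competition", "parasitism", "commensalism",
          "amensalism", "neutral")


@dataclass
class CommunityModel:
    member_ids: tuple[str, str]
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_ids: dict[str, str]
    member_of: dict[str, str]  # reaction id -> member id ('' = community exchange)
    coupling: float

    @property
    def reaction_map(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}


@dataclass
class InteractionResult:
    member_ids: tuple[str, str]
    s1: float
    s2: float
    j1: float
    j2: float
    label: str
    status: str = "optimal"


# ---------------------------------------------------------------------------
# Joining
# ---------------------------------------------------------------------------

def _namespace(model: MetabolicModel, prefix: str) -> tuple[list[Metabolite], list[Reaction]]:
    """Prefix cytosolic metabolite ids and all reaction ids; extracellular
    metabolites keep their ids and become the shared pool."""
    rename = {
        m.id: (m.id if m.compartment == "e" else f"{prefix}:{m.id}")
        for m in model.metabolites
    }
    mets = [
        replace(m, id=rename[m.id]) for m in model.metabolites
    ]
    rxns = []
    for r in model.reactions:
        if r.is_exchange:
            continue  # replaced by community-level exchanges
        rxns.append(Reaction(
            id=f"{prefix}:{r.id}",
            stoichiometry={rename[m]: c for m, c in r.stoichiometry.items()},
            lower_bound=r.lower_bound, upper_bound=r.upper_bound,
            is_exchange=False, is_biomass=r.is_biomass,
        ))
    return mets, rxns


def join_models(
    a: MetabolicModel, b: MetabolicModel, c: float = DEFAULT_COUPLING
) -> CommunityModel:
    """Join two validated models over a common extracellular compartment."""
    if a.id == b.id:
        raise ValueError(f"member ids must differ (both {a.id!r})")
    a.validate(), b.validate()
    mets: dict[str, Metabolite] = {}
    reactions: list[Reaction] = []
    member_of: dict[str, str] = {}
    exchange_ub: dict[str, float] = {}
    for model in (a, b):
        ns_mets, ns_rxns = _namespace(model, model.id)
        for m in ns_mets:
            if m.id in mets and mets[m.id].compartment != m.compartment:
                raise ValueError(f"id collision after namespacing: {m.id!r}")
            mets.setdefault(m.id, m)
        for r in ns_rxns:
            if r.id in member_of:
                raise ValueError(f"reaction id collision after namespacing: {r.id!r}")
            member_of[r.id] = model.id
            reactions.append(r)
        for ex in model.exchange_reactions():
            (met,) = ex.stoichiometry
            exchange_ub[met] = max(exchange_ub.get(met, 0.0), ex.upper_bound)
    for met, ub in sorted(exchange_ub.items()):
        rid = f"EX_{met}"
        reactions.append(Reaction(
            id=rid, stoichiometry={met: -1.0},
            lower_bound=0.0, upper_bound=ub, is_exchange=True,
        ))
        member_of[rid] = ""
    return CommunityModel(
        member_ids=(a.id, b.id),
        metabolites=list(mets.values()),
        reactions=reactions,
        biomass_ids={a.id: f"{a.id}:{a.biomass_id}", b.id: f"{b.id}:{b.biomass_id}"},
        member_of=member_of,
        coupling=c,
    )


# ---------------------------------------------------------------------------
# Community FBA
# ---------------------------------------------------------------------------

def _community_lp(community: CommunityModel, medium: Medium):
    S, met_ids, rxn_ids = stoichiometric_matrix(
        community.metabolites, community.reactions
    )
    idx = {r: j for j, r in enumerate(rxn_ids)}
    bounds = []
    for r in community.reactions:
        if r.is_exchange:
            (met,) = r.stoichiometry
            lb = -medium.uptake_limits.get(met, 0.0)
            bounds.append((lb, r.upper_bound))
        else:
            bounds.append((r.lower_bound, r.upper_bound))
    # coupling rows: v - c*mu <= 0 and -v - c*mu <= 0 per internal reaction
    rows, cols, vals = [], [], []
    n_row = 0
    for r in community.reactions:
        member = community.member_of[r.id]
        if not member or r.is_biomass:
            continue
        j = idx[r.id]
        mu = idx[community.biomass_ids[member]]
        rows += [n_row, n_row, n_row + 1, n_row + 1]
        cols += [j, mu, j, mu]
        vals += [1.0, -community.coupling, -1.0, -community.coupling]
        n_row += 2
    A_ub = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_row, len(rxn_ids))
    ) if n_row else None
    b_ub = np.zeros(n_row) if n_row else None
    return S, idx, bounds, A_ub, b_ub, rxn_ids


def community_fba(
    community: CommunityModel, medium: Medium, tol: float = DEFAULT_TOL
) -> tuple[float, float, str, dict[str, float]]:
    """Two-stage community FBA.

    Stage 1 maximizes mu1 + mu2; stage 2 pins the optimal sum and maximizes
    min(mu1, mu2), giving a deterministic split of degenerate optima.
    Returns ``(j1, j2, status, fluxes)``; infeasibility yields (0, 0).
    """
    S, idx, bounds, A_ub, b_ub, rxn_ids = _community_lp(community, medium)
    m1, m2 = (idx[community.biomass_ids[k]] for k in community.member_ids)
    n = len(rxn_ids)
    c1 = np.zeros(n)
    c1[[m1, m2]] = 1.0
    status, total, _ = solve_lp(c1, S, bounds, maximize=True,
                                A_ub=A_ub, b_ub=b_ub)
    if status != "optimal":
        return 0.0, 0.0, status, {}

    # stage 2: add t with t <= mu1, t <= mu2; keep mu1 + mu2 >= total - tol
    S2 = sparse.hstack([S, sparse.csr_matrix((S.shape[0], 1))], format="csr")
    ub_rows = [A_ub] if A_ub is not None else []
    ub_vecs = [b_ub] if b_ub is not None else []
    if ub_rows:
        ub_rows = [sparse.hstack(
            [A_ub, sparse.csr_matrix((A_ub.shape[0], 1))], format="csr")]
    extra = sparse.lil_matrix((3, n + 1))
    extra[0, m1], extra[0, n] = -1.0, 1.0        # t - mu1 <= 0
    extra[1, m2], extra[1, n] = -1.0, 1.0        # t - mu2 <= 0
    extra[2, m1], extra[2, m2] = -1.0, -1.0      # -(mu1 + mu2) <= -(total - tol)
    ub_rows.append(extra.tocsr())
    ub_vecs.append(np.array([0.0, 0.0, -(total - tol)]))
    A2 = sparse.vstack(ub_rows, format="csr")
    b2 = np.concatenate(ub_vecs)
    c2 = np.zeros(n + 1)
    c2[n] = 1.0
    status2, _, x = solve_lp(c2, S2, bounds + [(None, None)], maximize=True,
                             A_ub=A2, b_ub=b2)
    if status2 != "optimal":  # fall back to the stage-1 split
        _, _, x1 = solve_lp(c1, S, bounds, maximize=True, A_ub=A_ub, b_ub=b_ub)
        return max(x1[m1], 0.0), max(x1[m2], 0.0), status, dict(zip(rxn_ids, x1))
    return max(x[m1], 0.0), max(x[m2], 0.0), "optimal", dict(zip(rxn_ids, x[:n]))


def monoculture_growth(
    model: MetabolicModel, medium: Medium, c: float = DEFAULT_COUPLING
) -> float:
    """Growth rate on the medium with the same coupling as in the community
    (internal reactions limited to |v| <= c * mu)."""
    inert = MetabolicModel(
        id="__inert__",
        metabolites=[Metabolite(id="__x_c", compartment="c")],
        reactions=[Reaction(id="__bm", stoichiometry={"__x_c": -1.0},
                            lower_bound=0.0, upper_bound=0.0, is_biomass=True)],
        biomass_id="__bm",
    )
    community = join_models(model, inert, c=c)
    j1, _, status, _ = community_fba(community, medium)
    return j1 if status == "optimal" else 0.0


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_interaction(
    s1: float, s2: float, j1: float, j2: float, eps: float = DEFAULT_EPS
) -> str:
    """Label the pair from monoculture vs co-culture growth rates.

    Mutualism: j1 > s1 and j2 > s2; competition: j1 < s1 and j2 < s2;
    parasitism: one up, one down; commensalism: one equal, one up;
    amensalism: one equal, one down; neutral: both equal.  Equality is
    |j - s| <= eps * max(s, floor).
    """
    if min(s1, s2, j1, j2) < 0:
        raise ValueError("growth rates must be non-negative")

    def cmp(j: float, s: float) -> int:
        if abs(j - s) <= eps * max(s, EPS_FLOOR):
            return 0
        return 1 if j > s else -1

    d1, d2 = cmp(j1, s1), cmp(j2, s2)
    if d1 > 0 and d2 > 0:
        return "mutualism"
    if d1 < 0 and d2 < 0:
        return "competition"
    if d1 * d2 < 0:
        return "parasitism"
    if d1 == 0 and d2 == 0:
        return "neutral"
    return "commensalism" if d1 > 0 or d2 > 0 else "amensalism"


def evaluate_pair(
    a: MetabolicModel,
    b: MetabolicModel,
    medium: Medium,
    c: float = DEFAULT_COUPLING,
    eps: float = DEFAULT_EPS,
) -> InteractionResult:
    s1 = monoculture_growth(a, medium, c=c)
    s2 = monoculture_growth(b, medium, c=c)
    community = join_models(a, b, c=c)
    j1, j2, status, _ = community_fba(community, medium)
    return InteractionResult(
        member_ids=(a.id, b.id), s1=s1, s2=s2, j1=j1, j2=j2,
        label=classify_interaction(s1, s2, j1, j2, eps=eps), status=status,
    )


def interaction_screen(
    models: list[MetabolicModel],
    medium: Medium,
    c: float = DEFAULT_COUPLING,
    eps: float = DEFAULT_EPS,
) -> tuple[list[InteractionResult], dict[str, float]]:
    """Evaluate all unordered pairs; also return the fraction of pairs per
    interaction label."""
    if len(models) < 2:
        raise ValueError("interaction screen needs at least 2 models")
    results = [
        evaluate_pair(a, b, medium, c=c, eps=eps)
        for a, b in itertools.combinations(models, 2)
    ]
    fractions = {lab: 0.0 for lab in LABELS}
    for res in results:
        fractions[res.label] += 1.0 / len(results)
    return results, fractions


# ---------------------------------------------------------------------------
# Exchanged metabolites
# ---------------------------------------------------------------------------

def exchanged_metabolites(
    community: CommunityModel,
    medium: Medium,
    tol: float = DEFAULT_TOL,
) -> list[tuple[str, str, float]]:
    """Extracellular metabolites one member net-secretes and the other
    net-consumes at the stage-2 optimum.

    Returns ``(metabolite, donor, flux)`` with flux = min(|secretion|,
    |uptake|), i.e. the transferred amount.
    """
    j1, j2, status, fluxes = community_fba(community, medium)
    if status != "optimal":
        return []
    e_mets = [m.id for m in community.metabolites if m.compartment == "e"]
    net = {k: dict.fromkeys(e_mets, 0.0) for k in community.member_ids}
    for r in community.reactions:
        member = community.member_of[r.id]
        if not member:
            continue
        v = fluxes.get(r.id, 0.0)
        for met, coef in r.stoichiometry.items():
            if met in net[member]:
                net[member][met] += coef * v
    ka, kb = community.member_ids
    out = []
    for met in sorted(e_mets):
        pa, pb = net[ka][met], net[kb][met]
        if pa > tol and pb < -tol:
            out.append((met, ka, min(pa, -pb)))
        elif pb > tol and pa < -tol:
            out.append((met, kb, min(pb, -pa)))
    return out
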