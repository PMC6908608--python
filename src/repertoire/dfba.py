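"""Well-mixed dynamic-FBA co-culture simulator.

Each member is a full metabolic model re-optimized every time step with
uptake bounds set by the current metabolite pools; extracellular enzymes
(e.g. a secreted sucrose invertase) are modeled as independent species with
a single conversion reaction among extracellular metabolites and a fixed
abundance.  Pools are in mmol per (unit) culture volume, biomass in gDW/L,
time in hours; the integrator is explicit Euler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fba_core import ModelLP, solve_lp
from .model_io import MetabolicModel

logger = logging.getLogger("repertoire")

DEFAULT_DT = 0.05  # h
DEFAULT_VMAX = 10.0  # mmol/gDW/h hard uptake cap


@dataclass
class EnzymeSpecies:
    """An extracellular enzyme as an independent species: one conversion
    among e-compartment metabolites, fixed abundance, no biomass."""

    id: str
    stoichiometry: dict[str, float]  # negative = substrate, positive = product
    rate_constant: float  # mmol converted per unit enzyme per h
    abundance: float = 1.0

    def validate(self) -> "EnzymeSpecies":
        subs = [m for m, c in self.stoichiometry.items() if c < 0]
        if not subs:
            raise ValueError(f"enzyme {self.id!r}: no substrate")
        if self.rate_constant < 0 or self.abundance < 0:
            raise ValueError(f"enzyme {self.id!r}: negative rate or abundance")
        return self


@dataclass
class CocultureTrajectory:
    times: np.ndarray
    biomass: dict[str, np.ndarray]
    concentrations: dict[str, np.ndarray]
    clamp_events: int = 0
    n_steps: int = 0

    def final_biomass(self, member: str) -> float:
        return float(self.biomass[member][-1])

    def biomass_gain(self, member: str) -> float:
        return float(self.biomass[member][-1] - self.biomass[member][0])


def simulate_coculture(
    members: list[MetabolicModel],
    enzymes: list[EnzymeSpecies],
    init_biomass: dict[str, float],
    init_conc: dict[str, float],
    dt: float = DEFAULT_DT,
    t_end: float = 10.0,
    vmax: float = DEFAULT_VMAX,
) -> CocultureTrajectory:
    """Explicit-Euler dFBA of a well-mixed co-culture.

    Per step each member's exchange lower bound for metabolite m is
    ``-min(vmax, conc_m / (total_biomass * dt))`` so that the pool cannot be
    overdrawn even if every member takes its maximum; each member's FBA is
    solved independently (monoculture LP), biomass and pools are updated from
    the biomass and exchange fluxes, and enzyme conversions are applied at
    ``rate_constant * abundance`` capped by substrate availability.  LP
    failures zero that member's growth for the step; negative pools are
    clamped to zero and counted.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if any(x < 0 for x in init_biomass.values()) or any(
            x < 0 for x in init_conc.values()):
        raise ValueError("initial amounts must be non-negative")
    for enz in enzymes:
        enz.validate()

    lps = {m.id: ModelLP(m) for m in members}
    ex_map = {
        m.id: {next(iter(r.stoichiometry)): r.id
               for r in m.reactions if r.is_exchange}
        for m in members
    }
    mets = sorted(
        set(init_conc)
        | {met for m in members for met in ex_map[m.id]}
        | {met for e in enzymes for met in e.stoichiometry}
    )
    conc = {met: float(init_conc.get(met, 0.0)) for met in mets}
    X = {m.id: float(init_biomass.get(m.id, 0.0)) for m in members}

    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    bio_traj = {k: np.empty(n_steps + 1) for k in X}
    conc_traj = {met: np.empty(n_steps + 1) for met in mets}
    clamps = 0

    def record(i: int) -> None:
        for k in X:
            bio_traj[k][i] = X[k]
        for met in mets:
            conc_traj[met][i] = conc[met]

    record(0)
    for step in range(n_steps):
        total_X = sum(X.values())
        delta = dict.fromkeys(mets, 0.0)
        for model in members:
            lp = lps[model.id]
            if X[model.id] <= 0:
                continue
            for met, rid in ex_map[model.id].items():
                avail = conc[met] / (total_X * dt) if total_X > 0 else 0.0
                lp.set_bound(rid, lower=-min(vmax, max(avail, 0.0)))
            status, mu, x = solve_lp(
                lp.objective_vector(model.biomass_id), lp.S, lp.bounds,
                maximize=True,
            )
            if status != "optimal":
                logger.warning("dFBA: %s LP %s at t=%.3f; growth 0 this step",
                               model.id, status, step * dt)
                continue
            for met, rid in ex_map[model.id].items():
                delta[met] += x[lp.rxn_idx[rid]] * X[model.id] * dt
            X[model.id] += mu * X[model.id] * dt
        for enz in enzymes:
            cap = enz.rate_constant * enz.abundance
            for met, coef in enz.stoichiometry.items():
                if coef < 0:
                    cap = min(cap, conc[met] / (dt * -coef))
            if cap > 0:
                for met, coef in enz.stoichiometry.items():
                    delta[met] += coef * cap * dt
        for met in mets:
            conc[met] += delta[met]
            if conc[met] < 0:
                if conc[met] < -1e-9:
                    clamps += 1
                    logger.debug("dFBA: clamped %s (%.3g) at step %d",
                                 met, conc[met], step)
                conc[met] = 0.0
        record(step + 1)

    return CocultureTrajectory(
        times=times, biomass=bio_traj, concentrations=conc_traj,
        clamp_events=clamps, n_steps=n_steps,
    )


def monoculture(
    member: MetabolicModel,
    init_biomass: float,
    medium_conc: dict[str, float],
    dt: float = DEFAULT_DT,
    t_end: float = 10.0,
    vmax: float = DEFAULT_VMAX,
) -> CocultureTrajectory:
    """Single-member special case of :func:`simulate_coculture`."""
    return simulate_coculture(
        [member], [], {member.id: init_biomass}, medium_conc,
        dt=dt, t_end=t_end, vmax=vmax,
    )
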