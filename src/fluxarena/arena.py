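"""Spatial agent-based dynamic FBA co-culture simulator.

Bacterial agents live on a rectangular grid sharing per-cell substrate
fields.  Each timestep, every agent (in a freshly shuffled order) solves an
FBA problem whose exchange uptake bounds are tightened by the substrate
amount available in its own grid cell, grows exponentially at the resulting
rate, writes its exchange fluxes back into the local substrate pools,
divides when large enough into a free neighboring cell, and finally each
substrate field mixes with its von Neumann neighbors.  Replenished fields
(oxygen, by default, at 0.1 mM — a microaerobic environment) are reset to
their initial concentration after mixing.

Units: biomass pg (1 pg = 1e−12 gDW), substrate amounts fmol per cell
(1 fmol = 1e−12 mmol), fluxes mmol·gDW⁻¹·h⁻¹, time h.  The pg/fmol pairing
makes the bookkeeping exact: a flux v carried by an agent of b pg for dt h
moves v·b·dt fmol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .media import Medium
from .model_core import FluxSolution, FluxStatus, MetabolicModel, solve_fba

__all__ = [
    "Agent",
    "SubstrateField",
    "ArenaConfig",
    "Arena",
    "SimulationResult",
    "init_arena",
    "simulate",
    "run_replicates",
    "production_curve",
    "write_result_tsvs",
]

logger = logging.getLogger(__name__)

#: fmol per mmol
FMOL_PER_MMOL = 1e12


@dataclass
class Agent:
    agent_id: int
    species_id: str
    biomass: float  # pg
    position: tuple[int, int]


@dataclass
class SubstrateField:
    metabolite_id: str
    amounts: np.ndarray  # fmol per cell
    diffusion_rate: float
    replenished: bool
    initial_per_cell: float  # fmol, used to reset replenished fields

    def total(self) -> float:
        return float(self.amounts.sum())


@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry, timing and biomass policy.

    ``capacity`` defaults to rows × cols × division_threshold (each grid
    cell can carry one agent of roughly threshold size), which gives the
    750 pg total cap at the default 20×20 geometry.  ``cell_volume_L``
    defaults to a 1 µL arena split evenly over the grid.
    """

    rows: int = 20
    cols: int = 20
    cell_volume_L: float | None = None
    dt: float = 1.0  # h
    horizon: float = 45.0  # h
    division_threshold: float = 1.875  # pg
    capacity: float | None = None  # pg, None → rows*cols*division_threshold
    initial_agent_biomass: float | None = None  # pg, None → threshold/2
    oxygen_mM: float = 0.1
    oxygen_metabolite_id: str = "cpd_o2"
    diffusion_rate: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n_steps = self.horizon / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("horizon must be a multiple of dt")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    @property
    def effective_cell_volume(self) -> float:
        return self.cell_volume_L if self.cell_volume_L is not None else 1e-6 / self.n_cells

    @property
    def effective_capacity(self) -> float:
        return (
            self.capacity
            if self.capacity is not None
            else self.n_cells * self.division_threshold
        )

    @property
    def effective_initial_biomass(self) -> float:
        return (
            self.initial_agent_biomass
            if self.initial_agent_biomass is not None
            else self.division_threshold / 2.0
        )

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))


@dataclass
class SimulationResult:
    """Per-timestep record of a single arena run.

    ``exchange_series[s][k]`` is the biomass-weighted mean exchange flux of
    species ``s`` during the step ending at ``times[k]`` (empty at t=0);
    ``exchange_amounts[s][k]`` is the net fmol each metabolite moved by that
    species in the same step (secretion positive), which lets totals be
    re-derived without the flux→amount conversion.
    """

    times: np.ndarray
    biomass_series: dict[str, np.ndarray]
    concentration_series: dict[str, np.ndarray]  # arena-mean mM
    exchange_series: dict[str, list[dict[str, float]]]
    exchange_amounts: dict[str, list[dict[str, float]]]
    rng_seed: int
    config: ArenaConfig

    @property
    def species(self) -> list[str]:
        return list(self.biomass_series)

    def final_biomass(self, species_id: str) -> float:
        return float(self.biomass_series[species_id][-1])

    def total_final_biomass(self) -> float:
        return float(sum(b[-1] for b in self.biomass_series.values()))


_NEIGHBOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


class Arena:
    """Mutable simulation state; advanced in place by :meth:`step`."""

    def __init__(
        self,
        models: Mapping[str, MetabolicModel],
        fields: dict[str, SubstrateField],
        agents: list[Agent],
        config: ArenaConfig,
        rng: np.random.Generator,
    ):
        self.models = dict(models)
        self.fields = fields
        self.agents = agents
        self.config = config
        self.rng = rng
        self.time = 0.0
        self._next_agent_id = max((a.agent_id for a in agents), default=-1) + 1
        self._occupied = {a.position for a in agents}
        self._fba_cache: dict = {}
        self._neighbor_count = _neighbor_counts(config.rows, config.cols)
        # per-step exchange records, populated by step()
        self.last_step_fluxes: dict[str, dict[str, float]] = {}
        self.last_step_amounts: dict[str, dict[str, float]] = {}

    # ------------------------------------------------------------------
    def total_biomass(self) -> float:
        return sum(a.biomass for a in self.agents)

    def species_biomass(self) -> dict[str, float]:
        out = {s: 0.0 for s in self.models}
        for a in self.agents:
            out[a.species_id] += a.biomass
        return out

    def _free_neighbors(self, pos: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = pos
        out = []
        for dr, dc in _NEIGHBOR_OFFSETS:
            q = (r + dr, c + dc)
            if 0 <= q[0] < self.config.rows and 0 <= q[1] < self.config.cols:
                if q not in self._occupied:
                    out.append(q)
        return out

    def _solve_agent(self, agent: Agent) -> FluxSolution:
        """FBA with uptake bounds capped by local substrate availability."""
        model = self.models[agent.species_id]
        dt = self.config.dt
        overrides: dict[str, tuple[float, float]] = {}
        for rxn in model.exchange_reactions:
            if rxn.lower_bound >= 0:
                continue
            fld = self.fields.get(rxn.exchanged_metabolite)
            avail = fld.amounts[agent.position] if fld is not None else 0.0
            # fmol / (pg · h) == mmol / (gDW · h)
            max_uptake = avail / (agent.biomass * dt)
            eff_lb = -min(-rxn.lower_bound, max_uptake)
            if eff_lb != rxn.lower_bound:
                overrides[rxn.id] = (eff_lb, rxn.upper_bound)
        key = (agent.species_id, tuple(sorted(overrides.items())))
        sol = self._fba_cache.get(key)
        if sol is None:
            sol = solve_fba(model, overrides or None)
            self._fba_cache[key] = sol
        return sol

    # ------------------------------------------------------------------
    def step(self) -> None:
        """Advance the arena by one dt.

        Per agent (shuffled order): tighten uptake bounds by local
        availability, solve FBA, apply exchange fluxes to the local cell,
        grow exponentially (capped by 2×division threshold and the arena
        capacity), divide into a free neighbor when at threshold.  Then
        every field diffuses (conservatively, closed boundaries) and
        replenished fields are reset.
        """
        cfg = self.config
        dt = cfg.dt
        capacity = cfg.effective_capacity
        total = self.total_biomass()

        step_fluxweight: dict[str, dict[str, float]] = {s: {} for s in self.models}
        step_amounts: dict[str, dict[str, float]] = {s: {} for s in self.models}
        solve_weight: dict[str, float] = {s: 0.0 for s in self.models}

        order = self.rng.permutation(len(self.agents))
        newborns: list[Agent] = []
        for idx in order:
            agent = self.agents[idx]
            b0 = agent.biomass
            sol = self._solve_agent(agent)
            solve_weight[agent.species_id] += b0
            mu = sol.growth_rate if sol.optimal else 0.0

            if sol.optimal:
                model = self.models[agent.species_id]
                for rxn in model.exchange_reactions:
                    v = sol.fluxes.get(rxn.id, 0.0)
                    acc = step_fluxweight[agent.species_id]
                    acc[rxn.id] = acc.get(rxn.id, 0.0) + v * b0
                    if v == 0.0:
                        continue
                    met = rxn.exchanged_metabolite
                    delta = v * b0 * dt  # fmol, secretion positive
                    fld = self.fields.get(met)
                    if fld is not None:
                        new_amt = fld.amounts[agent.position] + delta
                        # the availability bound guarantees non-negativity;
                        # only float dust is swept here
                        if new_amt < 0:
                            if new_amt < -1e-6:
                                raise AssertionError(
                                    f"substrate {met} overdrawn by {new_amt} fmol"
                                )
                            new_amt = 0.0
                        fld.amounts[agent.position] = new_amt
                    amts = step_amounts[agent.species_id]
                    amts[met] = amts.get(met, 0.0) + delta

            if mu > 0:
                gain = b0 * (np.expm1(mu * dt))
                gain = min(gain, 2 * cfg.division_threshold - b0, capacity - total)
                if gain > 0:
                    agent.biomass = b0 + gain
                    total += gain

            if agent.biomass >= cfg.division_threshold:
                free = self._free_neighbors(agent.position)
                if free:  # otherwise division is deferred to a later step
                    child_pos = free[self.rng.integers(len(free))]
                    half = agent.biomass / 2.0
                    agent.biomass = half
                    child = Agent(
                        agent_id=self._next_agent_id,
                        species_id=agent.species_id,
                        biomass=half,
                        position=child_pos,
                    )
                    self._next_agent_id += 1
                    self._occupied.add(child_pos)
                    newborns.append(child)
        self.agents.extend(newborns)

        for fld in self.fields.values():
            _diffuse(fld, self._neighbor_count)
            if fld.replenished:
                fld.amounts[:] = fld.initial_per_cell

        self.time += dt
        self.last_step_fluxes = {
            s: {
                rid: (w / solve_weight[s] if solve_weight[s] > 0 else 0.0)
                for rid, w in acc.items()
            }
            for s, acc in step_fluxweight.items()
        }
        self.last_step_amounts = step_amounts


def _neighbor_counts(rows: int, cols: int) -> np.ndarray:
    k = np.full((rows, cols), 4.0)
    k[0, :] -= 1
    k[-1, :] -= 1
    k[:, 0] -= 1
    k[:, -1] -= 1
    return k


def _diffuse(fld: SubstrateField, k: np.ndarray) -> None:
    """One conservative mixing step with von Neumann neighbors.

    Each cell sends ``diffusion_rate`` of its amount, split equally among
    its in-grid neighbors; closed boundaries.  Total is conserved exactly
    (up to float rounding) because everything sent is received.
    """
    d = fld.diffusion_rate
    if d == 0:
        return
    A = fld.amounts
    share = d * A / k
    inflow = np.zeros_like(A)
    inflow[1:, :] += share[:-1, :]
    inflow[:-1, :] += share[1:, :]
    inflow[:, 1:] += share[:, :-1]
    inflow[:, :-1] += share[:, 1:]
    fld.amounts = A - d * A + inflow


# ---------------------------------------------------------------------------
# Construction and the simulation driver
# ---------------------------------------------------------------------------


def init_arena(
    models: Sequence[MetabolicModel],
    medium: Medium,
    inoculum: Mapping[str, int],
    config: ArenaConfig | None = None,
) -> Arena:
    """Place agents uniformly at random on distinct cells and fill fields.

    Each medium concentration c (mM) becomes a per-cell amount
    c × cell_volume (in fmol).  Metabolites exchanged by any model but
    absent from the medium start at zero; medium metabolites unknown to
    every model are tracked anyway (with a warning).  Oxygen is added at
    ``config.oxygen_mM`` (replenished) unless the medium already sets it.
    """
    config = config or ArenaConfig()
    model_map = {m.species_id: m for m in models}
    if len(model_map) != len(models):
        raise ValueError("species ids must be distinct")
    unknown = set(inoculum) - set(model_map)
    if unknown:
        raise ValueError(f"inoculum references unknown species {sorted(unknown)}")
    total_agents = sum(inoculum.values())
    if total_agents > config.n_cells:
        raise ValueError(
            f"inoculum of {total_agents} agents exceeds the {config.n_cells}-cell grid"
        )

    rng = np.random.default_rng(config.rng_seed)

    exchanged = {
        r.exchanged_metabolite for m in models for r in m.exchange_reactions
    }
    for met in medium.components:
        if met not in exchanged:
            logger.warning(
                "medium metabolite %s is not exchanged by any model; tracked anyway",
                met,
            )

    components = dict(medium.components)
    replenished = set(medium.replenished_set)
    if config.oxygen_metabolite_id not in components and config.oxygen_mM > 0:
        components[config.oxygen_metabolite_id] = config.oxygen_mM
        replenished.add(config.oxygen_metabolite_id)

    cell_vol = config.effective_cell_volume
    fields: dict[str, SubstrateField] = {}
    for met in sorted(exchanged | set(components)):
        conc = components.get(met, 0.0)
        per_cell = conc * cell_vol * FMOL_PER_MMOL
        fields[met] = SubstrateField(
            metabolite_id=met,
            amounts=np.full((config.rows, config.cols), per_cell),
            diffusion_rate=config.diffusion_rate,
            replenished=met in replenished,
            initial_per_cell=per_cell,
        )

    agents: list[Agent] = []
    if total_agents:
        cells = rng.choice(config.n_cells, size=total_agents, replace=False)
        i = 0
        b0 = config.effective_initial_biomass
        for species in sorted(inoculum):
            for _ in range(inoculum[species]):
                pos = (int(cells[i] // config.cols), int(cells[i] % config.cols))
                agents.append(Agent(agent_id=i, species_id=species, biomass=b0, position=pos))
                i += 1

    return Arena(model_map, fields, agents, config, rng)


def simulate(
    models: Sequence[MetabolicModel],
    medium: Medium,
    inoculum: Mapping[str, int],
    config: ArenaConfig | None = None,
) -> SimulationResult:
    """Run horizon/dt steps recording biomass, concentrations and fluxes.

    A fixed ``config.rng_seed`` gives a bitwise-identical result.
    """
    config = config or ArenaConfig()
    arena = init_arena(models, medium, inoculum, config)
    species = sorted(arena.models)
    n_cells = config.n_cells
    vol_L = n_cells * config.effective_cell_volume

    times = [0.0]
    biomass = {s: [arena.species_biomass()[s]] for s in species}
    conc = {m: [f.total() / FMOL_PER_MMOL / vol_L] for m, f in arena.fields.items()}
    fluxes: dict[str, list[dict[str, float]]] = {s: [{}] for s in species}
    amounts: dict[str, list[dict[str, float]]] = {s: [{}] for s in species}

    for _ in range(config.n_steps):
        arena.step()
        times.append(arena.time)
        sb = arena.species_biomass()
        for s in species:
            biomass[s].append(sb[s])
            fluxes[s].append(arena.last_step_fluxes.get(s, {}))
            amounts[s].append(arena.last_step_amounts.get(s, {}))
        for m, f in arena.fields.items():
            conc[m].append(f.total() / FMOL_PER_MMOL / vol_L)

    return SimulationResult(
        times=np.array(times),
        biomass_series={s: np.array(v) for s, v in biomass.items()},
        concentration_series={m: np.array(v) for m, v in conc.items()},
        exchange_series=fluxes,
        exchange_amounts=amounts,
        rng_seed=config.rng_seed,
        config=config,
    )


def run_replicates(
    models: Sequence[MetabolicModel],
    medium: Medium,
    inoculum: Mapping[str, int],
    config: ArenaConfig | None = None,
    n_runs: int = 12,
    base_seed: int | None = None,
) -> tuple[SimulationResult, list[SimulationResult]]:
    """n independent seeded runs (seeds base_seed..base_seed+n−1) and their
    per-timepoint mean.  Defaults to the 12-replicate growth-curve protocol;
    pass ``n_runs=100`` for metabolite-production profiling."""
    if n_runs < 1:
        raise ValueError("n_runs must be ≥ 1")
    config = config or ArenaConfig()
    if base_seed is None:
        base_seed = config.rng_seed
    runs = [
        simulate(models, medium, inoculum, replace(config, rng_seed=base_seed + i))
        for i in range(n_runs)
    ]
    first = runs[0]
    mean_biomass = {
        s: np.mean([r.biomass_series[s] for r in runs], axis=0) for s in first.species
    }
    mean_conc = {
        m: np.mean([r.concentration_series[m] for r in runs], axis=0)
        for m in first.concentration_series
    }
    mean_fluxes: dict[str, list[dict[str, float]]] = {}
    for s in first.species:
        per_time = []
        for k in range(len(first.times)):
            rids = set().union(*(r.exchange_series[s][k] for r in runs))
            per_time.append(
                {
                    rid: float(
                        np.mean([r.exchange_series[s][k].get(rid, 0.0) for r in runs])
                    )
                    for rid in rids
                }
            )
        mean_fluxes[s] = per_time
    mean = SimulationResult(
        times=first.times.copy(),
        biomass_series=mean_biomass,
        concentration_series=mean_conc,
        exchange_series=mean_fluxes,
        exchange_amounts={s: [{} for _ in first.times] for s in first.species},
        rng_seed=base_seed,
        config=config,
    )
    return mean, runs


def production_curve(result: SimulationResult, metabolite_id: str) -> pd.DataFrame:
    """Arena-total amount of one metabolite over time (fmol and mM).

    Negative net change relative to t=0 reads as consumption.
    """
    if metabolite_id not in result.concentration_series:
        raise KeyError(
            f"metabolite {metabolite_id!r} not tracked; known: "
            f"{sorted(result.concentration_series)}"
        )
    cfg = result.config
    vol_L = cfg.n_cells * cfg.effective_cell_volume
    mM = result.concentration_series[metabolite_id]
    fmol = mM * vol_L * FMOL_PER_MMOL
    return pd.DataFrame(
        {"time_h": result.times, "amount_fmol": fmol, "concentration_mM": mM}
    )


def write_result_tsvs(result: SimulationResult, outdir) -> None:
    """Tidy TSV writers: biomass.tsv, media.tsv, exchanges.tsv."""
    import os

    os.makedirs(outdir, exist_ok=True)
    rows = [
        {"time_h": t, "species": s, "biomass_pg": result.biomass_series[s][k]}
        for k, t in enumerate(result.times)
        for s in result.species
    ]
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "biomass.tsv"), sep="\t", index=False)
    rows = [
        {"time_h": t, "metabolite": m, "concentration_mM": result.concentration_series[m][k]}
        for k, t in enumerate(result.times)
        for m in sorted(result.concentration_series)
    ]
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "media.tsv"), sep="\t", index=False)
    rows = [
        {"time_h": t, "species": s, "reaction": rid, "flux": v}
        for k, t in enumerate(result.times)
        for s in result.species
        for rid, v in sorted(result.exchange_series[s][k].items())
    ]
    pd.DataFrame(rows, columns=["time_h", "species", "reaction", "flux"]).to_csv(
        os.path.join(outdir, "exchanges.tsv"), sep="\t", index=False
    )
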