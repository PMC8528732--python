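"""In-silico experiment designs: growth grids, interaction calls, screens.

Three designs built on the arena simulator:

* a mono/pair growth grid over media, binning total final biomass into
  weak (0–250 pg), intermediate (250–500 pg), strong (500–750 pg);
* interaction classification per species pair from mono- vs co-culture
  final biomasses (competition / inhibition / stimulation / neutral);
* a single-metabolite supplementation screen ("prebiotic" search) and its
  dose–response variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from itertools import combinations
from typing import Callable, Mapping, Sequence

import pandas as pd

from .arena import ArenaConfig, run_replicates, simulate
from .media import Medium
from .model_core import Compartment, MetabolicModel

__all__ = [
    "BIN_EDGES_PG",
    "GrowthGridCell",
    "ScreenRecord",
    "biomass_bin",
    "growth_grid",
    "classify_interaction",
    "supplementation_screen",
    "dose_response",
    "grid_frame",
    "screen_frame",
]

#: printed bin edges for total produced biomass (pg)
BIN_EDGES_PG = (250.0, 500.0, 750.0)

#: default agents inoculated per species in grids and screens
DEFAULT_INOCULUM = 10


def biomass_bin(total_pg: float) -> str:
    """weak [0, 250), intermediate [250, 500), strong [500, 750]."""
    if total_pg < BIN_EDGES_PG[0]:
        return "weak"
    if total_pg < BIN_EDGES_PG[1]:
        return "intermediate"
    return "strong"


@dataclass(frozen=True)
class GrowthGridCell:
    species_a: str
    species_b: str  # "" for mono-culture
    medium: str
    final_biomass: dict[str, float]  # pg per species at horizon
    bin: str

    @property
    def total(self) -> float:
        return sum(self.final_biomass.values())


@dataclass(frozen=True)
class ScreenRecord:
    metabolite_id: str
    dose_mM: float
    baseline_final: float
    supplemented_final: float
    fold_change: float
    promoting: bool
    applicable: bool = True


def _default_genus(species_id: str) -> str:
    return species_id.split("_")[0]


def growth_grid(
    models: Sequence[MetabolicModel],
    media: Sequence[Medium],
    config: ArenaConfig | None = None,
    n_runs: int = 12,
    inoculum_per_species: int = DEFAULT_INOCULUM,
    all_pairs: bool = False,
    genus_of: Callable[[str], str] = _default_genus,
) -> list[GrowthGridCell]:
    """Mean final biomass of every singleton and pair on every medium.

    Pairs are restricted to cross-genus combinations unless ``all_pairs``;
    each grid cell runs ``n_runs`` seeded replicates and records the mean
    final biomass per species plus its bin.
    """
    if not models or not media:
        raise ValueError("need at least one model and one medium")
    config = config or ArenaConfig()
    combos: list[tuple[MetabolicModel, ...]] = [(m,) for m in models]
    for a, b in combinations(models, 2):
        if all_pairs or genus_of(a.species_id) != genus_of(b.species_id):
            combos.append((a, b))
    cells = []
    for medium in media:
        for combo in combos:
            inoc = {m.species_id: inoculum_per_species for m in combo}
            mean, _ = run_replicates(list(combo), medium, inoc, config, n_runs=n_runs)
            finals = {s: mean.final_biomass(s) for s in mean.species}
            cells.append(
                GrowthGridCell(
                    species_a=combo[0].species_id,
                    species_b=combo[1].species_id if len(combo) > 1 else "",
                    medium=medium.name,
                    final_biomass=finals,
                    bin=biomass_bin(sum(finals.values())),
                )
            )
    return cells


def classify_interaction(
    mono_a: float,
    mono_b: float,
    pair_a: float,
    pair_b: float,
    sigma: float = 2.0,
    iota: float = 0.5,
    boundary_tol: float = 0.15,
) -> tuple[str, str]:
    """Interaction label per species from mono vs co-culture final biomass.

    Per species: *stimulation* when the co-culture biomass is at least
    σ× the mono value; *inhibition* when it drops to ≤ ι× mono while the
    partner is not decreased; *competition* when both species decrease;
    otherwise *neutral*.  Symmetric under swapping the two species.

    ``boundary_tol`` widens the decrease threshold multiplicatively: two
    identical competitors split a saturated arena at *exactly* ι = 0.5 of
    their mono-culture value, so a single stochastic run needs slack at
    that boundary to classify as competition.
    """

    def decreased(mono: float, pair: float) -> bool:
        return mono > 0 and pair <= iota * (1.0 + boundary_tol) * mono

    def increased(mono: float, pair: float) -> bool:
        if mono == 0:
            return pair > 0
        return pair >= sigma * mono

    dec_a, dec_b = decreased(mono_a, pair_a), decreased(mono_b, pair_b)
    if dec_a and dec_b:
        return ("competition", "competition")

    def label(mono, pair, dec_self, dec_other):
        if mono == 0 and pair == 0:
            return "neutral"
        if increased(mono, pair):
            return "stimulation"
        if dec_self and not dec_other:
            return "inhibition"
        return "neutral"

    return (
        label(mono_a, pair_a, dec_a, dec_b),
        label(mono_b, pair_b, dec_b, dec_a),
    )


def _medium_namespace(model: MetabolicModel, medium: Medium) -> set[str]:
    external = {
        m.id for m in model.metabolites if m.compartment is Compartment.external
    }
    return external | set(medium.components)


def supplementation_screen(
    model: MetabolicModel,
    base_medium: Medium,
    candidates: Sequence[str],
    dose_mM: float = 10.0,
    config: ArenaConfig | None = None,
    fold_threshold: float = 2.0,
    min_gain_pg: float = 10.0,
    inoculum_count: int = DEFAULT_INOCULUM,
) -> list[ScreenRecord]:
    """Rank single-metabolite supplements by growth fold-change.

    Each candidate is added to the base medium at ``dose_mM`` and a
    mono-culture is simulated; ``promoting`` requires both the fold-change
    and an absolute biomass gain of at least ``min_gain_pg``.  A candidate
    unknown to both the model's external metabolites and the medium is
    recorded as not applicable rather than failing.  Deterministic given
    the config seed.
    """
    if dose_mM < 0:
        raise ValueError("dose must be ≥ 0")
    if not candidates:
        raise ValueError("candidate list is empty")
    config = config or ArenaConfig()
    inoc = {model.species_id: inoculum_count}
    baseline = simulate([model], base_medium, inoc, config).final_biomass(
        model.species_id
    )
    namespace = _medium_namespace(model, base_medium)
    records = []
    for met in candidates:
        if met not in namespace:
            records.append(
                ScreenRecord(met, dose_mM, baseline, math.nan, math.nan, False, False)
            )
            continue
        supplemented = simulate(
            [model], base_medium.supplement(met, dose_mM), inoc, config
        ).final_biomass(model.species_id)
        fold = supplemented / baseline if baseline > 0 else math.inf
        promoting = fold >= fold_threshold and (supplemented - baseline) >= min_gain_pg
        records.append(
            ScreenRecord(met, dose_mM, baseline, supplemented, fold, promoting)
        )
    records.sort(
        key=lambda r: (-(r.fold_change) if r.applicable else math.inf, r.metabolite_id)
    )
    return records


def dose_response(
    model: MetabolicModel,
    base_medium: Medium,
    metabolite_id: str,
    doses_mM: Sequence[float],
    config: ArenaConfig | None = None,
    inoculum_count: int = DEFAULT_INOCULUM,
) -> pd.DataFrame:
    """Final biomass of a mono-culture per supplementation dose.

    Monotonicity is not assumed, only reported.
    """
    if any(d < 0 for d in doses_mM):
        raise ValueError("doses must be ≥ 0")
    config = config or ArenaConfig()
    inoc = {model.species_id: inoculum_count}
    rows = []
    for dose in doses_mM:
        medium = base_medium.supplement(metabolite_id, dose) if dose else base_medium
        final = simulate([model], medium, inoc, config).final_biomass(model.species_id)
        rows.append({"dose_mM": dose, "final_biomass_pg": final})
    return pd.DataFrame(rows)


def grid_frame(cells: Sequence[GrowthGridCell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        rows.append(
            {
                "species_a": c.species_a,
                "species_b": c.species_b,
                "medium": c.medium,
                "biomass_a_pg": c.final_biomass.get(c.species_a, 0.0),
                "biomass_b_pg": c.final_biomass.get(c.species_b, 0.0) if c.species_b else 0.0,
                "total_pg": c.total,
                "bin": c.bin,
            }
        )
    return pd.DataFrame(rows)


def screen_frame(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite_id": r.metabolite_id,
                "dose_mM": r.dose_mM,
                "baseline_final_pg": r.baseline_final,
                "supplemented_final_pg": r.supplemented_final,
                "fold_change": r.fold_change,
                "promoting": r.promoting,
                "applicable": r.applicable,
            }
            for r in records
        ]
    )
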