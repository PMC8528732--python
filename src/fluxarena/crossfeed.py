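"""Cross-feeding detection via relative flux ratios between two species.

For each exchange reaction and timepoint, the ratio r = vA/vB of the two
species' (biomass-weighted mean) exchange fluxes is formed; when r falls
strictly between −1 and 1 its reciprocal is reported instead, so the
statistic always highlights the larger flux and has magnitude ≥ 1.  A
negative sign means opposite transport directions — one species secretes
what the other takes up — and a persistently negative ratio across the
time course is called as a metabolite exchange.  Reactions where either
flux is (numerically) zero, or which one model lacks, are NOT_SHARED.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arena import SimulationResult
from .model_core import MetabolicModel

__all__ = [
    "NOT_SHARED",
    "FluxRatioEntry",
    "flux_ratio",
    "ratio_matrix",
    "ratio_matrices_over_time",
    "detect_exchanged",
    "ratio_matrix_frame",
]

#: flux magnitudes below this count as "not transported" (LP solver noise)
ZERO_FLUX_TOL = 1e-8

#: sentinel for reactions not shared between the two species at a timepoint
NOT_SHARED = "NOT_SHARED"


@dataclass(frozen=True)
class FluxRatioEntry:
    reaction_id: str
    time: float
    value: float | str  # ratio (|value| ≥ 1) or NOT_SHARED
    numerator_species: str
    denominator_species: str

    @property
    def shared(self) -> bool:
        return self.value != NOT_SHARED


def flux_ratio(vA: float, vB: float, zero_tol: float = ZERO_FLUX_TOL):
    """Relative flux ratio of two exchange fluxes for one reaction/timepoint.

    r = vA/vB; if −1 < r < 1 the reciprocal 1/r is returned instead, so the
    magnitude is always ≥ 1.  Either flux being zero (within ``zero_tol``)
    means the reaction is only transported by one species: NOT_SHARED.
    """
    if abs(vA) < zero_tol or abs(vB) < zero_tol:
        return NOT_SHARED
    r = vA / vB
    if -1.0 < r < 1.0:
        return 1.0 / r
    return r


def _series_at(result: SimulationResult, species: str, time: float) -> dict[str, float]:
    times = result.times
    idx = np.nonzero(np.isclose(times, time))[0]
    if not len(idx):
        raise ValueError(
            f"time {time} not on the recorded grid; available: {times.tolist()}"
        )
    return result.exchange_series[species][int(idx[0])]


def ratio_matrix(
    result_a: SimulationResult,
    result_b: SimulationResult,
    species_a: str,
    species_b: str,
    time: float = 32.0,
    model_a: MetabolicModel | None = None,
    model_b: MetabolicModel | None = None,
) -> dict[str, FluxRatioEntry]:
    """One FluxRatioEntry per exchange reaction present in either species.

    ``result_a`` and ``result_b`` may be the same object (a co-culture run).
    The default snapshot time is 32 h.  Passing the models widens the
    reaction universe to every exchange reaction either model declares;
    otherwise the union of reactions ever reported in the series is used.
    Reactions absent from one side are NOT_SHARED ("not present").
    """
    va = _series_at(result_a, species_a, time)
    vb = _series_at(result_b, species_b, time)
    if model_a is not None and model_b is not None:
        universe = {r.id for r in model_a.exchange_reactions} | {
            r.id for r in model_b.exchange_reactions
        }
        known_a = {r.id for r in model_a.exchange_reactions}
        known_b = {r.id for r in model_b.exchange_reactions}
    else:
        known_a = set().union(*result_a.exchange_series[species_a]) if any(
            result_a.exchange_series[species_a]
        ) else set()
        known_b = set().union(*result_b.exchange_series[species_b]) if any(
            result_b.exchange_series[species_b]
        ) else set()
        universe = known_a | known_b
    out = {}
    for rid in sorted(universe):
        if rid not in known_a or rid not in known_b:
            value: float | str = NOT_SHARED
        else:
            value = flux_ratio(va.get(rid, 0.0), vb.get(rid, 0.0))
        out[rid] = FluxRatioEntry(
            reaction_id=rid,
            time=time,
            value=value,
            numerator_species=species_a,
            denominator_species=species_b,
        )
    return out


def ratio_matrices_over_time(
    result_a: SimulationResult,
    result_b: SimulationResult,
    species_a: str,
    species_b: str,
    times: Sequence[float] | None = None,
    **kwargs,
) -> list[dict[str, FluxRatioEntry]]:
    """Ratio matrices at every (post-initial) recorded timepoint."""
    if times is None:
        times = result_a.times[1:]
    return [
        ratio_matrix(result_a, result_b, species_a, species_b, float(t), **kwargs)
        for t in times
    ]


def detect_exchanged(
    matrices: Iterable[Mapping[str, FluxRatioEntry]],
    reaction_to_metabolite: Mapping[str, str],
    consistency: float = 0.8,
    min_shared_timepoints: int = 3,
) -> list[str]:
    """Metabolites whose exchange ratio is consistently negative.

    A metabolite is flagged when its exchange reaction's ratio is negative
    in at least ``consistency`` of the timepoints where it is shared, and it
    is shared at ≥ ``min_shared_timepoints`` timepoints.  Output is sorted
    by descending mean |ratio| (most prominent exchange first).
    """
    if not (0 < consistency <= 1):
        raise ValueError("consistency must be in (0, 1]")
    shared: dict[str, list[float]] = {}
    for matrix in matrices:
        for rid, entry in matrix.items():
            if entry.shared:
                shared.setdefault(rid, []).append(float(entry.value))
    flagged = []
    for rid, values in shared.items():
        if len(values) < min_shared_timepoints:
            continue
        neg = sum(1 for v in values if v < 0)
        if neg / len(values) >= consistency:
            met = reaction_to_metabolite.get(rid, rid)
            flagged.append((met, float(np.mean(np.abs(values)))))
    flagged.sort(key=lambda pair: -pair[1])
    return [met for met, _ in flagged]


def reaction_metabolite_map(*models: MetabolicModel) -> dict[str, str]:
    """Exchange reaction id → exchanged metabolite id, across models."""
    out: dict[str, str] = {}
    for model in models:
        for rxn in model.exchange_reactions:
            out[rxn.id] = rxn.exchanged_metabolite
    return out


def ratio_matrix_frame(matrix: Mapping[str, FluxRatioEntry]) -> pd.DataFrame:
    """Heatmap-style table: reaction × ratio, NOT_SHARED as NA."""
    rows = [
        {
            "reaction": rid,
            "ratio": (e.value if e.shared else np.nan),
            "shared": e.shared,
            "numerator_species": e.numerator_species,
            "denominator_species": e.denominator_species,
            "time_h": e.time,
        }
        for rid, e in sorted(matrix.items())
    ]
    return pd.DataFrame(rows)
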