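"""Cumulative flux comparison between a supplemented medium and its baseline.

For each reaction the fluxes are first summed over the whole time course in
each medium; the difference of the two sums d = sum_baseline − sum_comparison
is then compressed to a log-scale magnitude log(|d| + 1), which is 0 exactly
when the media leave the reaction's cumulative flux unchanged and grows
monotonically with the discrepancy.  The sign of d is reported alongside
(the magnitude alone discards it).  Reaction groups (e.g. the TCA cycle)
are aggregated by summing the signed differences first, then applying the
log transform, so opposing reroutings within a group can cancel.

The logarithm is natural by default; base 10 is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CumulativeFluxEntry",
    "flux_sum",
    "cumulative_flux",
    "group_cumulative_flux",
    "cumulative_flux_table",
]


@dataclass(frozen=True)
class CumulativeFluxEntry:
    reaction_id: str
    baseline_medium: str
    comparison_medium: str
    sum_baseline: float
    sum_comparison: float
    value: float  # log(|d| + 1) ≥ 0
    sign_of_difference: int  # sign(sum_baseline − sum_comparison)


def flux_sum(series: Sequence[float]) -> float:
    """Signed sum of a reaction's flux values over all timepoints t=0..n."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("flux series is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("flux series contains non-finite values")
    return float(arr.sum())


def _log(x: float, base10: bool) -> float:
    return float(np.log10(x) if base10 else np.log(x))


def cumulative_flux(
    sum_baseline: float,
    sum_comparison: float,
    reaction_id: str = "",
    baseline_medium: str = "baseline",
    comparison_medium: str = "comparison",
    base10: bool = False,
) -> CumulativeFluxEntry:
    """log(|sum_baseline − sum_comparison| + 1), with the sign kept aside."""
    d = sum_baseline - sum_comparison
    return CumulativeFluxEntry(
        reaction_id=reaction_id,
        baseline_medium=baseline_medium,
        comparison_medium=comparison_medium,
        sum_baseline=sum_baseline,
        sum_comparison=sum_comparison,
        value=_log(abs(d) + 1.0, base10),
        sign_of_difference=int(np.sign(d)),
    )


def group_cumulative_flux(
    entries: Iterable[CumulativeFluxEntry],
    group_id: str = "group",
    base10: bool = False,
) -> CumulativeFluxEntry:
    """Group value: signed differences summed first, then log(|·|+1).

    Cancellation inside the group is intentional — the group value measures
    the *net* cumulative rerouting of the set.
    """
    entries = list(entries)
    if not entries:
        raise ValueError("reaction group is empty")
    sb = sum(e.sum_baseline for e in entries)
    sc = sum(e.sum_comparison for e in entries)
    return cumulative_flux(
        sb,
        sc,
        reaction_id=group_id,
        baseline_medium=entries[0].baseline_medium,
        comparison_medium=entries[0].comparison_medium,
        base10=base10,
    )


def cumulative_flux_table(
    baseline_series: Mapping[str, Sequence[float]],
    comparison_series: Mapping[str, Sequence[float]],
    baseline_medium: str = "baseline",
    comparison_medium: str = "comparison",
    base10: bool = False,
) -> pd.DataFrame:
    """Per-reaction cumulative-flux table over the union of reactions.

    A reaction missing from one medium contributes a zero flux sum there.
    Columns: reaction_id, sum_baseline, sum_comparison, signed_diff, value.
    """
    reactions = sorted(set(baseline_series) | set(comparison_series))
    rows = []
    for rid in reactions:
        sb = flux_sum(baseline_series[rid]) if rid in baseline_series else 0.0
        sc = flux_sum(comparison_series[rid]) if rid in comparison_series else 0.0
        entry = cumulative_flux(
            sb, sc, rid, baseline_medium, comparison_medium, base10
        )
        rows.append(
            {
                "reaction_id": rid,
                "sum_baseline": entry.sum_baseline,
                "sum_comparison": entry.sum_comparison,
                "signed_diff": entry.sum_baseline - entry.sum_comparison,
                "value": entry.value,
            }
        )
    return pd.DataFrame(rows)


def species_flux_series(result, species_id: str) -> dict[str, list[float]]:
    """Per-reaction flux time series for one species of a SimulationResult."""
    per_time = result.exchange_series[species_id]
    rids = set().union(*per_time) if per_time else set()
    return {rid: [step.get(rid, 0.0) for step in per_time] for rid in sorted(rids)}
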