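"""Growth-medium tables and supplementation operators.

A medium is a metabolite → concentration (mM) table plus the set of
metabolites held constant during simulation (replenished each step, e.g.
oxygen at 0.1 mM for a microaerobic environment).  Media are loaded from
TSV files with columns ``metabolite_id``, ``concentration_mM``,
``replenished``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = ["Medium", "load_medium", "write_medium", "DOSE_LADDER_MM"]

#: dose ladder used by dose–response screens: 10 nM, 0.1 µM, 0.1 mM, 1 mM, 100 mM
DOSE_LADDER_MM = (1e-5, 1e-4, 0.1, 1.0, 100.0)

_COLUMNS = ["metabolite_id", "concentration_mM", "replenished"]


@dataclass(frozen=True)
class Medium:
    name: str
    components: dict[str, float] = field(default_factory=dict)
    replenished_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for met, conc in self.components.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {met!r}: {conc}")

    def concentration(self, metabolite_id: str) -> float:
        return self.components.get(metabolite_id, 0.0)

    def supplement(self, metabolite_id: str, concentration_mM: float) -> "Medium":
        """Copy of this medium with the component increased by the dose.

        The original is unchanged; the copy's name records the operation.
        """
        if concentration_mM < 0:
            raise ValueError(f"negative dose {concentration_mM}")
        components = dict(self.components)
        components[metabolite_id] = (
            components.get(metabolite_id, 0.0) + concentration_mM
        )
        return replace(
            self,
            name=f"{self.name}+{metabolite_id}@{concentration_mM:g}",
            components=components,
        )

    def dose_ladder(self, metabolite_id: str, doses=DOSE_LADDER_MM) -> list["Medium"]:
        return [self.supplement(metabolite_id, d) for d in doses]


def supplement(medium: Medium, metabolite_id: str, concentration_mM: float) -> Medium:
    return medium.supplement(metabolite_id, concentration_mM)


def load_medium(tsv_path, name: str | None = None) -> Medium:
    df = pd.read_csv(tsv_path, sep="\t")
    unknown = set(df.columns) - set(_COLUMNS)
    if unknown or set(_COLUMNS) - set(df.columns):
        raise ValueError(
            f"medium file {tsv_path!s}: expected columns {_COLUMNS}, got {list(df.columns)}"
        )
    dupes = df["metabolite_id"][df["metabolite_id"].duplicated()]
    if len(dupes):
        raise ValueError(
            f"medium file {tsv_path!s}: duplicate metabolite rows {sorted(set(dupes))}"
        )
    if (df["concentration_mM"] < 0).any():
        bad = df.loc[df["concentration_mM"] < 0, "metabolite_id"].tolist()
        raise ValueError(f"medium file {tsv_path!s}: negative concentration for {bad}")
    components = dict(zip(df["metabolite_id"], df["concentration_mM"].astype(float)))
    repl = frozenset(df.loc[df["replenished"].astype(bool), "metabolite_id"])
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(tsv_path)))[0]
    return Medium(name=name, components=components, replenished_set=repl)


def write_medium(medium: Medium, tsv_path) -> None:
    df = pd.DataFrame(
        {
            "metabolite_id": list(medium.components),
            "concentration_mM": [medium.components[m] for m in medium.components],
            "replenished": [m in medium.replenished_set for m in medium.components],
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)
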