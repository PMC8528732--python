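"""Synthetic toy metabolic models and media with designed ground truth.

Every generator builds a model small enough to solve by hand whose optimal
behavior is known in closed form, so the whole pipeline — simulation,
cross-feeding detection, screens — can be validated against designed truth
without any genome-scale reconstruction:

* a linear chain species whose FBA optimum is exactly vmax × yield;
* an obligate producer → auxotrophic consumer cross-feeding pair (the
  producer co-secretes the shared metabolite stoichiometrically with
  biomass, so secretion cannot be hidden by alternate optima; the consumer
  cannot grow without it);
* an identical-competitor pair (same stoichiometry, distinct labels);
* a heterolactic species secreting lactate and acetate in a fixed ratio;
* a rich / limiting / limiting+M media suite with oxygen at 0.1 mM
  (replenished — constant microaerobic environment).

The toy namespace (cpd_glc, cpd_M, cpd_o2, ...) is neutral so externally
curated model ids can be swapped in via a mapping table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .media import Medium, write_medium
from .model_core import (
    Compartment,
    MetabolicModel,
    Metabolite,
    Reaction,
    solve_fba,
    write_model,
)

__all__ = [
    "GroundTruth",
    "make_chain_species",
    "make_crossfeeding_pair",
    "make_competitor_pair",
    "make_heterolactic_species",
    "make_media_suite",
    "fba_on_medium",
    "write_fixture_suite",
    "GLC",
    "M",
    "O2",
    "LAC",
    "ACE",
]

GLC = "cpd_glc"
M = "cpd_M"
O2 = "cpd_o2"
LAC = "cpd_lac"
ACE = "cpd_ace"

OPEN = 1000.0


@dataclass
class GroundTruth:
    """Designed truth for a synthetic scenario, checked at build time."""

    scenario: str
    designed_exchanges: list[tuple[str, str, str]] = field(default_factory=list)
    analytic_growth: dict[tuple[str, str], float] = field(default_factory=dict)
    expected_classification: dict[tuple[str, str], dict[str, str]] = field(
        default_factory=dict
    )

    def verify(self, models: dict[str, MetabolicModel], media: dict[str, Medium],
               tol: float = 1e-8) -> None:
        """Check analytic_growth against solve_fba for every entry."""
        for (species, medium_name), mu in self.analytic_growth.items():
            got = fba_on_medium(models[species], media[medium_name]).growth_rate
            if abs(got - mu) > tol:
                raise AssertionError(
                    f"{self.scenario}: μ({species}, {medium_name}) = {got}, "
                    f"designed {mu}"
                )
        for producer, consumer, met in self.designed_exchanges:
            for species in (producer, consumer):
                if models[species].exchange_for(met) is None:
                    raise AssertionError(
                        f"{self.scenario}: {species} lacks an exchange for {met}"
                    )


def fba_on_medium(model: MetabolicModel, medium: Medium):
    """FBA with uptake closed for metabolites the medium lacks.

    This is the instantaneous (amount-unlimited) growth rate on a medium —
    the closed form the arena converges to while substrates are abundant.
    """
    overrides = {}
    for rxn in model.exchange_reactions:
        if rxn.lower_bound < 0 and medium.concentration(rxn.exchanged_metabolite) <= 0:
            overrides[rxn.id] = (0.0, rxn.upper_bound)
    return solve_fba(model, overrides or None)


def _ext(met: str, formula: str | None = None) -> Metabolite:
    return Metabolite(id=met, name=met, compartment=Compartment.external,
                      formula=formula, charge=0 if formula else None)


def _int(met: str, formula: str | None = None) -> Metabolite:
    return Metabolite(id=met, name=met, compartment=Compartment.internal,
                      formula=formula, charge=0 if formula else None)


def _exchange(met: str, lb: float, ub: float = OPEN) -> Reaction:
    return Reaction(
        id=f"EX_{met}",
        stoichiometry={met: -1.0},
        lower_bound=lb,
        upper_bound=ub,
        is_exchange=True,
    )


def _transport(met: str, direction: str = "in") -> Reaction:
    inner = f"{met}_c"
    if direction == "in":
        stoich = {met: -1.0, inner: 1.0}
    else:
        stoich = {inner: -1.0, met: 1.0}
    return Reaction(
        id=f"T_{met}_{direction}",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=OPEN,
    )


def make_chain_species(
    species_id: str = "chain",
    substrate: str = GLC,
    yield_: float = 0.1,
    vmax: float = 10.0,
) -> MetabolicModel:
    """Minimal substrate → transport → biomass chain; μ* = vmax × yield."""
    if yield_ <= 0 or vmax <= 0:
        raise ValueError("yield and vmax must be positive")
    inner = f"{substrate}_c"
    biomass = Reaction(
        id=f"biomass_{species_id}",
        stoichiometry={inner: -1.0 / yield_},
        lower_bound=0.0,
        upper_bound=OPEN,
        objective_coefficient=1.0,
    )
    return MetabolicModel(
        species_id=species_id,
        metabolites=[_ext(substrate, "C6H12O6"), _int(inner, "C6H12O6")],
        reactions=[_exchange(substrate, -vmax), _transport(substrate, "in"), biomass],
        biomass_reaction_id=biomass.id,
    )


def make_crossfeeding_pair(
    metabolite: str = M,
) -> tuple[MetabolicModel, MetabolicModel, GroundTruth]:
    """Obligate producer → auxotrophic consumer pair for ``metabolite``.

    Producer: 1 biomass unit consumes 10 glucose and co-secretes 20 M
    (stoichiometrically coupled, so secretion is forced at any optimum);
    its glucose uptake cap of 3 gives μ* = 0.3 h⁻¹ — a deliberately slow
    grower that floods the arena with M.  Consumer: biomass needs both
    glucose (5) and a trace of M (0.5), cannot make M itself; μ* = 2.0 h⁻¹
    with both available, 0 without M.  On the limiting medium (glucose, no
    M) the consumer only grows when co-cultured with the producer, and the
    slow-producer/fast-consumer asymmetry makes the rescue decisive (≥ 5×)
    rather than being erased by space competition — the consumer then
    overgrows its benefactor, so the designed pair classification is
    inhibition (producer) / stimulation (consumer).
    """
    inner_glc = f"{GLC}_c"
    inner_m = f"{metabolite}_c"

    producer_biomass = Reaction(
        id="biomass_producer",
        stoichiometry={inner_glc: -10.0, inner_m: 20.0},
        lower_bound=0.0,
        upper_bound=OPEN,
        objective_coefficient=1.0,
    )
    producer = MetabolicModel(
        species_id="producer",
        metabolites=[
            _ext(GLC, "C6H12O6"),
            _int(inner_glc, "C6H12O6"),
            _ext(metabolite, "C4H4O4"),
            _int(inner_m, "C4H4O4"),
        ],
        reactions=[
            _exchange(GLC, -3.0),
            _transport(GLC, "in"),
            producer_biomass,
            _transport(metabolite, "out"),
            _exchange(metabolite, 0.0),  # secretion only
        ],
        biomass_reaction_id="biomass_producer",
    )

    consumer_biomass = Reaction(
        id="biomass_consumer",
        stoichiometry={inner_glc: -5.0, inner_m: -0.5},
        lower_bound=0.0,
        upper_bound=OPEN,
        objective_coefficient=1.0,
    )
    consumer = MetabolicModel(
        species_id="consumer",
        metabolites=[
            _ext(GLC, "C6H12O6"),
            _int(inner_glc, "C6H12O6"),
            _ext(metabolite, "C4H4O4"),
            _int(inner_m, "C4H4O4"),
        ],
        reactions=[
            _exchange(GLC, -10.0),
            _transport(GLC, "in"),
            _exchange(metabolite, -10.0),
            _transport(metabolite, "in"),
            consumer_biomass,
        ],
        biomass_reaction_id="biomass_consumer",
    )

    truth = GroundTruth(
        scenario="crossfeeding_pair",
        designed_exchanges=[("producer", "consumer", metabolite)],
        analytic_growth={
            ("producer", "rich"): 0.3,
            ("producer", "limiting"): 0.3,
            ("consumer", "rich"): 2.0,
            ("consumer", "limiting"): 0.0,
        },
        expected_classification={
            ("producer", "consumer"): {
                "producer": "inhibition",
                "consumer": "stimulation",
            }
        },
    )
    return producer, consumer, truth


def make_competitor_pair(
    base: MetabolicModel | None = None,
) -> tuple[MetabolicModel, MetabolicModel]:
    """Two label-distinct copies of one model (identical stoichiometry)."""
    import copy

    if base is None:
        base = make_chain_species()
    a = copy.deepcopy(base)
    b = copy.deepcopy(base)
    a.species_id = f"{base.species_id}_A"
    b.species_id = f"{base.species_id}_B"
    return a, b


def make_heterolactic_species(species_id: str = "heterolactic") -> MetabolicModel:
    """Glucose consumer secreting lactate and acetate 2:1 (coupled to biomass).

    1 biomass unit consumes 10 glucose and co-secretes 4 lactate + 2 acetate;
    both secretions are forced at any growing optimum.
    """
    inner_glc, inner_lac, inner_ace = f"{GLC}_c", f"{LAC}_c", f"{ACE}_c"
    biomass = Reaction(
        id=f"biomass_{species_id}",
        stoichiometry={inner_glc: -10.0, inner_lac: 4.0, inner_ace: 2.0},
        lower_bound=0.0,
        upper_bound=OPEN,
        objective_coefficient=1.0,
    )
    return MetabolicModel(
        species_id=species_id,
        metabolites=[
            _ext(GLC, "C6H12O6"),
            _int(inner_glc, "C6H12O6"),
            _ext(LAC, "C3H6O3"),
            _int(inner_lac, "C3H6O3"),
            _ext(ACE, "C2H4O2"),
            _int(inner_ace, "C2H4O2"),
        ],
        reactions=[
            _exchange(GLC, -10.0),
            _transport(GLC, "in"),
            biomass,
            _transport(LAC, "out"),
            _exchange(LAC, 0.0),
            _transport(ACE, "out"),
            _exchange(ACE, 0.0),
        ],
        biomass_reaction_id=biomass.id,
    )


def make_media_suite(metabolite: str = M) -> dict[str, Medium]:
    """rich / limiting / limiting+M media, all with 0.1 mM replenished oxygen.

    rich supports every toy species; limiting lacks M so the auxotrophic
    consumer cannot grow; limiting+M is the 10 mM supplementation rescue.
    """
    oxygen = frozenset({O2})
    rich = Medium(
        name="rich",
        components={GLC: 20.0, metabolite: 10.0, O2: 0.1},
        replenished_set=oxygen,
    )
    limiting = Medium(
        name="limiting",
        components={GLC: 20.0, O2: 0.1},
        replenished_set=oxygen,
    )
    plus = limiting.supplement(metabolite, 10.0)
    return {"rich": rich, "limiting": limiting, plus.name: plus, "limiting_plus": plus}


def write_fixture_suite(outdir) -> None:
    """Emit all toy models (toy_json) and media (TSV) into a directory."""
    os.makedirs(outdir, exist_ok=True)
    producer, consumer, _ = make_crossfeeding_pair()
    models = {
        "chain": make_chain_species(),
        "producer": producer,
        "consumer": consumer,
        "heterolactic": make_heterolactic_species(),
    }
    comp_a, comp_b = make_competitor_pair()
    models[comp_a.species_id] = comp_a
    models[comp_b.species_id] = comp_b
    for name, model in models.items():
        write_model(model, os.path.join(outdir, f"{name}.json"))
    media = make_media_suite()
    for key in ("rich", "limiting", "limiting_plus"):
        write_medium(media[key], os.path.join(outdir, f"{key}.tsv"))
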