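import logging

import pytest

from fluxarena.arena import ArenaConfig
from fluxarena.synthetic import (
    make_chain_species,
    make_competitor_pair,
    make_crossfeeding_pair,
    make_heterolactic_species,
    make_media_suite,
)

# the "tracked anyway" warnings for unused medium metabolites are expected
logging.getLogger("fluxarena.arena").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def chain_model():
    return make_chain_species()


@pytest.fixture(scope="session")
def crossfeeding_pair():
    return make_crossfeeding_pair()


@pytest.fixture(scope="session")
def competitor_pair():
    return make_competitor_pair()


@pytest.fixture(scope="session")
def heterolactic():
    return make_heterolactic_species()


@pytest.fixture(scope="session")
def media_suite():
    return make_media_suite()


@pytest.fixture
def small_config():
    """10×10 arena, 45 h: the desk-scale configuration used by scenario tests."""
    return ArenaConfig(rows=10, cols=10, rng_seed=0)


def cobra_from_model(model):
    """Independent oracle path: rebuild as a cobrapy model (GLPK solver)."""
    import cobra

    cm = cobra.Model(model.species_id)
    cm.solver = "glpk"
    mets = {
        m.id: cobra.Metabolite(m.id, compartment="e" if m.compartment.value == "external" else "c")
        for m in model.metabolites
    }
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.is_exchange:
            # cobra treats single-metabolite boundary reactions as exchanges
            pass
    cm.objective = model.biomass_reaction_id
    return cm
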