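"""Model container, FBA solver, blocked reactions, balances, and I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluxarena.model_core import (
    Compartment,
    FluxStatus,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    blocked_percentage,
    check_balances,
    find_blocked_reactions,
    parse_formula,
    read_model,
    solve_fba,
    write_model,
)
from fluxarena.synthetic import make_chain_species, make_crossfeeding_pair

from conftest import cobra_from_model


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


def test_chain_fba_matches_hand_solved_lp(chain_model):
    # glucose uptake 10 × biomass yield 0.1 → μ = 1.0 (2-variable LP by hand)
    sol = solve_fba(chain_model)
    assert sol.status is FluxStatus.optimal
    assert sol.growth_rate == pytest.approx(1.0, abs=1e-8)
    # uptake is negative by the secretion-positive convention
    assert sol.fluxes["EX_cpd_glc"] == pytest.approx(-10.0, abs=1e-8)


@given(
    vmax=st.floats(0.1, 50, allow_nan=False),
    yield_=st.floats(0.01, 1.0, allow_nan=False),
)
@settings(max_examples=25, deadline=None)
def test_chain_optimum_closed_form(vmax, yield_):
    """μ* = uptake bound × yield for any linear chain."""
    model = make_chain_species(vmax=vmax, yield_=yield_)
    sol = solve_fba(model)
    assert sol.growth_rate == pytest.approx(vmax * yield_, rel=1e-6)


def test_closed_exchanges_give_zero_growth(chain_model):
    overrides = {
        r.id: (0.0, r.upper_bound) for r in chain_model.exchange_reactions
    }
    sol = solve_fba(chain_model, overrides)
    assert sol.growth_rate == 0.0


def test_override_with_lb_above_ub_is_an_error(chain_model):
    with pytest.raises(ModelValidationError):
        solve_fba(chain_model, {"EX_cpd_glc": (1.0, -1.0)})


def test_override_unknown_reaction_is_an_error(chain_model):
    with pytest.raises(ModelValidationError):
        solve_fba(chain_model, {"nope": (0.0, 1.0)})


def test_objective_invariant_to_reaction_ordering(chain_model):
    reordered = MetabolicModel(
        species_id=chain_model.species_id,
        metabolites=list(chain_model.metabolites),
        reactions=list(reversed(chain_model.reactions)),
        biomass_reaction_id=chain_model.biomass_reaction_id,
    )
    a = solve_fba(chain_model).growth_rate
    b = solve_fba(reordered).growth_rate
    assert a == pytest.approx(b, rel=1e-6)


def test_solver_restart_reproducible(chain_model):
    sols = [solve_fba(chain_model) for _ in range(3)]
    for s in sols[1:]:
        assert s.fluxes == sols[0].fluxes


def test_relaxing_exchange_bounds_never_decreases_optimum():
    model = make_chain_species(vmax=5.0)
    base = solve_fba(model).growth_rate
    doubled = solve_fba(model, {"EX_cpd_glc": (-10.0, 1000.0)}).growth_rate
    assert doubled >= base - 1e-9


def test_fba_agrees_with_cobra_glpk_oracle():
    """Dual-route check: our HiGHS LP vs an independent cobrapy/GLPK solve."""
    producer, consumer, _ = make_crossfeeding_pair()
    for model in (make_chain_species(), producer, consumer):
        ours = solve_fba(model).growth_rate
        theirs = cobra_from_model(model).optimize().objective_value
        assert ours == pytest.approx(theirs, abs=1e-6)


def test_parsimonious_mode_preserves_objective(chain_model):
    plain = solve_fba(chain_model)
    pfba = solve_fba(chain_model, minimize_total_flux=True)
    assert pfba.growth_rate == pytest.approx(plain.growth_rate, rel=1e-6)
    assert sum(abs(v) for v in pfba.fluxes.values()) <= (
        sum(abs(v) for v in plain.fluxes.values()) + 1e-6
    )


# ---------------------------------------------------------------------------
# Blocked reactions
# ---------------------------------------------------------------------------


def _dead_end_model():
    """Chain model plus a reaction producing a metabolite nothing consumes."""
    model = make_chain_species()
    mets = list(model.metabolites) + [
        Metabolite(id="cpd_dead_c", name="dead end", compartment=Compartment.internal)
    ]
    rxns = list(model.reactions) + [
        Reaction(
            id="R_dead",
            stoichiometry={"cpd_glc_c": -1.0, "cpd_dead_c": 1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        )
    ]
    return MetabolicModel(
        species_id="deadend",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=model.biomass_reaction_id,
    )


def test_dead_end_reaction_is_blocked():
    model = _dead_end_model()
    assert find_blocked_reactions(model) == {"R_dead"}
    assert blocked_percentage(model) == pytest.approx(100.0 / 4)


def test_fully_connected_chain_has_no_blocked_reactions(chain_model):
    assert find_blocked_reactions(chain_model) == set()


def test_blocked_set_matches_cobra_oracle():
    """Brute-force cross-check through cobrapy's blocked-reaction finder."""
    from cobra.flux_analysis import find_blocked_reactions as cobra_blocked

    for model in (_dead_end_model(), make_chain_species()):
        cm = cobra_from_model(model)
        for rxn in cm.reactions:
            if len(rxn.metabolites) == 1:  # fully open exchanges
                rxn.lower_bound, rxn.upper_bound = -1000.0, 1000.0
        assert find_blocked_reactions(model) == set(cobra_blocked(cm))


# ---------------------------------------------------------------------------
# Balance checks
# ---------------------------------------------------------------------------


def _two_met_model(formula_a, formula_b, coef_b=1.0):
    mets = [
        Metabolite(id="A", compartment=Compartment.internal, formula=formula_a, charge=0),
        Metabolite(id="B", compartment=Compartment.internal, formula=formula_b, charge=0),
        Metabolite(id="A_e", compartment=Compartment.external, formula=formula_a, charge=0),
    ]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A_e": -1.0}, lower_bound=-10, upper_bound=10,
                 is_exchange=True),
        Reaction(id="T_A", stoichiometry={"A_e": -1.0, "A": 1.0}, lower_bound=0, upper_bound=10),
        Reaction(id="R1", stoichiometry={"A": -1.0, "B": coef_b}, lower_bound=0, upper_bound=10),
        Reaction(id="bio", stoichiometry={"B": -1.0}, lower_bound=0, upper_bound=10,
                 objective_coefficient=1.0),
    ]
    return MetabolicModel("balance_toy", mets, rxns, "bio")


@pytest.mark.parametrize(
    "formula_a, formula_b, coef_b, expect_balanced, expect_imbalance",
    [
        ("CH2O", "CH2O", 1.0, True, {}),
        ("C6H12O6", "C3H6O3", 2.0, True, {}),  # glycolysis-style 1→2 split
        ("CH2O", "CO2", 1.0, False, {"H": -2.0, "O": 1.0}),
    ],
)
def test_elemental_bookkeeping(formula_a, formula_b, coef_b, expect_balanced, expect_imbalance):
    model = _two_met_model(formula_a, formula_b, coef_b)
    report = {r.reaction_id: r for r in check_balances(model)}["R1"]
    assert report.balanced is expect_balanced
    assert report.element_imbalance == expect_imbalance


def test_missing_formula_reports_unchecked_not_fatal():
    model = _two_met_model("CH2O", "CH2O")
    model.metabolites[1] = Metabolite(id="B", compartment=Compartment.internal)
    model.validate()
    report = {r.reaction_id: r for r in check_balances(model)}["R1"]
    assert not report.checked and "B" in report.note


def test_exchange_reactions_are_excluded_from_balance_report():
    reports = check_balances(_two_met_model("CH2O", "CH2O"))
    assert "EX_A" not in {r.reaction_id for r in reports}


def test_formula_parser_rejects_garbage():
    assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
    with pytest.raises(ValueError):
        parse_formula("not a formula")


# ---------------------------------------------------------------------------
# Validation and I/O
# ---------------------------------------------------------------------------


def test_exchange_must_have_single_external_metabolite():
    mets = [Metabolite(id="x", compartment=Compartment.internal)]
    with pytest.raises(ModelValidationError):
        MetabolicModel(
            "bad",
            mets,
            [
                Reaction(id="EX_x", stoichiometry={"x": -1.0}, lower_bound=-1,
                         upper_bound=1, is_exchange=True, objective_coefficient=1.0),
            ],
            "EX_x",
        )


def test_unknown_metabolite_reference_names_it():
    mets = [Metabolite(id="x", compartment=Compartment.internal)]
    with pytest.raises(ModelValidationError, match="ghost"):
        MetabolicModel(
            "bad",
            mets,
            [Reaction(id="r", stoichiometry={"ghost": 1.0}, lower_bound=0,
                      upper_bound=1, objective_coefficient=1.0)],
            "r",
        )


def test_toy_json_round_trip(tmp_path, chain_model, heterolactic):
    for model in (chain_model, heterolactic):
        path = tmp_path / f"{model.species_id}.json"
        write_model(model, path)
        back = read_model(path)
        assert back.species_id == model.species_id
        assert back.biomass_reaction_id == model.biomass_reaction_id
        assert [m.id for m in back.metabolites] == [m.id for m in model.metabolites]
        for a, b in zip(back.reactions, model.reactions):
            assert (a.id, a.stoichiometry, a.lower_bound, a.upper_bound,
                    a.is_exchange, a.objective_coefficient) == (
                b.id, b.stoichiometry, b.lower_bound, b.upper_bound,
                b.is_exchange, b.objective_coefficient)
        # write(read(x)) == x byte-for-byte
        path2 = tmp_path / "again.json"
        write_model(back, path2)
        assert path.read_text() == path2.read_text()


def test_sbml_round_trip_through_cobra(tmp_path, chain_model):
    import cobra

    cm = cobra_from_model(chain_model)
    sbml_path = tmp_path / "chain.xml"
    cobra.io.write_sbml_model(cm, str(sbml_path))
    model = read_model(sbml_path, format="sbml")
    assert model.biomass_reaction_id == chain_model.biomass_reaction_id
    assert solve_fba(model).growth_rate == pytest.approx(1.0, abs=1e-6)


def test_sbml_without_objective_is_an_error(tmp_path, chain_model):
    import cobra

    cm = cobra_from_model(chain_model)
    cm.objective = cm.problem.Objective(0)
    sbml_path = tmp_path / "noobj.xml"
    cobra.io.write_sbml_model(cm, str(sbml_path))
    with pytest.raises(ModelValidationError, match="objective"):
        read_model(sbml_path, format="sbml")
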