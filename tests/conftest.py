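"""Shared fixtures: tiny hand-built models with pen-and-paper optima."""

from __future__ import annotations

import logging

import pytest
from hypothesis import HealthCheck, settings

from fluxfit import BiomassSpec, MetabolicModel, Metabolite, Reaction

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the "unknown knockout gene" warning is exercised deliberately in fixtures
logging.getLogger("fluxfit.fba").setLevel(logging.ERROR)


@pytest.fixture
def chain_model() -> MetabolicModel:
    """EX_a (uptake 10) → T → biomass(b_c). WT optimum = 10 by hand."""
    return MetabolicModel(
        metabolites=[Metabolite("a_e", "e"), Metabolite("b_c", "c")],
        reactions=[
            Reaction("EX_a", {"a_e": -1.0}, lb=-10.0, ub=1000.0, is_exchange=True),
            Reaction("T", {"a_e": -1.0, "b_c": 1.0}, lb=0.0, ub=1000.0, gpr="gT"),
        ],
        biomass=BiomassSpec(substrates={"b_c": 1.0}),
        id="chain",
    )


@pytest.fixture
def branched_model() -> MetabolicModel:
    """Two uptakes (10 each); biomass needs 1 A + 2 B → optimum = 5."""
    return MetabolicModel(
        metabolites=[
            Metabolite("a_e", "e"),
            Metabolite("b_e", "e"),
            Metabolite("a_c", "c"),
            Metabolite("b_c", "c"),
        ],
        reactions=[
            Reaction("EX_a", {"a_e": -1.0}, lb=-10.0, ub=1000.0, is_exchange=True),
            Reaction("EX_b", {"b_e": -1.0}, lb=-10.0, ub=1000.0, is_exchange=True),
            Reaction("TA", {"a_e": -1.0, "a_c": 1.0}, lb=0.0, ub=1000.0, gpr="gA"),
            Reaction("TB", {"b_e": -1.0, "b_c": 1.0}, lb=0.0, ub=1000.0, gpr="gB1 or gB2"),
        ],
        biomass=BiomassSpec(substrates={"a_c": 1.0, "b_c": 2.0}),
        id="branched",
    )


@pytest.fixture
def bypass_model() -> MetabolicModel:
    """Chain plus a spurious gene-free bypass Y that defeats knockouts.

    EX_a → T (gene gT) → b_c, and Y: a_e → b_c with no gene.  Knocking out
    gT should kill growth but does not while Y is present.
    """
    return MetabolicModel(
        metabolites=[Metabolite("a_e", "e"), Metabolite("b_c", "c")],
        reactions=[
            Reaction("EX_a", {"a_e": -1.0}, lb=-10.0, ub=1000.0, is_exchange=True),
            Reaction("T", {"a_e": -1.0, "b_c": 1.0}, lb=0.0, ub=1000.0, gpr="gT"),
            Reaction("Y", {"a_e": -1.0, "b_c": 1.0}, lb=0.0, ub=1000.0),
        ],
        biomass=BiomassSpec(substrates={"b_c": 1.0}),
        id="bypass",
    )
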