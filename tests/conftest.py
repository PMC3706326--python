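import numpy as np
import pytest
from hypothesis import settings

from bimodules import MetabolicNetwork, ScoredNetwork, weight_metabolites

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def chain_network():
    """R1 - A - R2 - B - R3: three reactions chained by two metabolites."""
    return MetabolicNetwork(
        reactions=frozenset({"R1", "R2", "R3"}),
        metabolites=frozenset({"A", "B"}),
        edges=frozenset({("R1", "A"), ("R2", "A"), ("R2", "B"), ("R3", "B")}),
        gene_map={"R1": frozenset({"g1"}), "R2": frozenset({"g2"}), "R3": frozenset({"g3"})},
    )


@pytest.fixture
def chain_scored(chain_network):
    """Scores +2, +1, -5 with c = 0.1 (both metabolites have degree 2)."""
    return ScoredNetwork(
        base=chain_network,
        reaction_score={"R1": 2.0, "R2": 1.0, "R3": -5.0},
        metabolite_weight=weight_metabolites(chain_network, 0.1),
        weight_constant=0.1,
        imputed=frozenset(),
        direction="up",
    )


@pytest.fixture
def hub_network():
    """A 12-reaction hub metabolite plus private metabolites per reaction.

    Mirrors the situation of a promiscuous metabolite shared by many
    reactions, each of which also has a low-degree metabolite of its own.
    """
    rxns = [f"R{i:02d}" for i in range(12)]
    edges = {(r, "HUB") for r in rxns} | {(r, f"m{r}") for r in rxns}
    return MetabolicNetwork(
        reactions=frozenset(rxns),
        metabolites=frozenset({"HUB"} | {f"m{r}" for r in rxns}),
        edges=frozenset(edges),
        gene_map={r: frozenset({f"g{r}"}) for r in rxns},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20130702)
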