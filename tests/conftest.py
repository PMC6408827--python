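import warnings

import pytest

from csnet.model import ConditionGraph, CSNInstance, Demand


@pytest.fixture(autouse=True)
def _quiet_demand_coverage_warnings():
    """Generated toys routinely leave some condition without a demand."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="no demand at condition")
        yield


def triangle(directed: bool = False) -> CSNInstance:
    """Unit-weight triangle, one demand; optimum 1."""
    g = ConditionGraph(num_conditions=1, directed=directed)
    g.add_edge("a", "b", 1.0, {1})
    g.add_edge("b", "c", 1.0, {1})
    g.add_edge("a", "c", 1.0, {1})
    return CSNInstance(graph=g, demands=[Demand("a", "b", 1)], variant="edge")


def path_instance(weights=(1.0, 2.0), condition: int = 1,
                  num_conditions: int = 1, directed: bool = True):
    """Simple path a -> m1 -> ... -> b with one end-to-end demand."""
    g = ConditionGraph(num_conditions=num_conditions, directed=directed)
    names = ["a"] + [f"m{i}" for i in range(1, len(weights))] + ["b"]
    for i, w in enumerate(weights):
        g.add_edge(names[i], names[i + 1], w, {condition})
    return CSNInstance(graph=g, demands=[Demand("a", "b", condition)],
                       variant="edge")
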