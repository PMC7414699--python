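import numpy as np
import pandas as pd
import pytest

from pathpse.graph import parse_graph


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chain_dag():
    return parse_graph([("A", "B"), ("B", "C")])


@pytest.fixture
def three_path_graph():
    # X1 -> X2 -> Y with a second mediator X3 fed by both X1 and X2
    return parse_graph(
        [("X1", "X2"), ("X2", "X3"), ("X1", "X3"), ("X2", "Y"), ("X3", "Y")]
    )


@pytest.fixture
def fig_network_edges():
    # binary myocardial-infarction network used by the simulation harness
    from pathpse.simulate import MI_EDGES

    return MI_EDGES


def linear_sem_chain(n, rng, a=0.7, b=0.6, confounded=True):
    """X1 -> X2 -> Y with confounders C1 (of X1, X2) and C2 (of X2, Y);
    C1 -> C2 so the two confounders are associated."""
    c1 = rng.normal(size=n)
    c2 = 0.6 * c1 + rng.normal(size=n)
    x1 = 0.8 * c1 + rng.normal(size=n)
    x2 = a * x1 + 0.5 * c1 + 0.4 * c2 + rng.normal(size=n)
    y = b * x2 + 0.7 * c2 + rng.normal(size=n)
    return pd.DataFrame({"C1": c1, "C2": c2, "X1": x1, "X2": x2, "Y": y})
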