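import networkx as nx
import numpy as np
import pytest

from polyqnet.geometry import HyperbolicPoint
from polyqnet.net_io import PWM


@pytest.fixture
def toy_interaction_file(tmp_path):
    """Six raw-dialect rows: scores 0.9, 0.71, 0.7, 0.5, a 0.71 self-pair and
    a duplicate of the 0.9 pair at lower score; at threshold 0.71 exactly two
    edges survive."""
    rows = [
        ("A", "1", "B", "2", "0.9", "exp"),
        ("B", "2", "C", "3", "0.71", "exp"),
        ("C", "3", "D", "4", "0.7", "exp"),
        ("D", "4", "E", "5", "0.5", "exp"),
        ("E", "5", "E", "5", "0.71", "exp"),
        ("B", "2", "A", "1", "0.3", "exp"),
    ]
    path = tmp_path / "edges.txt"
    path.write_text("\n".join("\t".join(r) for r in rows) + "\n")
    return path


@pytest.fixture
def certain_pwm():
    """Width-3 PWM with probability 1 on A, C, G; a perfect ACG match scores
    3 * log2(1/0.25) = 6 bits at pseudocount 0."""
    probs = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
        ]
    )
    return PWM(probs, threshold=6.0)


@pytest.fixture
def random_coords():
    rng = np.random.default_rng(7)
    return {
        f"n{i:03d}": HyperbolicPoint(float(r), float(t))
        for i, (r, t) in enumerate(
            zip(rng.uniform(0, 12, 40), rng.uniform(0, 2 * np.pi, 40))
        )
    }


@pytest.fixture
def triangle_graph():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("A", "C"), ("B", "C")])
    return g
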