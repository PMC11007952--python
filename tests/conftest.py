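import pytest

import volvoclock as vc
from volvoclock.tree import build_tree


@pytest.fixture(scope="session")
def volvocine():
    """The packaged volvocine fixture (tree, named nodes, traits)."""
    return vc.build_volvocine_fixture()


@pytest.fixture
def two_tip_tree():
    """((A:1, B:1)) cherry with 1 My branches."""
    return build_tree(
        [(0, 1), (0, 2)], {1: "A", 2: "B"}, lengths={1: 1.0, 2: 1.0},
        length_kind="my",
    )


@pytest.fixture
def balanced_four_tip():
    """((A,B),(C,D)) with unit-duration branches."""
    edges = [(0, 1), (0, 2), (1, 3), (1, 4), (2, 5), (2, 6)]
    labels = {3: "A", 4: "B", 5: "C", 6: "D"}
    lengths = {v: 1.0 for v in range(1, 7)}
    return build_tree(edges, labels, lengths=lengths, length_kind="my")


def random_tip_states(tree, states, rng, missing_prob=0.0):
    out = {}
    for lab in tree.tip_labels:
        if missing_prob and rng.random() < missing_prob:
            out[lab] = "?"
        else:
            out[lab] = states[rng.integers(len(states))]
    return out
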