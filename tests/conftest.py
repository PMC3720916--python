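import numpy as np
import pytest

from colonykit.branching import P1Schedule


def lineage_tree_pmf(probs, n_max):
    """Independent oracle: abortive-colony pmf by explicit enumeration of
    binary lineage trees.

    A tree shape is None (leaf = RCD cell) or a (left, right) pair (internal
    node = division); the probability of a shape rooted at generation g is
    the product of P1 over leaves and (1 - P1) over internal nodes, zero if
    any node would sit beyond the schedule horizon.  Feasible for n <= ~7
    (Catalan growth).
    """
    probs = np.asarray(probs, dtype=float)
    g_limit = probs.size - 1

    def shapes(n):
        if n == 1:
            yield None
            return
        for k in range(1, n):
            for left in shapes(k):
                for right in shapes(n - k):
                    yield (left, right)

    def prob(shape, g):
        if g > g_limit:
            return 0.0
        if shape is None:
            return probs[g]
        left, right = shape
        return (1.0 - probs[g]) * prob(left, g + 1) * prob(right, g + 1)

    return np.array([sum(prob(s, 0) for s in shapes(n))
                     for n in range(1, n_max + 1)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def half_schedule():
    return P1Schedule.constant(0.5, g_max=16)
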