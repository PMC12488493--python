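import numpy as np
import pytest

from eyemapper import SyntheticConfig
from eyemapper.pipeline import SyntheticWorld, build_world


@pytest.fixture(scope="session")
def default_world() -> SyntheticWorld:
    """Full synthetic world at the default study conditions (seed 1)."""
    return build_world(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def clean_world() -> SyntheticWorld:
    """Noise-free world (no jitter) for tight geometric checks."""
    return build_world(SyntheticConfig(seed=1, position_jitter_frac=0.0))


def random_tree(rng: np.random.Generator, n_nodes: int):
    """Random recursive tree (uniform attachment): parent[i] < i."""
    from eyemapper.skeleton import SkeletonTree

    parent = np.full(n_nodes, -1, dtype=int)
    for i in range(1, n_nodes):
        parent[i] = rng.integers(0, i)
    pos = rng.normal(size=(n_nodes, 3))
    return SkeletonTree(np.arange(1, n_nodes + 1), pos, parent)


def strahler_oracle(tree) -> dict[int, int]:
    """Independent recursive Strahler implementation (per branch index).

    Node rule applied by direct recursion: a leaf is 1; otherwise take the
    max over children, +1 if the max is attained at least twice.  Branch SN
    is the SN of the chain's distal node.
    """
    import sys

    from eyemapper.skeleton import branch_decomposition

    children: dict[int, list[int]] = {}
    for i, p in enumerate(tree.parent):
        if p >= 0:
            children.setdefault(int(p), []).append(i)

    sys.setrecursionlimit(max(10000, 10 * tree.n_nodes))
    memo: dict[int, int] = {}

    def sn(i: int) -> int:
        if i in memo:
            return memo[i]
        ch = children.get(i, [])
        if not ch:
            memo[i] = 1
        else:
            vals = sorted((sn(c) for c in ch), reverse=True)
            memo[i] = vals[0] + 1 if len(vals) > 1 and vals[1] == vals[0] else vals[0]
        return memo[i]

    out = {}
    for k, b in enumerate(branch_decomposition(tree)):
        out[k] = sn(int(b.node_chain[-1]))
    return out
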