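import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bodymap import simulate as sim

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def timetree():
    return sim.default_timetree()


@pytest.fixture(scope="session")
def small_atlas():
    return sim.simulate_atlas(sim.AtlasSimConfig(n_genes=400, n_tissues=6,
                                                 replicates=2, seed=123))


def random_additive_distances(rng: np.random.Generator, n_taxa: int):
    """Random additive distance matrix from a random binary tree.

    Returns (DataFrame distance matrix, total branch length of the
    generating tree).  Merging the two root edges preserves the edge sum,
    so the unrooted NJ reconstruction must recover ``total`` exactly.
    """
    dist: dict[tuple[str, str], float] = {}
    total = 0.0
    nodes = [{f"t{i}": 0.0} for i in range(n_taxa)]
    while len(nodes) > 1:
        j = int(rng.integers(1, len(nodes)))
        i = int(rng.integers(0, j))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.1, 1.0, size=2)
        total += la + lb
        for x, dx in a.items():
            for y, dy in b.items():
                dist[tuple(sorted((x, y)))] = dx + la + dy + lb
        merged = {x: dx + la for x, dx in a.items()}
        merged.update({y: dy + lb for y, dy in b.items()})
        nodes.append(merged)
    labels = [f"t{i}" for i in range(n_taxa)]
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for (x, y), d in dist.items():
        mat.loc[x, y] = mat.loc[y, x] = d
    return mat, total
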