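import numpy as np
import pytest

from clusaddle import ClusteredDataset, ScoreSet, assemble_scores
from clusaddle.scores import midrank


def random_scoreset(rng, m_range=(2, 5), n_range=(2, 5), midranked=True,
                    v_rule="unit", center=True):
    """A random clustered instance with mid-ranked pooled scores and a
    random within-cluster treated/control split (both arms present)."""
    M = int(rng.integers(m_range[0], m_range[1] + 1))
    sizes = rng.integers(n_range[0], n_range[1] + 1, size=M)
    cluster = np.repeat(np.arange(M), sizes)
    N = int(sizes.sum())
    if midranked:
        scores = midrank(rng.normal(size=N))
    else:
        scores = rng.normal(size=N)
    arm = np.zeros(N, dtype=int)
    start = 0
    for n in sizes:
        w = int(rng.integers(1, n))
        arm[start + rng.permutation(int(n))[:w]] = 1
        start += int(n)
    raw = ScoreSet(cluster, scores, arm, np.ones(M))
    return assemble_scores(raw, v_rule=v_rule, center=center)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_survival_data():
    """8 subjects in 3 clusters, mixed events and censorings."""
    return ClusteredDataset(
        cluster_id=[1, 1, 1, 2, 2, 2, 3, 3],
        y=[2.0, 5.0, 3.0, 1.0, 4.0, 4.0, 6.0, 2.5],
        arm=[1, 0, 1, 0, 1, 0, 1, 0],
        event=[1, 0, 1, 1, 1, 0, 0, 1],
    )
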