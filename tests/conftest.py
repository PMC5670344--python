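import numpy as np
import pytest

from phaselag.connectivity import BandDefinition

LOW_GAMMA = BandDefinition("low_gamma", 25, 40)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_dwpli(im: np.ndarray) -> float:
    """Literal double sum over ordered epoch pairs j != k (oracle)."""
    n = len(im)
    num = 0.0
    den = 0.0
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            num += im[j] * im[k]
            den += abs(im[j] * im[k])
    return num / den if den > 0 else 0.0


def enumerate_rank_sum_p(x, y) -> float:
    """Exact two-sided Wilcoxon rank-sum p by full enumeration (oracle).

    Counts group assignments whose rank sum deviates from its null mean
    at least as much as the observed one; valid for tie-free data, where
    the null distribution is symmetric.
    """
    from itertools import combinations

    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mean_w)
    count = 0
    total = 0
    for combo in combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        count += abs(w - mean_w) >= dev - 1e-9
        total += 1
    return count / total
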