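import warnings

import numpy as np
import pytest

from chromatex import ImageGrid, LabelMask, SceneSpec


@pytest.fixture(autouse=True)
def _quiet_small_sample_warnings():
    # analyses on tiny synthetic scenes trip the <100-nuclei advisory
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* nuclei analysed")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def control_spec():
    return SceneSpec(texture_regime="control", clumpiness=0.0, seed=7)


@pytest.fixture
def treated_spec():
    return SceneSpec(texture_regime="treated", clumpiness=0.4, seed=7)


def glcm_bruteforce(levelled, valid, levels, distance, angle, symmetric):
    """Independent pair-enumeration oracle for GLCM construction.

    Walks every pixel with two nested loops and counts the ordered pair at
    the requested offset when both endpoints are valid.
    """
    offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    dr, dc = offsets[angle]
    dr, dc = dr * distance, dc * distance
    h, w = levelled.shape
    counts = np.zeros((levels, levels), dtype=float)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < h and 0 <= c2 < w):
                continue
            if not (valid[r, c] and valid[r2, c2]):
                continue
            counts[levelled[r, c], levelled[r2, c2]] += 1
            if symmetric:
                counts[levelled[r2, c2], levelled[r, c]] += 1
    total = counts.sum()
    return counts / total if total else counts


def mwu_exact_bruteforce(a, b):
    """Exact two-tailed Mann-Whitney p by explicit enumeration of rank subsets."""
    import itertools

    from scipy.stats import rankdata

    a, b = list(a), list(b)
    n_a, n = len(a), len(a) + len(b)
    pooled = np.asarray(a + b, dtype=float)
    ranks = rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    all_ranks = np.arange(1, n + 1)
    us = [sum(comb) - n_a * (n_a + 1) / 2
          for comb in itertools.combinations(all_ranks, n_a)]
    us = np.asarray(us, dtype=float)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_lo, p_hi))
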