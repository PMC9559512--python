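"""Shared fixtures and independent reference implementations (oracles).

The oracles here are deliberately naive — literal loops and direct formula
transcriptions — so they stay independent of the vectorized/compiled code
paths they check.
"""

from __future__ import annotations

import math
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import configuration as hypothesis_configuration
from hypothesis import settings as hypothesis_settings

from rewirenet.pcit import partial_correlation

# property tests are derandomized; keep hypothesis' on-disk caches out of the
# repository (example database off, home dir in tmp)
hypothesis_configuration.set_hypothesis_home_dir(tempfile.mkdtemp(prefix="hyp-"))
hypothesis_settings.register_profile("rewirenet", database=None)
hypothesis_settings.load_profile("rewirenet")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    """Small deterministic count matrix with two classes and two batches."""
    rng = np.random.default_rng(7)
    genes = [f"G{i:03d}" for i in range(40)]
    samples = [f"S{i:02d}" for i in range(12)]
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(40, 12)), index=pd.Index(genes, name="gene"),
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "sample": samples,
            "class": ["P"] * 6 + ["NP"] * 6,
            "batch": ["B1", "B2"] * 6,
        }
    )
    return counts, meta


def pcit_significant_pairs_bruteforce(r: np.ndarray, n_samples: int, p_max: float = 0.05):
    """Literal O(n^3) PCIT + correlation-t-test reference.

    Returns the set of retained (i, j) index pairs (i < j). Mirrors the
    published elimination rule: for each trio the tolerance is the average
    of partial/direct ratios (0/0 -> 1, direct 0 with nonzero partial
    excluded) and the pair (x, y) is dropped if some z satisfies
    |r_xy| <= |eps r_xz| and |r_xy| <= |eps r_yz|.
    """
    from scipy import stats

    n = r.shape[0]
    eliminated = set()
    for x in range(n):
        for y in range(x + 1, n):
            for z in range(n):
                if z == x or z == y:
                    continue
                r_xy, r_xz, r_yz = r[x, y], r[x, z], r[y, z]
                if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
                    eliminated.add((x, y))
                    break
                if abs(r_xy) >= 1.0:
                    continue
                p_xy = partial_correlation(r_xy, r_xz, r_yz)
                p_xz = partial_correlation(r_xz, r_xy, r_yz)
                p_yz = partial_correlation(r_yz, r_xy, r_xz)
                terms = []
                for part, direct in ((p_xy, r_xy), (p_xz, r_xz), (p_yz, r_yz)):
                    if direct == 0.0:
                        if part == 0.0:
                            terms.append(1.0)
                    else:
                        terms.append(part / direct)
                if not terms:
                    continue
                eps = sum(terms) / len(terms)
                if abs(r_xy) <= abs(eps * r_xz) and abs(r_xy) <= abs(eps * r_yz):
                    eliminated.add((x, y))
                    break
    kept = set()
    for x in range(n):
        for y in range(x + 1, n):
            if (x, y) in eliminated:
                continue
            r_xy = r[x, y]
            if abs(r_xy) >= 1.0:
                p = 0.0
            else:
                t = r_xy * math.sqrt((n_samples - 2) / (1.0 - r_xy**2))
                p = 2.0 * stats.t.sf(abs(t), df=n_samples - 2)
            if p <= p_max:
                kept.add((x, y))
    return kept


def information_gain_bruteforce(x, y) -> float:
    """Raw best-binary-split gain by explicit enumeration of thresholds."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)

    def entropy(labels):
        h = 0.0
        n = len(labels)
        for c in set(labels):
            p = list(labels).count(c) / n
            h -= p * math.log2(p)
        return h

    xs = sorted(set(x))
    if len(xs) < 2:
        return 0.0
    h_y = entropy(y)
    best = h_y
    for lo, hi in zip(xs[:-1], xs[1:]):
        t = (lo + hi) / 2
        left = y[x <= t]
        right = y[x > t]
        h = len(left) / len(y) * entropy(left) + len(right) / len(y) * entropy(right)
        best = min(best, h)
    return h_y - best
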