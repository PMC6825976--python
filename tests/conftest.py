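"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-derivations (exhaustive
enumeration, literal running sums, step-up loops) kept independent of the
package's implementations so the two routes can be compared.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pytest

from regmaster.synthetic import SimParams, generate_reference_cohort


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_cohort():
    p = SimParams(n_tfs=5, targets_per_tf=8, n_background_genes=60,
                  n_samples=120, seed=11)
    expr, truth = generate_reference_cohort(p)
    return p, expr, truth


# ---------------------------------------------------------------------------
# oracles


def hypergeom_tail_oracle(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, n, N) by exact enumeration."""
    denom = math.comb(M, N)
    total = 0
    for x in range(k, min(n, N) + 1):
        if n - x > M - N or x > N:
            continue
        total += math.comb(n, x) * math.comb(M - n, N - x)
    return total / denom


def ks_running_sum_oracle(n_genes: int, hit_positions, hit_weights=None
                          ) -> tuple[float, float, float]:
    """Literal KS running sum; returns (max dev, min dev, signed ES).

    Hits step up by w/sum(w), misses down by 1/(n-m); the signed ES is the
    deviation of largest magnitude with ties resolved positive.
    """
    hits = set(int(i) for i in hit_positions)
    m = len(hits)
    if hit_weights is None:
        weights = {i: 1.0 for i in hits}
    else:
        weights = {int(i): float(w) for i, w in zip(hit_positions, hit_weights)}
    wsum = sum(weights.values())
    running = 0.0
    maxdev = mindev = 0.0
    for i in range(n_genes):
        if i in hits:
            running += weights[i] / wsum
        else:
            running -= 1.0 / (n_genes - m)
        maxdev = max(maxdev, running)
        mindev = min(mindev, running)
    # ties resolve positive; tolerance absorbs float accumulation error
    es = maxdev if maxdev >= -mindev - 1e-12 else mindev
    return maxdev, mindev, es


def bh_stepup_oracle(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def logrank_two_sample_oracle(time, event, group) -> float:
    """Two-sample log-rank chi-square from first principles."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    assert len(labels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == labels[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0
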