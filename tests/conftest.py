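"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oleoscreen.synthetic import LogisticParams, logistic_size


@pytest.fixture
def reference_logistic() -> tuple[np.ndarray, np.ndarray, LogisticParams]:
    """Noiseless offset logistic sampled every 15 min for 4 days."""
    p = LogisticParams(K=2000.0, s0=100.0, r=0.2, t_mid=40.0)
    t = np.arange(0.0, 96.0 + 0.125, 0.25)
    return t, logistic_size(t, p), p


def brute_force_window_slopes(times, values, w):
    """Per-window polyfit slopes — the dumb oracle for sliding_slopes."""
    centers, slopes = [], []
    for i in range(len(times) - w + 1):
        x, y = times[i : i + w], values[i : i + w]
        slopes.append(np.polyfit(x, y, 1)[0])
        centers.append(np.mean(x))
    return np.array(centers), np.array(slopes)


def mann_whitney_enumeration(a, b):
    """Exact two-sided Mann-Whitney by full enumeration (tie-free data only).

    U for group a counts pairs (x in a, y in b) with x > y. The two-sided p
    is the null probability of a U at least as far from n1*n2/2 as observed.
    """
    a, b = list(a), list(b)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(a)
    u_obs = sum(x > y for x in a for y in b)
    mid = n1 * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(x > y for x in ga for y in gb)
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
    return u_obs, count / total


def bh_stepup_oracle(p):
    """Benjamini-Hochberg by the literal step-up formula."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return np.minimum(adj, 1.0)


def literal_rank_oracle(table, kinds, k_growth=1.2, k_lipid=1.6):
    """Brute-force re-implementation of the weighted ranking procedure.

    Sort each variable (fitness/lipid descending, t_max ascending), assign
    descending ranks n..1 with average ranks on ties, multiply growth ranks
    by k_growth and lipid ranks by k_lipid, sum, and order strains by the
    summed score (ties broken by strain id). Returns strain ids best-first.
    """
    strains = list(table.index)
    n = len(strains)
    scores = {s: 0.0 for s in strains}
    for col in table.columns:
        ascending = kinds[col] == "t_max"
        vals = table[col]
        ranks = {}
        present = [s for s in strains if not (isinstance(vals[s], float) and math.isnan(vals[s]))]
        ordered = sorted(present, key=lambda s: vals[s], reverse=not ascending)
        # best value first -> rank n, n-1, ...; average ranks over ties
        pos = 0
        while pos < len(ordered):
            j = pos
            while j + 1 < len(ordered) and vals[ordered[j + 1]] == vals[ordered[pos]]:
                j += 1
            avg = np.mean([n - q for q in range(pos, j + 1)])
            for q in range(pos, j + 1):
                ranks[ordered[q]] = avg
            pos = j + 1
        for s in strains:
            if s not in ranks:
                ranks[s] = 1.0  # missing -> worst
            k = k_growth if kinds[col] in ("fitness", "t_max") else k_lipid
            scores[s] += k * ranks[s]
    return sorted(strains, key=lambda s: (-scores[s], str(s)))
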