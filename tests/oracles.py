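"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's implementation paths: the k-NN
oracle enumerates every candidate neighbor and distance with plain Python
loops; the ssGSEA oracle walks the ranked list element by element; the
Mann-Whitney oracle enumerates all group assignments of the pooled values.
"""

import itertools
import math

import numpy as np
import pandas as pd


def knn_impute_oracle(df: pd.DataFrame, k: int, min_quant_frac: float = 0.5):
    """Exhaustive k-NN imputation: all pairwise distances, ties by id."""
    obs_frac = df.notna().mean(axis=1)
    kept = df.loc[obs_frac >= min_quant_frac].copy()
    out = kept.copy()
    for prot in kept.index:
        row = kept.loc[prot]
        for s in kept.columns:
            if not pd.isna(row[s]):
                continue
            candidates = []
            for other in kept.index:
                if other == prot or pd.isna(kept.loc[other, s]):
                    continue
                both = row.notna() & kept.loc[other].notna()
                if not both.any():
                    continue
                d = math.sqrt(float(((row[both] - kept.loc[other, both]) ** 2).sum()))
                candidates.append((d, other))
            candidates.sort(key=lambda t: (t[0], t[1]))
            chosen = candidates[:k]
            if chosen:
                out.loc[prot, s] = float(
                    np.mean([kept.loc[o, s] for _, o in chosen]))
    return out


def ssgsea_oracle(values: pd.Series, members, alpha: float) -> float:
    """Step-by-step weighted running-sum enrichment score."""
    members = set(members)
    n = len(values)
    m = sum(1 for f in values.index if f in members)
    # average ranks, ascending (top abundance -> rank ~ n)
    order_asc = sorted(values.index, key=lambda f: (values[f], f))
    rank = {}
    i = 0
    vals_sorted = [values[f] for f in order_asc]
    while i < n:
        j = i
        while j + 1 < n and vals_sorted[j + 1] == vals_sorted[i]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            rank[order_asc[t]] = avg
        i = j + 1
    walk = sorted(values.index, key=lambda f: (-values[f], f))
    norm = sum(rank[f] ** alpha for f in walk if f in members)
    score = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for f in walk:
        if f in members:
            cum_in += rank[f] ** alpha / norm
        else:
            cum_out += 1.0 / (n - m)
        score += cum_in - cum_out
    return score


def mwu_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Assumes no ties in the pooled sample. Returns (U_x, p_two_sided) with
    p = 2 * min(P(U <= u), P(U >= u)) capped at 1.
    """
    x = list(x)
    y = list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)

    def u_stat(a, b):
        return sum(1 for ai in a for bi in b if ai > bi)

    u_obs = u_stat(x, y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(u_stat(a, b))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))
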