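"""Independent brute-force oracles shared by the test modules."""

import itertools

import numpy as np
from scipy import stats as sps


def mann_whitney_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumeration of all group assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), na):
        us.append(ranks[list(combo)].sum() - na * (na + 1) / 2)
    us = np.asarray(us)
    mu = len(a) * len(b) / 2
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-9))


def fisher_exact_oracle(table):
    """Two-sided Fisher p: sum of hypergeometric tables at most as probable."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = sps.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    probs = rv.pmf(support)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())
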