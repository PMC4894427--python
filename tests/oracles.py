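"""Independent oracles used by the test suite.

These deliberately avoid the package's own fitting code paths: the mixed
model is evaluated through an explicit covariance matrix and scipy's
multivariate normal density, maximized by a refined brute-force grid over
the two variance components with numerical GLS means at each grid point.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import multivariate_normal

SPECIES = ("human", "chimpanzee", "rhesus")
PAIR_MEMBERS = {"HC": ("human", "chimpanzee"),
                "HR": ("human", "rhesus"),
                "CR": ("chimpanzee", "rhesus")}


def brute_mixed_llf(y, species, individual, equal_pair=None,
                    n_grid=17, n_rounds=3):
    """Maximized Gaussian log-likelihood of the random-intercept model.

    Brute-force grid over (sigma_ind^2, sigma_rep^2), refined around the
    running optimum; species means by GLS solve at each grid point.
    """
    y = np.asarray(y, dtype=float)
    inds = list(dict.fromkeys(individual))
    Z = np.array([[1.0 if individual[k] == i else 0.0 for i in inds]
                  for k in range(len(y))])
    mapping = {s: s for s in SPECIES}
    if equal_pair is not None:
        a, b = PAIR_MEMBERS[equal_pair]
        mapping[a] = mapping[b] = a + b
    glabels = [mapping[s] for s in species]
    gl = list(dict.fromkeys(glabels))
    X = np.array([[1.0 if glabels[k] == g else 0.0 for g in gl]
                  for k in range(len(y))])
    ZZt = Z @ Z.T
    eye = np.eye(len(y))
    tot = float(np.var(y))

    def ll(sa2, se2):
        V = sa2 * ZZt + se2 * eye
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        return multivariate_normal.logpdf(y, mean=X @ beta, cov=V)

    lo_a, hi_a = 0.0, 4 * tot
    lo_e, hi_e = 1e-6, 4 * tot
    best = (-np.inf, (tot / 2, tot / 2))
    for _ in range(n_rounds):
        for sa in np.linspace(lo_a, hi_a, n_grid):
            for se in np.linspace(lo_e, hi_e, n_grid):
                v = ll(sa, se)
                if v > best[0]:
                    best = (v, (sa, se))
        sa, se = best[1]
        da = (hi_a - lo_a) / (n_grid - 1)
        de = (hi_e - lo_e) / (n_grid - 1)
        lo_a, hi_a = max(0.0, sa - da), sa + da
        lo_e, hi_e = max(1e-8, se - de), se + de
    return best[0]


def brute_lr(y, species, individual, pair):
    """Likelihood-ratio statistic from the brute-force oracle."""
    full = brute_mixed_llf(y, species, individual)
    red = brute_mixed_llf(y, species, individual, equal_pair=pair)
    return 2.0 * (full - red)


def bh_by_hand(pvalues):
    """Step-up BH adjustment computed directly from its definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def exhaustive_split_p(values, n_low, statistic):
    """Exact one-sided permutation p for a two-group median difference.

    Enumerates every assignment of ``n_low`` of the values to the low
    group; returns the fraction of assignments with median(low) -
    median(high) >= the observed statistic.
    """
    values = np.asarray(values, dtype=float)
    idx = range(len(values))
    count = total = 0
    for low in itertools.combinations(idx, n_low):
        low = list(low)
        high = [i for i in idx if i not in set(low)]
        stat = np.median(values[low]) - np.median(values[high])
        count += stat >= statistic - 1e-15
        total += 1
    return count / total


def exhaustive_relabel_coupling_p(R, S, statistic):
    """Exact node-relabeling null for the coupling median difference.

    ``R``: symmetric correlation matrix; ``S``: same-reaction mask.
    Enumerates all node permutations.
    """
    n = R.shape[0]
    iu = np.triu_indices(n, k=1)
    r_all = R[iu]
    count = total = 0
    for perm in itertools.permutations(range(n)):
        perm = np.asarray(perm)
        Sp = S[np.ix_(perm, perm)][iu]
        stat = np.median(r_all[Sp]) - np.median(r_all[~Sp])
        count += stat >= statistic - 1e-15
        total += 1
    return count / total


def exhaustive_group_mean_p(values, n_a, statistic):
    """Exact one-sided permutation p for a two-group mean difference."""
    values = np.asarray(values, dtype=float)
    idx = range(len(values))
    count = total = 0
    for ga in itertools.combinations(idx, n_a):
        ga = list(ga)
        gb = [i for i in idx if i not in set(ga)]
        stat = values[ga].mean() - values[gb].mean()
        count += stat >= statistic - 1e-15
        total += 1
    return count / total
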