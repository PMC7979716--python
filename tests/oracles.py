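"""Independent brute-force oracles shared by the unit and acceptance suites.

These enumerate the exact null distributions directly (itertools over
permutations, sign flips or labellings) and never call the implementations
they check.
"""

import itertools
import math

import numpy as np
from scipy import stats as sps


def oracle_spearman_p(x, y):
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)

    def rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))

    obs = abs(rho(rx, ry))
    count = sum(abs(rho(rx, np.array(p))) >= obs - 1e-12
                for p in itertools.permutations(ry))
    return count / math.factorial(len(x))


def oracle_wilcoxon_p(diff):
    r = sps.rankdata(np.abs(diff))
    w = r[diff > 0].sum()
    lo = hi = 0
    for signs in itertools.product([1, -1], repeat=len(diff)):
        wp = sum(ri for ri, s in zip(r, signs) if s > 0)
        lo += wp <= w + 1e-12
        hi += wp >= w - 1e-12
    n = 2 ** len(diff)
    return min(1.0, 2.0 * min(lo, hi) / n)


def oracle_mannwhitney_p(g1, g2):
    pooled = np.concatenate([g1, g2])
    ranks = sps.rankdata(pooled)
    n1 = len(g1)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array([sum(ranks[list(c)]) - n1 * (n1 + 1) / 2
                   for c in itertools.combinations(range(len(pooled)), n1)])
    lo = (us <= u_obs + 1e-12).mean()
    hi = (us >= u_obs - 1e-12).mean()
    return min(1.0, 2.0 * min(lo, hi))


def brute_force_band(tumour, roi, band_um, px):
    """Zone-B oracle: explicit disk-offset dilation (exact Euclidean rule)."""
    r = int(np.floor(band_um / px))
    h, w = tumour.shape
    pad = np.zeros((h + 2 * r, w + 2 * r), dtype=bool)
    pad[r:r + h, r:r + w] = tumour
    near = np.zeros_like(tumour)
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            if (di * di + dj * dj) * px * px > band_um * band_um:
                continue
            near |= pad[r + di:r + di + h, r + dj:r + dj + w]
    return near & roi & ~tumour
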