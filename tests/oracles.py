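"""Independent brute-force oracles used by the tests.

These deliberately re-derive the consensus rules and Fisher's method from
their definitions, edge by edge, without touching the package's vectorized
implementations.
"""

import math

import numpy as np
from scipy import stats


def sv_oracle_include(edge_weights, theta):
    """Simple-voting inclusion for one edge given its w per-network weights.

    M = max(#negatives, #positives); include iff M >= floor(theta*w) and
    the edge is present somewhere (M >= 1).
    """
    signs = [0 if x == 0 else (1 if x > 0 else -1) for x in edge_weights]
    m = max(signs.count(1), signs.count(-1))
    w = len(edge_weights)
    return m >= math.floor(theta * w) and m >= 1


def ss_oracle_include(edge_weights, network_maxima, theta):
    """Scaled-sum inclusion for one edge.

    ``network_maxima`` are max|weights| per network (0 for empty networks,
    which contribute nothing).  include iff |sum_i w_i/max_i| > (w-1)*theta
    and the sum is nonzero.
    """
    s = 0.0
    for x, peak in zip(edge_weights, network_maxima):
        if peak > 0:
            s += x / peak
    w = len(edge_weights)
    return abs(s) > (w - 1) * theta and s != 0


def fisher_merge(pvalue_matrices):
    """Fisher's combined p-value, edge by edge."""
    mats = [np.asarray(m) for m in pvalue_matrices]
    k = len(mats)
    out = np.empty_like(mats[0])
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            psi = -2.0 * sum(math.log(m[i, j]) for m in mats)
            out[i, j] = stats.chi2.sf(psi, 2 * k)
    return out
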