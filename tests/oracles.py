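"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the transport oracle
solves the earth-mover LP directly, the per-base CNV oracle expands
segments to individual bases, and the product-limit oracle walks risk
sets by hand.
"""

import numpy as np
from scipy.optimize import linprog


def transport_cost(f1, f2):
    """Optimal 1-D transport cost between histograms, cost |i - j| bins.

    Solved as an explicit linear program over the full coupling matrix.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    n = len(f1)
    cost = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).ravel()
    # row-sum and column-sum equality constraints (last one redundant)
    a_eq = []
    for i in range(n):
        row = np.zeros((n, n))
        row[i, :] = 1.0
        a_eq.append(row.ravel())
    for j in range(n):
        col = np.zeros((n, n))
        col[:, j] = 1.0
        a_eq.append(col.ravel())
    b_eq = np.concatenate([f1, f2])
    res = linprog(cost, A_eq=np.array(a_eq)[:-1], b_eq=b_eq[:-1], bounds=(0, None), method="highs")
    assert res.success
    return res.fun


def per_base_cnv_std(profile):
    """Population std of segment means expanded base-by-base."""
    values = np.concatenate(
        [np.full(seg.length, seg.segment_mean) for seg in profile.segments]
    )
    return float(np.std(values))


def product_limit(times, events):
    """Kaplan-Meier by direct risk-set accounting; returns (times, probs)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(times[events]):
        at_risk = np.sum(times >= t)
        deaths = np.sum((times == t) & events)
        s *= 1.0 - deaths / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)
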