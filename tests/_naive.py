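"""Deliberately naive MFDFA used as an independent oracle.

Explicit loops over segments and scales, np.polyfit per segment on the raw
1..n abscissa, direct power means — no code shared with the optimised
implementation in mfpatch.mfdfa.
"""

import numpy as np


def naive_segment_variances(profile, n, order=1):
    N = len(profile)
    m = N // n
    t = np.arange(1, n + 1, dtype=float)
    f2 = []
    for nu in range(m):  # forward
        seg = np.asarray(profile[nu * n : (nu + 1) * n], dtype=float)
        coef = np.polyfit(t, seg, order)
        f2.append(np.mean((seg - np.polyval(coef, t)) ** 2))
    for nu in range(m):  # backward, tiling from the end
        seg = np.asarray(profile[N - (nu + 1) * n : N - nu * n], dtype=float)
        coef = np.polyfit(t, seg, order)
        f2.append(np.mean((seg - np.polyval(coef, t)) ** 2))
    return np.array(f2)


def naive_fq(f2, q):
    f2 = np.asarray(f2, dtype=float)
    pos = f2 > 0
    if q == 0:
        return float(np.exp(0.5 * np.mean(np.log(f2[pos]))))
    if q > 0:
        return float((np.sum(f2[pos] ** (q / 2.0)) / f2.size) ** (1.0 / q))
    return float(np.mean(f2[pos] ** (q / 2.0)) ** (1.0 / q))


def naive_mfdfa(x, q_values, scales, order=1):
    """F_q(n) matrix (len(q_values), len(scales)) by brute force."""
    x = np.asarray(x, dtype=float)
    profile = np.cumsum(x - x.mean())
    fq = np.empty((len(q_values), len(scales)))
    for j, n in enumerate(scales):
        f2 = naive_segment_variances(profile, int(n), order)
        for i, q in enumerate(q_values):
            fq[i, j] = naive_fq(f2, float(q))
    return fq


def naive_hurst(scales, fq_row):
    slope, _ = np.polyfit(np.log(scales), np.log(fq_row), 1)
    return float(slope)
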