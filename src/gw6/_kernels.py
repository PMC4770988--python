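"""Numerical kernels for the sliding-correlation inner loops.

The windowed Pearson correlation over all channel pairs is the hot path of
the whole analysis (Nt × n_samples running windows at step 1). The jitted
kernels keep a running window sum per pair instead of materialising
full-length cumulative arrays; over float64 and window lengths of tens of
samples the accumulator drift is ~n·eps and irrelevant at the 1e-10 level.

Numba is optional: if it is missing, the vectorised NumPy fallbacks in
:mod:`gw6.core` are used instead (identical results, a few times slower).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def pair_corr_kernel(data, ia, ib, L):  # pragma: no cover - jitted
    """Windowed Pearson r for each (ia[k], ib[k]) channel pair, centred, edge-copied.

    Returns (r, n_degenerate) where degenerate windows (zero variance in
    either channel) produce r = 0.
    """
    npairs = ia.shape[0]
    n = data.shape[1]
    nvalid = n - L + 1
    half = L // 2
    out = np.empty((npairs, n))
    ndegen = 0
    for k in range(npairs):
        a = data[ia[k]]
        b = data[ib[k]]
        sa = 0.0
        sb = 0.0
        saa = 0.0
        sbb = 0.0
        sab = 0.0
        for i in range(L):
            sa += a[i]
            sb += b[i]
            saa += a[i] * a[i]
            sbb += b[i] * b[i]
            sab += a[i] * b[i]
        for start in range(nvalid):
            va = saa - sa * sa / L
            vb = sbb - sb * sb / L
            denom = va * vb
            if denom <= 0.0:
                r = 0.0
                ndegen += 1
            else:
                r = (sab - sa * sb / L) / np.sqrt(denom)
                if r > 1.0:
                    r = 1.0
                elif r < -1.0:
                    r = -1.0
            out[k, half + start] = r
            if start + L < n:
                j = start + L
                sa += a[j] - a[start]
                sb += b[j] - b[start]
                saa += a[j] * a[j] - a[start] * a[start]
                sbb += b[j] * b[j] - b[start] * b[start]
                sab += a[j] * b[j] - a[start] * b[start]
        for x in range(half):
            out[k, x] = out[k, half]
        for x in range(half + nvalid, n):
            out[k, x] = out[k, half + nvalid - 1]
    return out, ndegen


@njit(cache=True)
def epoch_mean_kernel(traces, starts, length):  # pragma: no cover - jitted
    """Mean over stimulus-locked windows of a (rows, n) array: R'(I, X)."""
    rows = traces.shape[0]
    m = starts.shape[0]
    out = np.zeros((rows, length))
    for s in range(m):
        st = starts[s]
        for r in range(rows):
            for x in range(length):
                out[r, x] += traces[r, st + x]
    return out / m
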