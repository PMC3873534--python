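"""Hartigan's dip statistic of unimodality with Monte Carlo calibration.

The dip of a sample is the smallest sup-norm distance between its empirical
distribution function and any unimodal distribution function (one convex to
the left of its mode and concave to the right, a jump at the mode allowed).
It is computed by the classical iterative construction: within a shrinking
candidate modal interval the greatest convex minorant (GCM) and least
concave majorant (LCM) of the empirical CDF are intersected until the
maximum distance between them no longer exceeds the largest deviation of
the CDF from the GCM fit below the interval and from the LCM fit above it.

P-values are calibrated by Monte Carlo against the uniform distribution,
the standard reference null: the dip of ``n`` uniforms stochastically
dominates the dip of samples from any unimodal law, making the test
conservative.  The null distribution depends only on the sample size, so it
is cached per ``(n, n_reference, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DipResult", "dip_statistic", "dip_test"]


@dataclass(frozen=True)
class DipResult:
    dip_statistic: float
    p_value: float
    n: int
    n_reference: int


def _minorant_pointers(x: np.ndarray) -> np.ndarray:
    """For each i the previous touch index of the greatest convex minorant."""
    n = x.size
    mn = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        mn[i] = i - 1
        while True:
            j = mn[i]
            if j == 0:
                break
            k = mn[j]
            if (x[i] - x[j]) * (j - k) < (x[j] - x[k]) * (i - j):
                break
            mn[i] = k
    return mn


def _majorant_pointers(x: np.ndarray) -> np.ndarray:
    """For each i the next touch index of the least concave majorant."""
    n = x.size
    mj = np.zeros(n, dtype=np.int64)
    mj[n - 1] = n - 1
    for i in range(n - 2, -1, -1):
        mj[i] = i + 1
        while True:
            j = mj[i]
            if j == n - 1:
                break
            k = mj[j]
            if (x[i] - x[j]) * (j - k) < (x[j] - x[k]) * (i - j):
                break
            mj[i] = k
    return mj


def dip_statistic(values) -> float:
    """Hartigan's dip of a one-dimensional sample.

    Bounded below by ``1/(2n)`` for non-degenerate samples; 0 for samples
    with fewer than two distinct values.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    if n < 2 or x[0] == x[-1]:
        return 0.0
    mn = _minorant_pointers(x)
    mj = _majorant_pointers(x)

    low, high = 0, n - 1
    dip = 1.0  # in count units; final value divided by 2n

    while True:
        # GCM touch points from high down to low, LCM from low up to high.
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))

        if len(gcm) > 2 or len(lcm) > 2:
            # Walk both curves from low upward; d is the largest vertical gap
            # between LCM and GCM (in counts), recorded with its location.
            d = 0.0
            ig = len(gcm) - 1
            ih = 0
            ix = len(gcm) - 2
            iv = 1
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next change point comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next change point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > len(lcm) - 1:
                    iv = len(lcm) - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
            ig, ih = len(gcm) - 1, len(lcm) - 1

        if d < dip:
            break

        # Largest deviation of the CDF above the GCM below the modal interval…
        dip_l = 0.0
        for j in range(ig, len(gcm) - 1):
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if t > dip_l:
                        dip_l = t
        # …and below the LCM above it.
        dip_u = 0.0
        for j in range(ih, len(lcm) - 1):
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if t > dip_u:
                        dip_u = t

        dipnew = max(dip_l, dip_u)
        if dipnew > dip:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low, high = gcm[ig], lcm[ih]

    return dip / (2.0 * n)


_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _null_dips(n: int, n_reference: int, seed: int) -> np.ndarray:
    key = (n, n_reference, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(97,)))
        _NULL_CACHE[key] = np.array(
            [dip_statistic(rng.random(n)) for _ in range(n_reference)]
        )
    return _NULL_CACHE[key]


def dip_test(values, n_reference: int = 2000, seed: int = 0) -> DipResult:
    """Dip test of unimodality with a uniform Monte Carlo reference.

    ``p = (1 + #{null dips >= observed}) / (n_reference + 1)`` over
    ``n_reference`` uniform samples of the same size.  Requires at least 4
    observations.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError("dip test requires at least 4 finite observations")
    obs = dip_statistic(x)
    null = _null_dips(x.size, n_reference, seed)
    p = (1 + int(np.sum(null >= obs))) / (n_reference + 1)
    return DipResult(obs, p, int(x.size), n_reference)
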