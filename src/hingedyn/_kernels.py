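"""Single-source integrator kernel for the hinge Langevin/metadynamics runs.

The kernel is written once in plain Python (IEEE-ordered scalar arithmetic)
and compiled with numba when available; both paths execute the identical
expression sequence, so their results agree bitwise and the interpreted
path doubles as the reference implementation.

Bias modes: 0 = unbiased, 1 = single CV theta (radians), 2 = single CV w
(nm), 3 = two CVs (theta_rad, w).  The bias lives on per-CV uniform grids
(value and d/ds arrays, linear interpolation); hills are deposited inside
the kernel out to ``cut`` sigma with the tempered height taken from the
grid-interpolated bias.

Deposited hill centers and heights are quantized to 9 significant decimal
digits (the package's text precision), so a HILLS file replay rebuilds the
bias grids bit-for-bit and a resumed run continues byte-identically.
"""

from __future__ import annotations

import math

import numpy as np

_DEG = math.pi / 180.0


def _q9_py(x):
    """Quantize to 9 significant decimal digits (exact text round trip)."""
    if x == 0.0:
        return 0.0
    e = math.floor(math.log10(abs(x)))
    s = 10.0 ** (8 - e)
    return round(x * s) / s


def _deposit_1d_py(c, h, cut, sig, lo, inv, ax, v, d):
    jlo = int((c - cut * sig - lo) * inv) + 1
    if jlo < 0:
        jlo = 0
    jhi = int((c + cut * sig - lo) * inv) + 1
    if jhi > v.shape[0]:
        jhi = v.shape[0]
    for j in range(jlo, jhi):
        x = ax[j] - c
        gg = h * math.exp(-x * x / (2.0 * sig * sig))
        v[j] += gg
        d[j] += gg * (-x / (sig * sig))


def _deposit_2d_py(c1, c2, h, cut, sig1, sig2, lo1, inv1, ax1,
                   lo2, inv2, ax2, v, da, db):
    jlo = int((c1 - cut * sig1 - lo1) * inv1) + 1
    if jlo < 0:
        jlo = 0
    jhi = int((c1 + cut * sig1 - lo1) * inv1) + 1
    if jhi > v.shape[0]:
        jhi = v.shape[0]
    klo = int((c2 - cut * sig2 - lo2) * inv2) + 1
    if klo < 0:
        klo = 0
    khi = int((c2 + cut * sig2 - lo2) * inv2) + 1
    if khi > v.shape[1]:
        khi = v.shape[1]
    for j in range(jlo, jhi):
        x1 = ax1[j] - c1
        g1 = math.exp(-x1 * x1 / (2.0 * sig1 * sig1))
        for k in range(klo, khi):
            x2 = ax2[k] - c2
            gg = h * g1 * math.exp(-x2 * x2 / (2.0 * sig2 * sig2))
            v[j, k] += gg
            da[j, k] += gg * (-x1 / (sig1 * sig1))
            db[j, k] += gg * (-x2 / (sig2 * sig2))


# module-level names the kernel closes over; rebound to the numba-compiled
# versions below before the kernel itself is (lazily) compiled
_q9 = _q9_py
_deposit_1d = _deposit_1d_py
_deposit_2d = _deposit_2d_py


def _interp_1d_py(s, lo, inv, top, arr):
    f = (s - lo) * inv
    j = int(f)
    if j < 0:
        j = 0
        f = 0.0
    elif j > top:
        j = top
        f = 1.0
    else:
        f -= j
    return (1.0 - f) * arr[j] + f * arr[j + 1]


def _interp_2d_py(s1, s2, lo1, inv1, top1, lo2, inv2, top2, arr):
    f = (s1 - lo1) * inv1
    j = int(f)
    if j < 0:
        j = 0
        f = 0.0
    elif j > top1:
        j = top1
        f = 1.0
    else:
        f -= j
    g = (s2 - lo2) * inv2
    k = int(g)
    if k < 0:
        k = 0
        g = 0.0
    elif k > top2:
        k = top2
        g = 1.0
    else:
        g -= k
    return ((1.0 - f) * ((1.0 - g) * arr[j, k] + g * arr[j, k + 1])
            + f * ((1.0 - g) * arr[j + 1, k] + g * arr[j + 1, k + 1]))


_interp_1d = _interp_1d_py
_interp_2d = _interp_2d_py


def _core_py(theta, w, step0, n_steps, noise,
             dt_g, amp, B, A, tm, dl, kw, w0n, coup,
             mode, pace_steps, w0h, inv_kbdt, cut,
             lo1, inv1, sig1, ax1, v1, d1,
             lo2, inv2, sig2, ax2, v2, d2a, d2b,
             stride, rec_theta, rec_w, rec_bias, rec_k0,
             hill_c1, hill_c2, hill_h, hill_step, hill_k0):
    """Advance ``n_steps`` steps from global step ``step0``.

    Mutates the grids and record/hill arrays in place; returns
    (theta, w, rec_k, hill_k, reflections).
    """
    top1 = v1.shape[0] - 2
    topa = v2.shape[0] - 2
    topb = v2.shape[1] - 2
    rec_k = rec_k0
    hill_k = hill_k0
    refl = 0
    for i in range(n_steps):
        u = (theta - tm) / dl
        ft = (4.0 * B * u * (u * u - 1.0) + 0.5 * A) / dl + coup * (w - w0n)
        fw = kw * (w - w0n) + coup * (theta - tm)

        if mode == 1:
            ft += _interp_1d(theta * _DEG, lo1, inv1, top1, d1) * _DEG
        elif mode == 2:
            fw += _interp_1d(w, lo1, inv1, top1, d1)
        elif mode == 3:
            ft += _interp_2d(theta * _DEG, w, lo1, inv1, topa,
                             lo2, inv2, topb, d2a) * _DEG
            fw += _interp_2d(theta * _DEG, w, lo1, inv1, topa,
                             lo2, inv2, topb, d2b)

        theta += -dt_g * ft + amp * noise[i, 0]
        w += -dt_g * fw + amp * noise[i, 1]
        if theta <= 0.0:
            theta = -theta
            refl += 1
        elif theta >= 180.0:
            theta = 360.0 - theta
            refl += 1
        if w <= 0.0:
            w = -w
            refl += 1

        step = step0 + i + 1

        if mode != 0 and pace_steps > 0 and step % pace_steps == 0:
            if mode == 3:
                vcur = _interp_2d(theta * _DEG, w, lo1, inv1, topa,
                                  lo2, inv2, topb, v2)
            elif mode == 1:
                vcur = _interp_1d(theta * _DEG, lo1, inv1, top1, v1)
            else:
                vcur = _interp_1d(w, lo1, inv1, top1, v1)
            h = _q9(w0h * math.exp(-vcur * inv_kbdt))

            if mode == 3:
                c1 = _q9(theta * _DEG)
                c2 = _q9(w)
                _deposit_2d(c1, c2, h, cut, sig1, sig2, lo1, inv1, ax1,
                            lo2, inv2, ax2, v2, d2a, d2b)
                hill_c1[hill_k] = c1
                hill_c2[hill_k] = c2
            else:
                c = _q9(theta * _DEG) if mode == 1 else _q9(w)
                _deposit_1d(c, h, cut, sig1, lo1, inv1, ax1, v1, d1)
                hill_c1[hill_k] = c
                hill_c2[hill_k] = np.nan
            hill_h[hill_k] = h
            hill_step[hill_k] = step
            hill_k += 1

        if stride > 0 and step % stride == 0:
            rec_theta[rec_k] = theta
            rec_w[rec_k] = w
            if mode == 3:
                rec_bias[rec_k] = _interp_2d(theta * _DEG, w, lo1, inv1,
                                             topa, lo2, inv2, topb, v2)
            elif mode == 1:
                rec_bias[rec_k] = _interp_1d(theta * _DEG, lo1, inv1,
                                             top1, v1)
            elif mode == 2:
                rec_bias[rec_k] = _interp_1d(w, lo1, inv1, top1, v1)
            rec_k += 1
    return theta, w, rec_k, hill_k, refl


try:  # compiled path: same source, bit-identical results
    from numba import njit

    _q9 = njit(cache=False)(_q9_py)
    _deposit_1d = njit(cache=False)(_deposit_1d_py)
    _deposit_2d = njit(cache=False)(_deposit_2d_py)
    _interp_1d = njit(cache=False)(_interp_1d_py)
    _interp_2d = njit(cache=False)(_interp_2d_py)
    core = njit(cache=False)(_core_py)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    core = _core_py
    HAVE_NUMBA = False

core_py = _core_py
q9 = _q9
deposit_1d = _deposit_1d
deposit_2d = _deposit_2d
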