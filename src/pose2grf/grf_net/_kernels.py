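"""Optional numba-compiled recurrent kernels.

The pure-numpy implementation in :mod:`pose2grf.grf_net.layers` is the
reference; these kernels compute the identical recursions with compiled
per-timestep loops, which removes the Python dispatch overhead that
dominates at the hidden sizes this package trains. Selected automatically
when numba imports; the gradient tests exercise whichever path is active,
and a dedicated test checks the two paths agree when numba is present.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f

        return deco


@njit(cache=False)
def lstm_seq_forward(XW, U, reverse):  # pragma: no cover - compiled
    B, T, H4 = XW.shape
    H = H4 // 4
    dt = XW.dtype
    Hs = np.zeros((B, T, H), dtype=dt)
    I_ = np.empty((B, T, H), dtype=dt)
    F_ = np.empty((B, T, H), dtype=dt)
    G_ = np.empty((B, T, H), dtype=dt)
    O_ = np.empty((B, T, H), dtype=dt)
    Cprev = np.empty((B, T, H), dtype=dt)
    TC = np.empty((B, T, H), dtype=dt)
    h = np.zeros((B, H), dtype=dt)
    c = np.zeros((B, H), dtype=dt)
    for step in range(T):
        t = T - 1 - step if reverse else step
        z = XW[:, t, :] + np.dot(h, U)
        for bi in range(B):
            for k in range(H):
                i = 1.0 / (1.0 + np.exp(-z[bi, k]))
                f = 1.0 / (1.0 + np.exp(-z[bi, H + k]))
                g = np.tanh(z[bi, 2 * H + k])
                o = 1.0 / (1.0 + np.exp(-z[bi, 3 * H + k]))
                cp = c[bi, k]
                cn = f * cp + i * g
                tc = np.tanh(cn)
                I_[bi, t, k] = i
                F_[bi, t, k] = f
                G_[bi, t, k] = g
                O_[bi, t, k] = o
                Cprev[bi, t, k] = cp
                TC[bi, t, k] = tc
                c[bi, k] = cn
                h[bi, k] = o * tc
        Hs[:, t, :] = h
    return Hs, I_, F_, G_, O_, Cprev, TC


@njit(cache=False)
def lstm_seq_backward(dHs, I_, F_, G_, O_, Cprev, TC, UT, reverse):  # pragma: no cover
    B, T, H = dHs.shape
    dt = dHs.dtype
    dZ = np.empty((B, T, 4 * H), dtype=dt)
    dh_next = np.zeros((B, H), dtype=dt)
    dc_next = np.zeros((B, H), dtype=dt)
    for step in range(T):
        t = step if reverse else T - 1 - step
        dz_t = np.empty((B, 4 * H), dtype=dZ.dtype)
        for bi in range(B):
            for k in range(H):
                i = I_[bi, t, k]
                f = F_[bi, t, k]
                g = G_[bi, t, k]
                o = O_[bi, t, k]
                cp = Cprev[bi, t, k]
                tc = TC[bi, t, k]
                dh = dHs[bi, t, k] + dh_next[bi, k]
                do = dh * tc
                dc = dc_next[bi, k] + dh * o * (1.0 - tc * tc)
                dc_next[bi, k] = dc * f
                dz_t[bi, k] = dc * g * i * (1.0 - i)
                dz_t[bi, H + k] = dc * cp * f * (1.0 - f)
                dz_t[bi, 2 * H + k] = dc * i * (1.0 - g * g)
                dz_t[bi, 3 * H + k] = do * o * (1.0 - o)
        dZ[:, t, :] = dz_t
        dh_next = np.dot(dz_t, UT)
    return dZ
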