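"""Compiled kernels for the growth-maximization optimal control problem.

The control is piecewise constant on N intervals; the augmented state
(p_hat, r_hat, log_vol) is advanced with fixed-step classical Runge-Kutta
(``nsub`` substeps per control interval).  The gradient of the biomass
objective with respect to every interval's allocation is obtained by an
exact discrete adjoint sweep through the stored Runge-Kutta stages, so the
objective/gradient pair is consistent to machine precision -- a requirement
for resolving the nearly flat singular arc and the chattering entry.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_states", "objective_and_gradient"]


@njit(cache=True, inline="always")
def _f(p, r, a, EM, K):
    mu = r * p / (K + p)
    return (1.0 - r) * EM - (1.0 + p) * mu, mu * (a - r), mu


@njit(cache=True, inline="always")
def _jac(p, r, a, EM, K):
    """Jacobian of (dp, dr, dv) wrt (p, r); v never feeds back."""
    d = K + p
    mu = r * p / d
    mu_p = r * K / (d * d)
    mu_r = p / d
    a00 = -mu - (1.0 + p) * mu_p
    a01 = -EM - (1.0 + p) * mu_r
    a10 = mu_p * (a - r)
    a11 = mu_r * (a - r) - mu
    return a00, a01, a10, a11, mu_p, mu_r


@njit(cache=True)
def forward_states(alpha, p0, r0, EM, K, h, nsub):
    """Integrate forward; returns node states, shape (N+1, 3)."""
    N = alpha.shape[0]
    out = np.empty((N + 1, 3))
    p, r, v = p0, r0, 0.0
    out[0, 0], out[0, 1], out[0, 2] = p, r, v
    for k in range(N):
        a = alpha[k]
        for _ in range(nsub):
            k1p, k1r, k1v = _f(p, r, a, EM, K)
            k2p, k2r, k2v = _f(p + 0.5 * h * k1p, r + 0.5 * h * k1r, a, EM, K)
            k3p, k3r, k3v = _f(p + 0.5 * h * k2p, r + 0.5 * h * k2r, a, EM, K)
            k4p, k4r, k4v = _f(p + h * k3p, r + h * k3r, a, EM, K)
            p += h / 6.0 * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
            r += h / 6.0 * (k1r + 2.0 * k2r + 2.0 * k3r + k4r)
            v += h / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        out[k + 1, 0], out[k + 1, 1], out[k + 1, 2] = p, r, v
    return out


@njit(cache=True)
def objective_and_gradient(alpha, p0, r0, EM, K, h, nsub, w, pstar, rstar):
    """Biomass objective with terminal anchoring, and its exact gradient.

    Maximized quantity: ``J = log_vol(T) - w*((p_T-p*)^2 + (r_T-r*)^2)``.
    Returns ``(J, dJ/dalpha)``.
    """
    N = alpha.shape[0]
    M = N * nsub
    # stored stage states: (step, stage, component p/r); v stages not needed
    SP = np.empty((M, 4))
    SR = np.empty((M, 4))
    p, r, v = p0, r0, 0.0
    idx = 0
    for k in range(N):
        a = alpha[k]
        for _ in range(nsub):
            k1p, k1r, k1v = _f(p, r, a, EM, K)
            x2p, x2r = p + 0.5 * h * k1p, r + 0.5 * h * k1r
            k2p, k2r, k2v = _f(x2p, x2r, a, EM, K)
            x3p, x3r = p + 0.5 * h * k2p, r + 0.5 * h * k2r
            k3p, k3r, k3v = _f(x3p, x3r, a, EM, K)
            x4p, x4r = p + h * k3p, r + h * k3r
            k4p, k4r, k4v = _f(x4p, x4r, a, EM, K)
            SP[idx, 0], SR[idx, 0] = p, r
            SP[idx, 1], SR[idx, 1] = x2p, x2r
            SP[idx, 2], SR[idx, 2] = x3p, x3r
            SP[idx, 3], SR[idx, 3] = x4p, x4r
            p += h / 6.0 * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
            r += h / 6.0 * (k1r + 2.0 * k2r + 2.0 * k3r + k4r)
            v += h / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
            idx += 1
    J = v - w * ((p - pstar) ** 2 + (r - rstar) ** 2)

    # adjoint sweep
    lp = -2.0 * w * (p - pstar)
    lr = -2.0 * w * (r - rstar)
    lv = 1.0
    grad = np.zeros(N)
    h6 = h / 6.0
    idx = M - 1
    for k in range(N - 1, -1, -1):
        a = alpha[k]
        ga = 0.0
        for _ in range(nsub):
            # stage weights of classical RK4: 1,2,2,1 (scaled by h/6)
            # kbar_i are adjoints of the stage derivatives k_i
            p1, r1 = SP[idx, 0], SR[idx, 0]
            p2, r2 = SP[idx, 1], SR[idx, 1]
            p3, r3 = SP[idx, 2], SR[idx, 2]
            p4, r4 = SP[idx, 3], SR[idx, 3]

            kb4p = h6 * lp
            kb4r = h6 * lr
            kb4v = h6 * lv
            a00, a01, a10, a11, mp4, mr4 = _jac(p4, r4, a, EM, K)
            xb4p = a00 * kb4p + a10 * kb4r + mp4 * kb4v
            xb4r = a01 * kb4p + a11 * kb4r + mr4 * kb4v
            mu4 = r4 * p4 / (K + p4)
            ga += mu4 * kb4r

            kb3p = 2.0 * h6 * lp + h * xb4p
            kb3r = 2.0 * h6 * lr + h * xb4r
            kb3v = 2.0 * h6 * lv
            a00, a01, a10, a11, mp3, mr3 = _jac(p3, r3, a, EM, K)
            xb3p = a00 * kb3p + a10 * kb3r + mp3 * kb3v
            xb3r = a01 * kb3p + a11 * kb3r + mr3 * kb3v
            mu3 = r3 * p3 / (K + p3)
            ga += mu3 * kb3r

            kb2p = 2.0 * h6 * lp + 0.5 * h * xb3p
            kb2r = 2.0 * h6 * lr + 0.5 * h * xb3r
            kb2v = 2.0 * h6 * lv
            a00, a01, a10, a11, mp2, mr2 = _jac(p2, r2, a, EM, K)
            xb2p = a00 * kb2p + a10 * kb2r + mp2 * kb2v
            xb2r = a01 * kb2p + a11 * kb2r + mr2 * kb2v
            mu2 = r2 * p2 / (K + p2)
            ga += mu2 * kb2r

            kb1p = h6 * lp + 0.5 * h * xb2p
            kb1r = h6 * lr + 0.5 * h * xb2r
            kb1v = h6 * lv
            a00, a01, a10, a11, mp1, mr1 = _jac(p1, r1, a, EM, K)
            xb1p = a00 * kb1p + a10 * kb1r + mp1 * kb1v
            xb1r = a01 * kb1p + a11 * kb1r + mr1 * kb1v
            mu1 = r1 * p1 / (K + p1)
            ga += mu1 * kb1r

            lp = lp + xb1p + xb2p + xb3p + xb4p
            lr = lr + xb1r + xb2r + xb3r + xb4r
            # lv unchanged: v is a pure integrator
            idx -= 1
        grad[k] = ga
    return J, grad
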