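r"""Coarse-grained self-replicator model of microbial growth.

The cell is reduced to two macroreactions: the metabolic machinery *M*
converts external substrate into precursor metabolites *P*, and the gene
expression machinery *R* converts precursors into new machinery, a fraction
``alpha`` of the flux going to *R* and ``1 - alpha`` to *M*.  With
concentrations ``p = P/Vol``, ``r = R/Vol`` and the volume proportional to
total macromolecular mass, the dimensional dynamics are

.. math::

    \dot p = e_M(1/\beta - r) - k_R r \frac{p}{K_R + p}(1 + \beta p), \qquad
    \dot r = k_R r \frac{p}{K_R + p}(\alpha - \beta r),

with growth rate :math:`\mu = \beta k_R r p/(K_R+p)`.  Rescaling
``p_hat = beta*p``, ``r_hat = beta*r``, ``t_hat = k_R*t`` leaves a single
parameter ``K = beta*K_R`` plus the environment input ``E_M = e_M/k_R``:

.. math::

    \dot{\hat p} = (1-\hat r)E_M - (1+\hat p)\hat\mu, \qquad
    \dot{\hat r} = \hat\mu\,(\alpha - \hat r), \qquad
    \hat\mu = \frac{\hat p}{K + \hat p}\,\hat r.

This module holds the parameter containers, the right-hand sides, the
steady-state analysis (including the closed-form growth-rate optimum) and the
optimal steady-state curve ``r_hat = g(p_hat)`` that underlies the feedback
strategies.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULTS

__all__ = [
    "DimParams",
    "NondimParams",
    "SteadyState",
    "OptimalAllocation",
    "nondimensionalize",
    "growth_rate_nondim",
    "rhs_nondim",
    "rhs_dim",
    "jacobian_nondim",
    "steady_state_for_alpha",
    "trivial_steady_state",
    "optimal_allocation_env",
    "optimal_allocation_dim",
    "optimal_curve_g",
    "optimal_curve_mu",
    "optimal_precursor",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class DimParams:
    """Dimensional rate constants of the self-replicator.

    e_M : nutrient efficiency [1/h] (environment input, substrate folded in)
    k_R : gene-expression rate constant [1/h]
    K_R : precursor half-saturation of translation [g/L]
    beta: inverse cytoplasmic density [L/g]
    """

    e_M: float = 3.6
    k_R: float = 3.6
    K_R: float = 1.0
    beta: float = 0.003

    def __post_init__(self) -> None:
        _require_positive(e_M=self.e_M, k_R=self.k_R, K_R=self.K_R, beta=self.beta)


@dataclass(frozen=True)
class NondimParams:
    """Nondimensional reduction: ``E_M = e_M/k_R``, ``K = beta*K_R``."""

    E_M: float = 1.0
    K: float = 0.003

    def __post_init__(self) -> None:
        _require_positive(E_M=self.E_M, K=self.K)


def nondimensionalize(params: DimParams) -> tuple[NondimParams, float]:
    """Reduce dimensional parameters to ``(E_M, K)``.

    Returns the nondimensional parameter set together with the time-scale
    factor ``k_R`` converting nondimensional time back to hours
    (``t [h] = t_hat / k_R``).
    """
    return NondimParams(E_M=params.e_M / params.k_R, K=params.beta * params.K_R), params.k_R


def growth_rate_nondim(p_hat: float, r_hat: float, params: NondimParams) -> float:
    """Nondimensional growth rate ``mu_hat = r_hat * p_hat/(K + p_hat)``."""
    p_hat = np.asarray(p_hat, dtype=float)
    return r_hat * p_hat / (params.K + p_hat)


def _check_alpha(alpha: float) -> None:
    a = np.asarray(alpha, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError(f"allocation alpha must lie in [0, 1], got {alpha!r}")


def rhs_nondim(
    p_hat: float, r_hat: float, alpha: float, params: NondimParams
) -> tuple[float, float]:
    """Time derivatives ``(dp_hat/dt_hat, dr_hat/dt_hat)``."""
    _check_alpha(alpha)
    mu = growth_rate_nondim(p_hat, r_hat, params)
    dp = (1.0 - r_hat) * params.E_M - (1.0 + p_hat) * mu
    dr = mu * (alpha - r_hat)
    return dp, dr


def rhs_dim(
    p: float, r: float, alpha: float, params: DimParams
) -> tuple[float, float, float]:
    """Dimensional derivatives ``(dp/dt, dr/dt, dlog(Vol)/dt)``.

    The third component is the growth rate ``mu = beta * v_R``, i.e. the
    derivative of the natural log of population volume.
    """
    _check_alpha(alpha)
    v_M = params.e_M * (1.0 / params.beta - r)
    v_R = params.k_R * r * p / (params.K_R + p)
    mu = params.beta * v_R
    dp = v_M - v_R * (1.0 + params.beta * p)
    dr = v_R * (alpha - params.beta * r)
    return dp, dr, mu


def jacobian_nondim(
    p_hat: float,
    r_hat: float,
    alpha: float,
    params: NondimParams,
    rel_step: float | None = None,
) -> np.ndarray:
    """Central-difference Jacobian of the nondimensional vector field."""
    if rel_step is None:
        rel_step = DEFAULTS.jacobian_rel_step
    x0 = np.array([p_hat, r_hat], dtype=float)
    J = np.empty((2, 2))
    for j in range(2):
        h = rel_step * max(abs(x0[j]), 1.0)
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        fp = rhs_nondim(xp[0], xp[1], alpha, params)
        fm = rhs_nondim(xm[0], xm[1], alpha, params)
        J[:, j] = (np.asarray(fp) - np.asarray(fm)) / (2 * h)
    return J


@dataclass(frozen=True)
class SteadyState:
    """A fixed point of the nondimensional system for constant ``alpha``."""

    p_hat: float
    r_hat: float
    mu_hat: float
    alpha: float
    stable: bool
    eigenvalues: tuple[complex, complex]
    degenerate: bool = False

    @property
    def state(self) -> tuple[float, float]:
        return (self.p_hat, self.r_hat)


def _with_stability(
    p_hat: float, r_hat: float, alpha: float, params: NondimParams, degenerate: bool = False
) -> SteadyState:
    eig = np.linalg.eigvals(jacobian_nondim(p_hat, r_hat, alpha, params))
    return SteadyState(
        p_hat=float(p_hat),
        r_hat=float(r_hat),
        mu_hat=float(growth_rate_nondim(p_hat, r_hat, params)),
        alpha=float(alpha),
        stable=bool(np.all(eig.real < 0)),
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        degenerate=degenerate,
    )


def steady_state_for_alpha(alpha: float, params: NondimParams) -> SteadyState:
    """Nontrivial steady state for a constant allocation ``alpha`` in (0, 1).

    The precursor coordinate is the positive root of a quadratic; the "+"
    branch is the only nonnegative one and is always taken.  At the
    boundaries ``alpha = 0`` (no machinery synthesis, growth stalls) and
    ``alpha = 1`` (machinery only, ``r_hat -> 1``) the quadratic degenerates;
    the limiting fixed point is returned with ``degenerate=True`` and a
    warning.
    """
    E, K = params.E_M, params.K
    if alpha == 0.0:
        # r decays to 0 while p grows without bound: no finite fixed point.
        warnings.warn("alpha = 0 is degenerate: non-growing boundary fixed point")
        return SteadyState(
            p_hat=np.inf, r_hat=0.0, mu_hat=0.0, alpha=0.0, stable=False,
            eigenvalues=(complex(np.nan), complex(np.nan)), degenerate=True,
        )
    if alpha == 1.0:
        warnings.warn("alpha = 1 is degenerate: trivial fixed point (0, 1)")
        return _with_stability(0.0, 1.0, alpha, params, True)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha!r}")
    b = (1.0 - alpha) * E - alpha
    p_star = (b + np.sqrt(b * b + 4.0 * alpha * (1.0 - alpha) * E * K)) / (2.0 * alpha)
    return _with_stability(p_star, alpha, alpha, params)


def trivial_steady_state(params: NondimParams, alpha: float = 0.5) -> SteadyState:
    """The no-growth fixed point ``(p_hat, r_hat) = (0, 1)``.

    With no precursors and the cytoplasm filled by idle machinery the growth
    rate vanishes, so (0, 1) is a fixed point for *every* allocation.  For
    any ``alpha < 1`` it is a saddle (one positive eigenvalue); at the
    degenerate boundary ``alpha = 1`` the unstable direction collapses to a
    center manifold.  Stability is reported at the given ``alpha``.
    """
    return _with_stability(0.0, 1.0, alpha, params)


@dataclass(frozen=True)
class OptimalAllocation:
    """Closed-form growth-rate optimum over constant allocations."""

    alpha: float
    mu_hat: float
    p_hat: float
    r_hat: float
    params: NondimParams = field(repr=False, default=NondimParams())


def optimal_allocation_env(E_M: float, K: float) -> OptimalAllocation:
    r"""Growth-maximizing constant allocation for environment ``(E_M, K)``.

    .. math::

        \alpha^*_{opt} = \frac{E_M + \sqrt{K E_M}}{E_M + 2\sqrt{K E_M} + 1},
        \qquad
        \hat\mu^*_{opt} = \frac{E_M}{E_M + 2\sqrt{K E_M} + 1},

    attained at the precursor level :math:`\hat p^*_{opt} = \sqrt{K E_M}`
    (first-order condition on the steady-state growth rate along the
    precursor nullcline).
    """
    params = NondimParams(E_M=E_M, K=K)
    s = np.sqrt(K * E_M)
    denom = E_M + 2.0 * s + 1.0
    alpha = (E_M + s) / denom
    mu = E_M / denom
    return OptimalAllocation(alpha=float(alpha), mu_hat=float(mu), p_hat=float(s), r_hat=float(alpha), params=params)


def optimal_allocation_dim(e_M: float, k_R: float, K: float) -> tuple[float, float]:
    """Dimensional form of the optimum: returns ``(alpha_opt, mu_opt [1/h])``.

    Identical to the nondimensional route with ``E_M = e_M/k_R`` and
    ``mu_opt = k_R * mu_hat_opt``.
    """
    _require_positive(e_M=e_M, k_R=k_R, K=K)
    s = np.sqrt(K * e_M * k_R)
    denom = e_M + 2.0 * s + k_R
    return float((e_M + s) / denom), float(e_M * k_R / denom)


def optimal_precursor(E_M: float, K: float) -> float:
    """Precursor coordinate of the optimal steady state, ``sqrt(K*E_M)``."""
    return float(np.sqrt(K * E_M))


def optimal_curve_g(p_hat, K: float):
    r"""Optimal steady-state curve ``r_hat = g(p_hat)``.

    ``g(p) = p(K+p) / (p^2 + 2Kp + K)`` maps a precursor level to the
    machinery level that maximizes the steady-state growth rate attainable at
    that precursor abundance.  It satisfies ``g(p_opt*(E_M)) = alpha_opt*(E_M)``
    for every environment, is strictly increasing, with ``g(0) = 0`` and
    ``g -> 1`` as ``p_hat -> inf``.
    """
    p = np.asarray(p_hat, dtype=float)
    out = p * (K + p) / (p * p + 2.0 * K * p + K)
    return out if out.ndim else float(out)


def optimal_curve_mu(p_hat, K: float):
    """Maximal steady-state growth rate as a function of the precursor level."""
    p = np.asarray(p_hat, dtype=float)
    out = p * p / (p * p + 2.0 * K * p + K)
    return out if out.ndim else float(out)
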