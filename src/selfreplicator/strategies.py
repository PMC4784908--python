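"""Feedback resource-allocation strategies.

Three closed-loop laws drive the self-replicator to the growth-maximizing
steady state of a constant environment:

* **nutrient-only** -- ``alpha = f(E_M)``: a constant allocation set from the
  sensed environment; ``f`` equals the closed-form steady-state optimum.
* **precursor-only** -- ``alpha = g(p_hat)``: allocation follows the optimal
  steady-state curve evaluated at the current precursor level.
* **on-off** -- ``alpha = h(p_hat, r_hat)``: a switch that shuts machinery
  synthesis off above the curve ``g`` and saturates it below, holding the
  optimal allocation exactly on the optimal steady state.

Each exact law has a biochemically plausible approximation (Michaelis-Menten
for ``f``, Hill with cooperativity 2 for ``g``, a steep Hill ratio for the
discontinuous ``h``); the half-saturation constants of the approximations are
fitted once over documented domains.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

from .config import DEFAULTS
from .model import NondimParams, optimal_allocation_env, optimal_curve_g

__all__ = [
    "StrategySpec",
    "f_nutrient",
    "f_mm_approx",
    "g_hill_approx",
    "h_onoff",
    "h_smooth",
    "fit_half_saturation",
    "default_K_mE",
    "default_K_mp",
    "make_control",
    "STRATEGY_KINDS",
]

STRATEGY_KINDS = (
    "nutrient_only",
    "precursor_only",
    "on_off",
    "on_off_smooth",
    "mm_approx",
    "hill_approx",
    "constant",
)


def f_nutrient(E_M: float, K: float) -> float:
    """Nutrient-only law: the closed-form optimal allocation for ``E_M``."""
    if E_M < 0:
        raise ValueError("E_M must be nonnegative")
    if E_M == 0.0:
        return 0.0
    return optimal_allocation_env(E_M, K).alpha


def f_mm_approx(E_M, K_mE: float):
    """Michaelis-Menten approximation ``E_M/(E_M + K_mE)`` of the nutrient law."""
    if K_mE <= 0:
        raise ValueError("K_mE must be positive")
    E = np.asarray(E_M, dtype=float)
    out = E / (E + K_mE)
    return out if out.ndim else float(out)


def g_hill_approx(p_hat, K_mp: float):
    """Hill approximation ``p^2/(p^2 + K_mp^2)`` of the precursor law."""
    if K_mp <= 0:
        raise ValueError("K_mp must be positive")
    p = np.asarray(p_hat, dtype=float)
    out = p * p / (p * p + K_mp * K_mp)
    return out if out.ndim else float(out)


def h_onoff(
    p_hat: float,
    r_hat: float,
    params: NondimParams,
    eps_pt: float | None = None,
) -> float:
    """Discontinuous on-off law.

    Returns 0 above the optimal curve (``r_hat > g(p_hat)``), 1 below it, and
    the optimal allocation when the state coincides with the optimal steady
    state within relative tolerance ``eps_pt``.
    """
    if eps_pt is None:
        eps_pt = DEFAULTS.optimal_point_rtol
    opt = optimal_allocation_env(params.E_M, params.K)
    if (
        abs(p_hat - opt.p_hat) <= eps_pt * max(opt.p_hat, 1e-30)
        and abs(r_hat - opt.r_hat) <= eps_pt * max(opt.r_hat, 1e-30)
    ):
        return opt.alpha
    g = optimal_curve_g(p_hat, params.K)
    return 0.0 if r_hat > g else 1.0


def h_smooth(
    p_hat: float,
    r_hat: float,
    params: NondimParams,
    n: float | None = None,
) -> float:
    """Continuous surrogate ``g(p)^n / (g(p)^n + r^n)`` of the on-off law.

    Evaluated in log space to avoid overflow at large exponents.  On the
    measure-zero set ``r_hat = g(p_hat) = 0`` the value is defined as 0.5 by
    continuity along the curve.
    """
    if n is None:
        n = DEFAULTS.hill_exponent
    g = optimal_curve_g(p_hat, params.K)
    if g <= 0.0 and r_hat <= 0.0:
        return 0.5
    if g <= 0.0:
        return 0.0
    if r_hat <= 0.0:
        return 1.0
    # logistic in n*(log g - log r)
    z = n * (np.log(g) - np.log(r_hat))
    if z >= 0:
        return float(1.0 / (1.0 + np.exp(-z)))
    ez = np.exp(z)
    return float(ez / (1.0 + ez))


def fit_half_saturation(
    target: Callable[[np.ndarray], np.ndarray],
    family: Callable[[np.ndarray, float], np.ndarray],
    domain: np.ndarray,
    bracket: tuple[float, float] = (1e-4, 1e4),
) -> float:
    """Least-squares fit of a one-constant response family to a target curve.

    Deterministic given the evaluation grid: minimizes the summed squared
    deviation over ``domain`` with a bounded scalar search on the log of the
    half-saturation constant.
    """
    x = np.asarray(domain, dtype=float)
    y = np.asarray(target(x), dtype=float)

    def loss(log_km: float) -> float:
        return float(np.sum((family(x, np.exp(log_km)) - y) ** 2))

    res = minimize_scalar(
        loss, bounds=(np.log(bracket[0]), np.log(bracket[1])), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(np.exp(res.x))


@lru_cache(maxsize=None)
def default_K_mE(K: float = 0.003) -> float:
    """Half-saturation of the Michaelis-Menten nutrient approximation.

    Fitted over ``E_M in [0.01, 10]`` (200-point geometric grid).
    """
    grid = np.geomspace(0.01, 10.0, 200)
    return fit_half_saturation(
        lambda E: np.array([f_nutrient(e, K) for e in E]), f_mm_approx, grid
    )


@lru_cache(maxsize=None)
def default_K_mp(K: float = 0.003) -> float:
    """Half-saturation of the Hill precursor approximation.

    Fitted over ``p_hat in [0, 1]`` (201-point uniform grid).
    """
    grid = np.linspace(0.0, 1.0, 201)
    return fit_half_saturation(
        lambda p: optimal_curve_g(p, K), g_hill_approx, grid
    )


@dataclass(frozen=True)
class StrategySpec:
    """Serializable description of a feedback strategy.

    ``kind`` selects the law; ``constants`` holds its named constants
    (``K_mE``, ``K_mp``, ``n`` for the smooth on-off exponent, ``alpha`` for
    the constant strategy).  Missing approximation constants are fitted on
    demand from the model parameters.
    """

    kind: str
    constants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(
                f"unknown strategy kind {self.kind!r}; expected one of {STRATEGY_KINDS}"
            )
        for name, value in self.constants.items():
            if name == "alpha":
                if not 0.0 <= value <= 1.0:
                    raise ValueError("constant strategy alpha must lie in [0, 1]")
            elif value <= 0:
                raise ValueError(f"strategy constant {name!r} must be positive")
        if self.kind == "constant" and "alpha" not in self.constants:
            raise ValueError("constant strategy requires an 'alpha' constant")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "constants": dict(self.constants)}

    @classmethod
    def from_dict(cls, data: dict) -> "StrategySpec":
        return cls(kind=data["kind"], constants=dict(data.get("constants", {})))

    @classmethod
    def from_cli_name(cls, name: str) -> "StrategySpec":
        """Parse CLI names: nutrient, precursor, onoff, onoff-smooth, constant:<a>."""
        mapping = {
            "nutrient": "nutrient_only",
            "precursor": "precursor_only",
            "onoff": "on_off",
            "onoff-smooth": "on_off_smooth",
        }
        if name.startswith("constant:"):
            return cls("constant", {"alpha": float(name.split(":", 1)[1])})
        if name in mapping:
            return cls(mapping[name])
        return cls(name)


def make_control(
    spec: StrategySpec, params: NondimParams
) -> Callable[[float, float], float]:
    """Build the state-feedback map ``(p_hat, r_hat) -> alpha`` for a spec.

    The discontinuous on-off law is closed-loop simulated through its smooth
    surrogate elsewhere; requesting ``on_off`` here returns the exact
    discontinuous map.
    """
    kind, c = spec.kind, spec.constants
    if kind == "nutrient_only":
        a = f_nutrient(params.E_M, params.K)
        return lambda p, r: a
    if kind == "precursor_only":
        return lambda p, r: float(optimal_curve_g(p, params.K))
    if kind == "on_off":
        return lambda p, r: h_onoff(p, r, params)
    if kind == "on_off_smooth":
        n = c.get("n", DEFAULTS.hill_exponent)
        return lambda p, r: h_smooth(p, r, params, n=n)
    if kind == "mm_approx":
        km = c.get("K_mE", default_K_mE(params.K))
        a = f_mm_approx(params.E_M, km)
        return lambda p, r: a
    if kind == "hill_approx":
        km = c.get("K_mp", default_K_mp(params.K))
        return lambda p, r: float(g_hill_approx(p, km))
    if kind == "constant":
        a = float(c["alpha"])
        return lambda p, r: a
    raise AssertionError(kind)
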