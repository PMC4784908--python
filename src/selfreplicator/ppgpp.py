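"""Reduced ppGpp read-out and comparison with the on-off response surface.

In enterobacteria the alarmone ppGpp rises when ribosomes stall on uncharged
tRNA and inhibits ribosomal RNA transcription, making it a natural
integrator of precursor supply (charged tRNA) and ribosome demand.  This
module implements a minimal quasi-steady-state (QSS) reduction of that
mechanism on top of the self-replicator state ``(p_hat, r_hat)``:

* The tRNA charging capacity follows the amino-acid (precursor) pool with
  an effective cooperativity, ``q(p) = p^H/(K_t^H + p^H)`` -- a reduced
  description of the multi-step activation of charging by the pool (the
  same kind of effective cooperativity that makes the optimal steady-state
  curve itself Hill-like in the precursor level).
* With charging in fast equilibrium, the uncharged-tRNA fraction balances
  charging supply against translation demand:
  ``u = rho*r / (q(p) + rho*r)``, ``rho`` the translation-to-charging rate
  ratio.  ``u`` rises with ribosome content and falls with precursor level.
* RelA-driven synthesis is proportional to stalled ribosomes,
  ``S = k_syn * r * u``; hydrolysis is Michaelian with a small basal
  first-order leak, ``V_max*G/(K_h+G) + k_basal*G``.  Because hydrolysis
  operates near saturation (``K_h`` small), the QSS balance is zero-order
  ultrasensitive: ppGpp jumps when synthesis approaches the hydrolysis
  capacity.
* Transcription control (the read-out): ``alpha = K_I/(K_I + ppGpp)``.

The default constants are calibrated once, deterministically, so that the
half-activation locus of the induced allocation surface tracks the optimal
steady-state curve ``r_hat = g(p_hat)`` (anchored exactly at the optimal
steady state of the reference environment ``E_M = 1``), and then frozen as
the dataclass defaults; :func:`calibrate_ppgpp_params` recomputes them from
scratch.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

from .model import NondimParams, optimal_allocation_env, optimal_curve_g
from .strategies import h_onoff

__all__ = [
    "PpgppParams",
    "alpha_from_ppgpp",
    "uncharged_fraction",
    "ppgpp_qss",
    "alpha_ppgpp",
    "response_surface",
    "onoff_surface",
    "ppgpp_surface",
    "surface_frame",
    "compare_surfaces",
    "calibrate_ppgpp_params",
    "DEFAULT_P_GRID",
    "DEFAULT_R_GRID",
]

#: Default phase-plane grids for surface comparison: precursor levels up to
#: ~2x the optimal level of a rich medium, the full machinery range.
DEFAULT_P_GRID = np.linspace(0.0, 0.1, 51)
DEFAULT_R_GRID = np.linspace(0.0, 1.0, 51)


@dataclass(frozen=True)
class PpgppParams:
    """Constants of the reduced ppGpp mechanism (defaults: calibrated).

    K_I           : transcription inhibition constant [umol/L]
    k_syn         : RelA synthesis gain per stalled-ribosome unit [umol/(L h)]
    V_max         : saturable (SpoT) hydrolysis capacity [umol/(L h)]
    K_h           : hydrolysis half-saturation [umol/L]; small relative to
                    K_I, putting the balance in the zero-order regime
    k_basal       : basal first-order degradation [1/h]; keeps the QSS
                    finite when synthesis exceeds V_max
    rho           : translation-to-charging rate ratio (dimensionless)
    charging_hill : effective cooperativity H of the charging capacity
    charging_K    : half-saturation K_t of the charging capacity
                    (nondimensional precursor units)
    """

    K_I: float = 50.0
    k_syn: float = 129413.99458194616
    V_max: float = 1000.0
    K_h: float = 0.1
    k_basal: float = 0.01
    rho: float = 0.01
    charging_hill: float = 3.012902572439113
    charging_K: float = 0.07044705910505698

    def __post_init__(self) -> None:
        for name in (
            "K_I", "k_syn", "V_max", "K_h", "k_basal", "rho",
            "charging_hill", "charging_K",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def alpha_from_ppgpp(conc, K_I: float):
    """Allocation from a ppGpp concentration: ``K_I/(K_I + ppGpp)``.

    Strictly decreasing in the concentration; 1 at zero ppGpp, 0.5 at
    ``conc = K_I``, 0 in the limit of saturating ppGpp.
    """
    if K_I <= 0:
        raise ValueError("K_I must be positive")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("ppGpp concentration must be nonnegative")
    out = K_I / (K_I + c)
    return out if out.ndim else float(out)


def _charging_capacity(p_hat, params: PpgppParams):
    p = np.asarray(p_hat, dtype=float)
    H, Kt = params.charging_hill, params.charging_K
    with np.errstate(divide="ignore"):
        ph = np.where(p > 0, p, 0.0) ** H
    return ph / (Kt**H + ph)


def uncharged_fraction(p_hat, r_hat, params: PpgppParams):
    """QSS uncharged-tRNA fraction ``rho*r/(q(p) + rho*r)``."""
    q = _charging_capacity(p_hat, params)
    r = np.asarray(r_hat, dtype=float)
    denom = q + params.rho * r
    u = np.where(denom > 0, params.rho * r / np.where(denom > 0, denom, 1.0), 0.0)
    return u if u.ndim else float(u)


def ppgpp_qss(p_hat, r_hat, params: PpgppParams | None = None):
    """QSS ppGpp concentration [umol/L] at a replicator state.

    Positive root of the synthesis/degradation balance
    ``k_syn*r*u = V_max*G/(K_h+G) + k_basal*G``.  Increasing in ``r_hat``
    (more ribosomes competing for the same precursor pool stall more often),
    decreasing in ``p_hat``; tends to 0 in the no-stalling limit
    ``p_hat -> inf``.
    """
    if params is None:
        params = PpgppParams()
    u = uncharged_fraction(p_hat, r_hat, params)
    S = params.k_syn * np.asarray(r_hat, dtype=float) * u
    b = params.k_basal * params.K_h + params.V_max - S
    G = (-b + np.sqrt(b * b + 4.0 * params.k_basal * S * params.K_h)) / (
        2.0 * params.k_basal
    )
    G = np.maximum(G, 0.0)
    return G if np.ndim(G) else float(G)


def alpha_ppgpp(p_hat, r_hat, params: PpgppParams | None = None):
    """Allocation induced by the ppGpp read-out at a replicator state."""
    if params is None:
        params = PpgppParams()
    return alpha_from_ppgpp(ppgpp_qss(p_hat, r_hat, params), params.K_I)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def _anchored_k_syn(params: PpgppParams, model_params: NondimParams) -> float:
    """Synthesis gain putting ``alpha = alpha_opt*`` exactly at the optimal
    steady state of ``model_params``."""
    opt = optimal_allocation_env(model_params.E_M, model_params.K)
    G_target = params.K_I * (1.0 - opt.alpha) / opt.alpha
    S_req = (
        params.V_max * G_target / (params.K_h + G_target)
        + params.k_basal * G_target
    )
    u = uncharged_fraction(opt.p_hat, opt.r_hat, params)
    return float(S_req / (opt.r_hat * u))


def half_activation_r(p_hat: float, params: PpgppParams) -> float:
    """Machinery level where the induced allocation crosses 0.5 at ``p_hat``."""

    def fn(r):
        return alpha_ppgpp(p_hat, r, params) - 0.5

    if fn(1.0) > 0:
        return float("nan")
    return float(brentq(fn, 1e-9, 1.0, xtol=1e-13))


def calibrate_ppgpp_params(
    E_M: float = 1.0,
    K: float = 0.003,
    base: PpgppParams | None = None,
    p_range: tuple[float, float] = (0.002, 0.12),
    n_probe: int = 50,
) -> PpgppParams:
    """Recompute the calibrated constants from scratch (deterministic).

    Anchors ``k_syn`` at the optimal steady state of ``(E_M, K)`` and fits
    the charging-capacity shape ``(H, K_t)`` by minimizing the maximal
    deviation of the half-activation locus from the optimal curve ``g`` over
    the probed precursor range.  The scale constants (``K_I``, ``V_max``,
    ``K_h``, ``k_basal``, ``rho``) are taken from ``base`` and not fitted.
    """
    base = base or PpgppParams()
    model_params = NondimParams(E_M=E_M, K=K)
    ps = np.linspace(p_range[0], p_range[1], n_probe)
    g = optimal_curve_g(ps, K)

    def build(H: float, Kt: float) -> PpgppParams:
        cand = replace(base, charging_hill=H, charging_K=Kt)
        return replace(cand, k_syn=_anchored_k_syn(cand, model_params))

    def objective(x: np.ndarray) -> float:
        cand = build(float(np.exp(x[0])), float(np.exp(x[1])))
        rh = np.array([half_activation_r(p, cand) for p in ps])
        rh = np.where(np.isnan(rh), 1.2, rh)
        return float(np.max(np.abs(rh - g)))

    res = minimize(
        objective,
        np.log([base.charging_hill, base.charging_K]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-11, "maxiter": 2000},
    )
    return build(float(np.exp(res.x[0])), float(np.exp(res.x[1])))


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


def response_surface(alpha_fn, p_grid=None, r_grid=None) -> np.ndarray:
    """Tabulate an allocation law on a phase-plane grid.

    ``alpha_fn(p_hat, r_hat) -> alpha``; returns an array of shape
    ``(len(p_grid), len(r_grid))``.  Deterministic.
    """
    p_grid = DEFAULT_P_GRID if p_grid is None else np.asarray(p_grid, dtype=float)
    r_grid = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, dtype=float)
    out = np.empty((len(p_grid), len(r_grid)))
    for i, p in enumerate(p_grid):
        for j, r in enumerate(r_grid):
            out[i, j] = alpha_fn(p, r)
    return out


def onoff_surface(params: NondimParams, p_grid=None, r_grid=None) -> np.ndarray:
    """Response surface of the discontinuous on-off strategy."""
    return response_surface(lambda p, r: h_onoff(p, r, params), p_grid, r_grid)


def ppgpp_surface(
    ppgpp_params: PpgppParams | None = None, p_grid=None, r_grid=None
) -> np.ndarray:
    """Response surface of the ppGpp-mediated allocation."""
    pp = ppgpp_params or PpgppParams()
    return response_surface(lambda p, r: alpha_ppgpp(p, r, pp), p_grid, r_grid)


def surface_frame(surface: np.ndarray, p_grid, r_grid, source: str) -> pd.DataFrame:
    """Long-format table ``p_hat, r_hat, alpha, source`` of a surface."""
    P, R = np.meshgrid(p_grid, r_grid, indexing="ij")
    return pd.DataFrame(
        {
            "p_hat": P.ravel(),
            "r_hat": R.ravel(),
            "alpha": surface.ravel(),
            "source": source,
        }
    )


def compare_surfaces(
    surface_a: np.ndarray,
    surface_b: np.ndarray,
    p_grid=None,
    r_grid=None,
    K: float = 0.003,
    delta: float = 0.02,
) -> float:
    """Fraction of grid points where two surfaces fall on the same side of 0.5.

    Points within a band ``|r_hat - g(p_hat)| < delta`` around the optimal
    curve are excluded: both laws transition there and the side is not
    meaningful.  Returns a value in [0, 1].
    """
    p_grid = DEFAULT_P_GRID if p_grid is None else np.asarray(p_grid, dtype=float)
    r_grid = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, dtype=float)
    if surface_a.shape != (len(p_grid), len(r_grid)) or surface_a.shape != surface_b.shape:
        raise ValueError("surface shapes must match the grids")
    g = optimal_curve_g(p_grid, K)
    mask = np.abs(r_grid[None, :] - g[:, None]) >= delta
    side_a = surface_a >= 0.5
    side_b = surface_b >= 0.5
    agree = (side_a == side_b) & mask
    return float(agree.sum() / mask.sum())
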