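r"""Steady-state growth laws and model fitting to (growth rate, RNA/protein) data.

Across growth media (different nutrient efficiencies ``e_M``) the optimal
constant allocation traces a quasi-linear relation between the maximal
growth rate and the machinery fraction -- the first bacterial growth law.
Within one medium, inhibiting translation (lowering ``k_R``, e.g. with
chloramphenicol) traces a second, negatively sloped relation.  Both follow
from the closed-form optimum

.. math::

    \alpha^*_{opt} = \frac{e_M + \sqrt{K e_M k_R}}{e_M + 2\sqrt{K e_M k_R} + k_R},
    \qquad
    \mu^*_{opt} = \frac{e_M k_R}{e_M + 2\sqrt{K e_M k_R} + k_R}.

The measured RNA/protein mass ratio is proportional to the machinery
fraction, ``r_hat* = alpha_opt* = gamma * (RNA/protein)``, with a
dimensionless conversion ``gamma``.  Fitting estimates ``k_R``, ``gamma``,
one ``e_M`` per medium and one ``k_R`` multiplier per inhibitor dose from a
table of (growth rate, ratio) measurements, using differential evolution
with a recorded seed.  A synthetic-data generator emulating the classical
6-media x 5-dose design supports parameter-recovery studies.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .model import optimal_allocation_dim

__all__ = [
    "GrowthLawDataset",
    "FitResult",
    "predict_growth_law",
    "chloramphenicol_series",
    "invert_e_M",
    "generate_synthetic_dataset",
    "fit_growth_laws",
    "DEFAULT_MEDIA_E_M",
    "DEFAULT_DOSE_FACTORS",
]

#: Default nutrient efficiencies [1/h] of the six synthetic growth media,
#: spanning maximal growth rates ~0.4-1.7 1/h at k_R = 2.23 1/h.
DEFAULT_MEDIA_E_M = (0.5, 0.9, 1.4, 2.0, 3.0, 4.8)

#: Default translation-inhibitor dose levels, expressed as multipliers of
#: k_R in (0, 1]; dose 0 is the uninhibited condition.
DEFAULT_DOSE_FACTORS = (1.0, 0.8, 0.6, 0.45, 0.3)

#: Documented default gene-expression rate constant [1/h] for growth-law
#: curves (typical of E. coli data fits).
DEFAULT_K_R = 2.23

#: Default RNA/protein -> machinery-fraction conversion, calibrated so the
#: synthetic ratios match typical E. coli RNA/protein measurements
#: (ratio ~ 0.35 at mu ~ 1/h).
DEFAULT_GAMMA = 1.35


@dataclass
class GrowthLawDataset:
    """Tidy table of steady-state growth measurements.

    Columns: ``medium`` (label), ``dose`` (inhibitor level index, 0 =
    uninhibited), ``growth_rate`` [1/h], ``rna_protein_ratio``
    (dimensionless mass ratio), ``sd`` (measurement standard deviation).
    """

    frame: pd.DataFrame

    REQUIRED = ("medium", "dose", "growth_rate", "rna_protein_ratio", "sd")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset missing column {sorted(missing)[0]!r}")
        if (self.frame["growth_rate"] <= 0).any():
            raise ValueError("growth rates must be positive")
        if (self.frame["rna_protein_ratio"] <= 0).any():
            raise ValueError("RNA/protein ratios must be positive")

    @property
    def media(self) -> list:
        return sorted(self.frame["medium"].unique())

    @property
    def doses(self) -> list:
        return sorted(self.frame["dose"].unique())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GrowthLawDataset":
        return cls(pd.read_csv(path))


@dataclass
class FitResult:
    """Fitted growth-law parameters."""

    k_R: float
    gamma: float
    e_M: dict
    dose_factors: dict
    loss: float
    seed: int
    n_points: int = 0


def predict_growth_law(
    k_R: float, K: float, e_M_values
) -> tuple[np.ndarray, np.ndarray]:
    """Growth-law curve across media: ``(mu_opt [1/h], alpha_opt)`` arrays."""
    e = np.atleast_1d(np.asarray(e_M_values, dtype=float))
    pairs = [optimal_allocation_dim(ei, k_R, K) for ei in e]
    alpha = np.array([a for a, _ in pairs])
    mu = np.array([m for _, m in pairs])
    return mu, alpha


def chloramphenicol_series(
    e_M: float, K: float, k_R_values
) -> tuple[np.ndarray, np.ndarray]:
    """Translation-inhibition curve at fixed medium: vary ``k_R`` downward.

    Lower ``k_R`` (higher inhibitor dose) lowers the attainable growth rate
    while raising the optimal machinery fraction.
    """
    k = np.atleast_1d(np.asarray(k_R_values, dtype=float))
    pairs = [optimal_allocation_dim(e_M, ki, K) for ki in k]
    alpha = np.array([a for a, _ in pairs])
    mu = np.array([m for _, m in pairs])
    return mu, alpha


def invert_e_M(mu: float, k_R: float, K: float) -> float:
    r"""Nutrient efficiency implied by an observed maximal growth rate.

    Solves ``mu = e_M k_R / (e_M + 2 sqrt(K e_M k_R) + k_R)`` for ``e_M``
    (quadratic in ``sqrt(e_M)``; the positive branch).  Requires
    ``mu < k_R``; the growth rate saturates at ``k_R`` as the medium becomes
    infinitely rich.
    """
    if not mu < k_R:
        raise ValueError(f"growth rate {mu} must be below k_R = {k_R}")
    skk = np.sqrt(K * k_R)
    disc = mu * mu * K * k_R + (k_R - mu) * mu * k_R
    x = (mu * skk + np.sqrt(disc)) / (k_R - mu)
    return float(x * x)


def generate_synthetic_dataset(
    k_R: float = DEFAULT_K_R,
    gamma: float = DEFAULT_GAMMA,
    media_e_M=DEFAULT_MEDIA_E_M,
    dose_factors=DEFAULT_DOSE_FACTORS,
    K: float = 0.003,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> GrowthLawDataset:
    """Synthetic growth-law measurements in the 6-media x 5-dose design.

    Each dose scales ``k_R`` by a factor in (0, 1] shared across media.
    Noise is multiplicative Gaussian (relative s.d. ``noise_sigma``) applied
    independently to growth rate and ratio; ``noise_sigma = 0`` puts every
    point exactly on the model curve.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, e in enumerate(media_e_M):
        for j, d in enumerate(dose_factors):
            alpha, mu = optimal_allocation_dim(e, k_R * d, K)
            ratio = alpha / gamma
            mu_obs = mu * (1.0 + noise_sigma * rng.standard_normal())
            ratio_obs = ratio * (1.0 + noise_sigma * rng.standard_normal())
            rows.append(
                {
                    "medium": f"M{i + 1}",
                    "dose": j,
                    "growth_rate": abs(mu_obs),
                    "rna_protein_ratio": abs(ratio_obs),
                    "sd": noise_sigma * ratio,
                }
            )
    return GrowthLawDataset(pd.DataFrame(rows))


def _joint_loss_factory(dataset: GrowthLawDataset, K: float):
    """Vectorized joint relative-residual loss over (mu, ratio) pairs.

    Free parameters: ``[k_R, gamma, e_M per medium, dose multipliers]``.
    Sharing each medium's ``e_M`` across its dose series is what pins down
    ``k_R``; relative residuals match the multiplicative error model.
    """
    df = dataset.frame
    media, doses = dataset.media, dataset.doses
    mi = df["medium"].map({m: i for i, m in enumerate(media)}).to_numpy()
    di = df["dose"].map({d: i for i, d in enumerate(doses)}).to_numpy()
    mu_o = df["growth_rate"].to_numpy()[:, None]
    ra_o = df["rna_protein_ratio"].to_numpy()[:, None]
    nm, nd = len(media), len(doses)

    def loss(theta: np.ndarray) -> np.ndarray:
        T = theta[:, None] if theta.ndim == 1 else theta
        k_R, gamma = T[0], T[1]
        e = T[2 : 2 + nm][mi]
        dfac = np.vstack([np.ones(T.shape[1]), T[2 + nm :]])[di]
        k_eff = k_R[None, :] * dfac
        s = np.sqrt(K * e * k_eff)
        den = e + 2.0 * s + k_eff
        alpha = (e + s) / den
        mu = e * k_eff / den
        res = ((mu - mu_o) / mu_o) ** 2 + ((alpha / gamma[None, :] - ra_o) / ra_o) ** 2
        out = res.sum(axis=0)
        return out if theta.ndim > 1 else float(out[0])

    return loss, nm, nd


def _ratio_loss_factory(dataset: GrowthLawDataset, K: float):
    """Ratio-coordinate loss with the nutrient efficiency inverted per point.

    Eliminates the per-medium efficiencies from the search but discards the
    constraint that doses of one medium share ``e_M``; kept as a
    configurable alternative (it is poorly conditioned in ``k_R`` under
    noise).
    """
    df = dataset.frame
    doses = dataset.doses
    mu_obs = df["growth_rate"].to_numpy()
    ratio_obs = df["rna_protein_ratio"].to_numpy()
    dose_idx = df["dose"].map({d: i for i, d in enumerate(doses)}).to_numpy()

    def loss(theta: np.ndarray) -> float:
        k_R, gamma = theta[0], theta[1]
        dfac = np.concatenate([[1.0], theta[2:]])
        total = 0.0
        for i in range(len(mu_obs)):
            k_eff = k_R * dfac[dose_idx[i]]
            if mu_obs[i] >= 0.999 * k_eff:
                total += (10.0 + mu_obs[i] / k_eff) ** 2
                continue
            e = invert_e_M(mu_obs[i], k_eff, K)
            alpha, _ = optimal_allocation_dim(e, k_eff, K)
            total += (alpha / gamma - ratio_obs[i]) ** 2
        return total

    return loss, len(doses)


def fit_growth_laws(
    dataset: GrowthLawDataset,
    K: float = 0.003,
    seed: int = 0,
    loss: str = "joint",
    maxiter: int = 500,
    popsize: int = 15,
    polish: bool = True,
    bounds_k_R: tuple[float, float] = (0.1, 20.0),
    bounds_gamma: tuple[float, float] = (0.1, 10.0),
    bounds_e_M: tuple[float, float] = (0.01, 50.0),
) -> FitResult:
    """Fit ``(k_R, gamma, e_M per medium, dose multipliers)`` to a dataset.

    ``K`` is held fixed (not identifiable from this data; set from
    literature).  Global search by differential evolution (population
    ``popsize`` x dimension, up to ``maxiter`` generations, recorded
    ``seed``), followed by a local polish.

    ``loss="joint"`` (default) minimizes summed squared *relative* residuals
    of predicted versus measured growth rate and ratio jointly, with one
    free nutrient efficiency per medium and one free ``k_R`` multiplier per
    inhibitor dose.  ``loss="ratio_inversion"`` instead eliminates the
    efficiencies by inverting the growth-rate relation per point and scores
    only the ratio coordinate.
    """
    df = dataset.frame
    if len(df) < 2 or len(dataset.media) < 2:
        raise ValueError("dataset is underdetermined: need >= 2 media with >= 2 points")
    if loss == "joint":
        fn, nm, nd = _joint_loss_factory(dataset, K)
        bounds = (
            [bounds_k_R, bounds_gamma] + [bounds_e_M] * nm + [(0.01, 1.0)] * (nd - 1)
        )
        result = differential_evolution(
            fn, bounds, seed=seed, maxiter=maxiter, popsize=popsize, tol=1e-10,
            polish=polish, init="sobol", vectorized=True, updating="deferred",
        )
        theta = result.x
        k_R, gamma = float(theta[0]), float(theta[1])
        e_M = {m: float(theta[2 + i]) for i, m in enumerate(dataset.media)}
        dfac = {
            d: (1.0 if i == 0 else float(theta[2 + nm + i - 1]))
            for i, d in enumerate(dataset.doses)
        }
    elif loss == "ratio_inversion":
        fn, nd = _ratio_loss_factory(dataset, K)
        bounds = [bounds_k_R, bounds_gamma] + [(0.01, 1.0)] * (nd - 1)
        result = differential_evolution(
            fn, bounds, seed=seed, maxiter=maxiter, popsize=popsize, tol=1e-10,
            polish=polish, init="sobol",
        )
        theta = result.x
        k_R, gamma = float(theta[0]), float(theta[1])
        dfac = {
            d: (1.0 if i == 0 else float(theta[2 + i - 1]))
            for i, d in enumerate(dataset.doses)
        }
        e_M = {}
        for medium, grp in df.groupby("medium"):
            vals = [
                invert_e_M(row["growth_rate"], k_R * dfac[row["dose"]], K)
                for _, row in grp.iterrows()
                if row["growth_rate"] < 0.999 * k_R * dfac[row["dose"]]
            ]
            e_M[medium] = float(np.mean(vals)) if vals else float("nan")
    else:
        raise ValueError(f"unknown loss {loss!r}")
    return FitResult(
        k_R=k_R,
        gamma=gamma,
        e_M=e_M,
        dose_factors=dfac,
        loss=float(result.fun),
        seed=seed,
        n_points=len(df),
    )
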