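"""Package-wide numeric constants and run configuration.

All residual/identity tolerances used by the analytical cross-checks live in
one frozen record so that every module (and every test) agrees on what
"equal" means numerically.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass(frozen=True)
class NumericConfig:
    """Shared numeric tolerances and solver defaults.

    Attributes
    ----------
    fixed_point_residual:
        Maximum admissible magnitude of the model right-hand side at a
        reported steady state.
    identity_rtol:
        Tolerance for closed-form identities (two analytic routes to the
        same quantity).
    ode_rtol, ode_atol:
        Relative/absolute tolerances for closed-loop stiff integration.
    report_points:
        Number of evenly spaced reporting times on a dense trajectory.
    hill_exponent:
        Exponent of the smooth surrogate of the discontinuous on-off law.
    optimal_point_rtol:
        Relative tolerance for deciding that a state coincides with the
        optimal steady state (third branch of the on-off law).
    jacobian_rel_step:
        Relative step of the central-difference Jacobian used for the
        stability analysis of steady states.
    """

    fixed_point_residual: float = 1e-10
    identity_rtol: float = 1e-12
    ode_rtol: float = 1e-10
    ode_atol: float = 1e-12
    report_points: int = 2000
    hill_exponent: float = 100.0
    optimal_point_rtol: float = 1e-6
    jacobian_rel_step: float = 1e-7


DEFAULTS = NumericConfig()

#: Reference nondimensional parameter set used throughout: E_M = 1, K = 0.003.
DEFAULT_E_M = 1.0
DEFAULT_K = 0.003


class ConfigError(ValueError):
    """A run configuration violated the schema; the message names the key."""


_DIM_KEYS = {"e_M", "k_R", "K_R", "beta"}
_NONDIM_KEYS = {"E_M", "K"}
_TOP_KEYS = {
    "model",
    "scenario",
    "strategy",
    "solver",
    "seed",
    "out_dir",
}


@dataclass
class RunConfig:
    """A validated run configuration.

    Exactly one of the two parameter groups (dimensional ``e_M,k_R,K_R,beta``
    or nondimensional ``E_M,K``) is present in ``model``.  Missing
    nondimensional values fall back to the reference preset
    (``E_M = 1``, ``K = 0.003``).
    """

    model: dict = field(default_factory=lambda: {"E_M": DEFAULT_E_M, "K": DEFAULT_K})
    scenario: dict = field(default_factory=dict)
    strategy: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."

    @property
    def is_dimensional(self) -> bool:
        return _DIM_KEYS.issubset(self.model.keys())

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_model_group(model: Mapping[str, Any]) -> dict:
    keys = set(model.keys())
    has_dim = bool(keys & _DIM_KEYS)
    has_nondim = bool(keys & _NONDIM_KEYS)
    if has_dim and has_nondim:
        raise ConfigError(
            "model: both dimensional and nondimensional parameter groups "
            f"present ({sorted(keys)}); provide exactly one"
        )
    unknown = keys - _DIM_KEYS - _NONDIM_KEYS
    if unknown:
        raise ConfigError(f"model: unknown key {sorted(unknown)[0]!r}")
    if has_dim:
        missing = _DIM_KEYS - keys
        if missing:
            raise ConfigError(f"model: missing dimensional key {sorted(missing)[0]!r}")
        return dict(model)
    out = {"E_M": DEFAULT_E_M, "K": DEFAULT_K}
    out.update(model)
    return out


def parse_config(data: Mapping[str, Any]) -> RunConfig:
    """Validate a mapping into a :class:`RunConfig`."""
    unknown = set(data.keys()) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r}")
    model = _validate_model_group(data.get("model", {}))
    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed: must be an integer")
    return RunConfig(
        model=model,
        scenario=dict(data.get("scenario", {})),
        strategy=dict(data.get("strategy", {})),
        solver=dict(data.get("solver", {})),
        seed=seed,
        out_dir=str(data.get("out_dir", ".")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON or YAML run configuration from *path*."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError("configuration root must be a mapping")
    return parse_config(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict()))
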