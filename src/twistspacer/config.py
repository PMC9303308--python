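"""Run configuration: model-constant overrides and analysis thresholds."""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .torsion import TwistParameters

#: keys accepted in a config file
MODEL_KEYS = ("k_theta", "alpha0_deg", "theta_P_deg", "n_ref", "sigma_ref")
THRESHOLD_KEYS = ("alpha", "delay", "exclude_16", "seed", "sigma0")
ALLOWED_KEYS = MODEL_KEYS + THRESHOLD_KEYS


@dataclass
class RunConfig:
    params: TwistParameters
    alpha: float = 0.05
    delay: float = 60.0
    exclude_16: bool = True
    sigma0: float = -0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")

    def as_dict(self) -> dict:
        return {
            "k_theta": self.params.k_theta,
            "alpha0_deg": self.params.alpha0_deg,
            "theta_P_deg": self.params.theta_p_deg,
            "n_ref": self.params.n_ref,
            "sigma_ref": self.params.sigma_ref,
            "alpha": self.alpha,
            "delay": self.delay,
            "exclude_16": self.exclude_16,
            "sigma0": self.sigma0,
            "seed": self.seed,
        }


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Unknown keys are rejected so typos cannot silently fall back to defaults.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a key-value mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(raw) - set(ALLOWED_KEYS))
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    params = TwistParameters.from_degrees(
        k_theta=raw.get("k_theta", 71.4),
        alpha0_deg=raw.get("alpha0_deg", 34.0),
        theta_p_deg=raw.get("theta_P_deg"),
        n_ref=int(raw.get("n_ref", 17)),
        sigma_ref=raw.get("sigma_ref", -0.06),
    )
    return RunConfig(
        params=params,
        alpha=float(raw.get("alpha", 0.05)),
        delay=float(raw.get("delay", 60.0)),
        exclude_16=bool(raw.get("exclude_16", True)),
        sigma0=float(raw.get("sigma0", -0.06)),
        seed=int(raw.get("seed", 0)),
    )
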