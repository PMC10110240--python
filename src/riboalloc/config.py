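"""Run configuration: a flat key-value document with unit-suffixed keys.

Config files are flat YAML mappings (``key: value`` lines, no nesting).
Every key carries its unit in the name (``gamma_max_per_hr``,
``km_cnt_mM``) so the hour/second conventions are unmistakable. Defaulted
parameters are logged to stderr with their provenance: a literature-derived
value or an unverified suggestion.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .params import (
    M_RB_AA,
    PHI_O_DEFAULT,
    VTL_MAX_AA_PER_S,
    FluxParityKinetics,
    SimpleKinetics,
)

__all__ = ["RunConfig", "load_config", "serialize_config", "config_hash"]

logger = logging.getLogger(__name__)

# (default value, provenance) for every optional key.
_DEFAULTS: dict[str, tuple[object, str]] = {
    "vtl_max_aa_s": (VTL_MAX_AA_PER_S, "literature value"),
    "m_rb_aa": (M_RB_AA, "literature value"),
    "nu_max_per_hr": (4.0, "unverified suggestion"),
    "km_cpc_rel": (0.03, "unverified suggestion"),
    "km_cnt_mM": (0.1, "unverified suggestion"),
    "yield_per_mM": (1.0, "unverified suggestion"),
    "phi_o": (PHI_O_DEFAULT, "unverified suggestion"),
    "tau": (3.0, "unverified suggestion"),
    "kappa_max_per_hr": (2.0e-2, "unverified suggestion"),
    "km_trna_c_rel": (2.0e-5, "unverified suggestion"),
    "km_trna_u_rel": (3.0e-6, "unverified suggestion"),
    "phi_rb": (None, "scenario-dependent"),
    "scenario": ("III", "package default"),
    "t_max_hr": (20.0, "package default"),
    "dt_hr": (0.01, "package default"),
    "tol": (1e-6, "package default"),
    "out_format": ("csv", "package default"),
}

_REQUIRED = ("model",)
_MODELS = ("simple", "flux_parity")
_SCENARIOS = ("I", "II", "III")


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully defaulted run configuration."""

    model: str
    vtl_max_aa_s: float
    m_rb_aa: float
    nu_max_per_hr: float
    km_cpc_rel: float
    km_cnt_mM: float
    yield_per_mM: float
    phi_o: float
    tau: float
    kappa_max_per_hr: float
    km_trna_c_rel: float
    km_trna_u_rel: float
    scenario: str
    phi_rb: float | None
    t_max_hr: float
    dt_hr: float
    tol: float
    out_format: str
    extras: dict = field(default_factory=dict)

    @property
    def gamma_max_per_hr(self) -> float:
        return self.vtl_max_aa_s * 3600.0 / self.m_rb_aa

    def simple_kinetics(self) -> SimpleKinetics:
        return SimpleKinetics.from_elongation(
            vtl_max=self.vtl_max_aa_s,
            m_Rb=self.m_rb_aa,
            nu_max=self.nu_max_per_hr,
            Km_cpc=self.km_cpc_rel,
            Km_cnt=self.km_cnt_mM,
            Y=self.yield_per_mM,
        )

    def flux_parity_kinetics(self) -> FluxParityKinetics:
        return FluxParityKinetics(
            gamma_max=self.gamma_max_per_hr,
            nu_max=self.nu_max_per_hr,
            Km_tRNAc=self.km_trna_c_rel,
            Km_tRNAu=self.km_trna_u_rel,
            tau=self.tau,
            kappa_max=self.kappa_max_per_hr,
            phi_O=self.phi_o,
            Km_cnt=self.km_cnt_mM,
            Y=self.yield_per_mM,
            m_Rb=self.m_rb_aa,
        )


def _from_mapping(raw: dict) -> RunConfig:
    for key in _REQUIRED:
        if key not in raw:
            raise ConfigError(f"missing required config key: {key!r}")
    model = raw["model"]
    if model not in _MODELS:
        raise ConfigError(f"model must be one of {_MODELS}, got {model!r}")
    values: dict = {"model": model}
    known = set(_DEFAULTS) | set(_REQUIRED)
    extras = {k: v for k, v in raw.items() if k not in known}
    for key, (default, provenance) in _DEFAULTS.items():
        if key in raw:
            values[key] = raw[key]
        else:
            values[key] = default
            logger.info(
                "config: %s defaulted to %r (%s)", key, default, provenance
            )
    for key in (
        "vtl_max_aa_s",
        "m_rb_aa",
        "nu_max_per_hr",
        "km_cpc_rel",
        "km_cnt_mM",
        "yield_per_mM",
        "tau",
        "kappa_max_per_hr",
        "km_trna_c_rel",
        "km_trna_u_rel",
        "t_max_hr",
        "dt_hr",
        "tol",
    ):
        try:
            values[key] = float(values[key])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config key {key!r} must be numeric") from exc
        if values[key] <= 0:
            raise ConfigError(f"config key {key!r} must be positive")
    if not 0 <= float(values["phi_o"]) < 1:
        raise ConfigError("phi_o must lie in [0, 1)")
    values["phi_o"] = float(values["phi_o"])
    if values["scenario"] not in _SCENARIOS:
        raise ConfigError(
            f"scenario must be one of {_SCENARIOS}, got "
            f"{values['scenario']!r}"
        )
    if values["out_format"] not in ("csv", "json"):
        raise ConfigError("out_format must be 'csv' or 'json'")
    if values["phi_rb"] is not None:
        phi_rb = float(values["phi_rb"])
        if not 0 <= phi_rb <= 1:
            raise ConfigError("phi_rb must lie in [0, 1]")
        if phi_rb + values["phi_o"] > 1:
            raise ConfigError("phi_rb + phi_o must not exceed 1")
        values["phi_rb"] = phi_rb
    return RunConfig(**values, extras=extras)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a flat key-value config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file not parseable: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key-value mapping")
    for key, value in raw.items():
        if isinstance(value, (dict, list)):
            raise ConfigError(
                f"config must be flat; key {key!r} holds a nested structure"
            )
    return _from_mapping(raw)


def serialize_config(config: RunConfig) -> dict:
    """Normalized flat mapping (round-trips through load)."""
    out = asdict(config)
    extras = out.pop("extras")
    out.update(extras)
    return out


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the normalized config, for provenance headers."""
    payload = json.dumps(serialize_config(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
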