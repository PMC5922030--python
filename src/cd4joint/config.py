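"""Declarative scenario configuration (YAML)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .joint import McmcSettings
from .params import TrueParameters, table_preset

__all__ = ["load_config", "ScenarioConfig"]


class ScenarioConfig(dict):
    """A parsed scenario: cohort size, truth, schedule, sampler settings."""

    @property
    def params(self) -> TrueParameters:
        return self["params"]

    @property
    def settings(self) -> McmcSettings:
        return self["settings"]


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a YAML scenario file.

    Recognised keys: ``n``, ``seed``, ``max_followups``, ``miss_prob``,
    ``params`` (either ``preset`` or a mapping overriding preset fields,
    e.g. ``rho``, ``sigma_b2``, ``beta1``), ``terms`` (restrict the preset
    fixed effects), ``sampler`` (McmcSettings fields).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = ScenarioConfig(raw)
    cfg.setdefault("n", 792)
    cfg.setdefault("seed", 0)
    cfg.setdefault("max_followups", 20)
    cfg.setdefault("miss_prob", 0.1)

    pspec = raw.get("params", "preset")
    params = table_preset(raw.get("terms"))
    if isinstance(pspec, dict):
        fields = dict(
            beta1={**params.beta1, **pspec.get("beta1", {})},
            beta2={**params.beta2, **pspec.get("beta2", {})},
            Sigma_nu=np.asarray(pspec.get("Sigma_nu", params.Sigma_nu), dtype=float),
            sigma_b2=pspec.get("sigma_b2", params.sigma_b2),
            sigma_nu2=pspec.get("sigma_nu2", params.sigma_nu2),
            tau=tuple(pspec.get("tau", params.tau)),
            tau_b=pspec.get("tau_b", params.tau_b),
            rho=pspec.get("rho", params.rho),
            phi=pspec.get("phi", params.phi),
        )
        params = TrueParameters(**fields)
    cfg["params"] = params
    cfg["settings"] = McmcSettings(**raw.get("sampler", {}))
    return cfg
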