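"""Configuration parsing, run manifests and synthetic test fixtures."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import recovery_model
from .network import VARIANTS, ModelParameters

_PARAM_KEYS = {f.name for f in fields(ModelParameters)}
_RUN_KEYS = {"variant", "soi", "n_stimuli", "bidirectional", "added_ff", "added_fb",
             "meg_weights"}


@dataclass
class RunSettings:
    """Stimulation and variant settings resolved from a config file."""

    variant: str = "DEF"
    soi: float = 0.5
    n_stimuli: int = 111
    bidirectional: bool = False
    added_ff: float | None = None
    added_fb: float | None = None
    meg_weights: str = "depressed"


@dataclass
class RunManifest:
    """Fully resolved provenance of a run; exports are reproducible from it."""

    parameters: dict
    settings: dict
    tool_version: str
    seed: int | None = None  # only noise-bearing fixtures carry a seed
    outputs: list[str] | None = None

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def load_config(path: str | Path | None) -> tuple[ModelParameters, RunSettings]:
    """Read a YAML/JSON config; missing keys fall back to the defaults.

    Keys are named after the model symbols (tau_m, tau_o, tau_rec, a,
    alpha, w_ee_d, ..., k2_d) plus run settings (variant, soi, n_stimuli,
    bidirectional, added_ff, added_fb, meg_weights).  Unknown keys are
    rejected.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _PARAM_KEYS - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    params = ModelParameters(**{k: raw[k] for k in raw if k in _PARAM_KEYS})
    settings = RunSettings(**{k: raw[k] for k in raw if k in _RUN_KEYS})
    if settings.variant not in VARIANTS:
        raise ValueError(f"unknown variant {settings.variant!r}")
    return params, settings


def make_manifest(params: ModelParameters, settings: RunSettings,
                  seed: int | None = None, outputs=None) -> RunManifest:
    from . import __version__

    return RunManifest(
        parameters=asdict(params),
        settings=asdict(settings),
        tool_version=__version__,
        seed=seed,
        outputs=list(outputs) if outputs else None,
    )


FIXTURE_KINDS = ("exp_recovery", "damped_wave")


def make_fixture(
    kind: str,
    params: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a synthetic CSV fixture for the fitting/peak-extraction tools.

    ``exp_recovery`` samples the saturating-exponential recovery model
    (optionally with multiplicative Gaussian noise of relative sigma);
    ``damped_wave`` samples a sum of damped cosines
    sum_k amp_k exp(gamma_k t) cos(2 pi nu_k t + phase_k).
    """
    p = dict(params or {})
    if kind == "exp_recovery":
        sois = np.asarray(p.get("sois", (0.5, 1.0, 2.5, 5.0, 10.0)), dtype=float)
        y = recovery_model(sois, p.get("A", 1.0), p.get("t0", -1.0), p.get("tau", 2.5))
        sigma = p.get("sigma", 0.0)
        if sigma > 0:
            rng = np.random.default_rng(seed)
            y = y * (1.0 + sigma * rng.standard_normal(y.size))
        return pd.DataFrame({"soi_s": sois, "peak_amplitude": y})
    if kind == "damped_wave":
        t = np.arange(0.0, p.get("duration", 0.6), p.get("dt", 1e-3))
        modes = p.get("modes", [{"amp": 1.0, "gamma": -10.0, "nu": 5.0, "phase": 0.0}])
        r = np.zeros_like(t)
        for m in modes:
            r += m.get("amp", 1.0) * np.exp(m["gamma"] * t) * np.cos(
                2 * np.pi * m["nu"] * t + m.get("phase", 0.0)
            )
        return pd.DataFrame({"time_s": t, "R": r})
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
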