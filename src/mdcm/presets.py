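"""Regime presets: parameter sets + calibrated drive/threshold defaults.

Each preset is a structured text (YAML) file shipped with the package:

* ``decision`` — bistable fixed-point (choice-attractor) regime;
* ``steady_state_control`` — same family with increased self-excitation
  (C7 = 3) and balanced laterals, suppressing multistability;
* ``period_doubling`` — rate model, two alternating oscillation amplitudes;
* ``chaos`` — rate model with asymmetric inhibitory laterals.

Printed parameters are the tabulated ground-truth/prior values; the
unprinted knobs (firing threshold ``V_star``, constant drives, stimulus
amplitude, decision threshold) carry the regime-scan calibration
documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .models import DecisionModelParams, RateModelParams
from .stimuli import NoiseProcessSpec, StimulusSpec

__all__ = ["RegimePreset", "load_preset", "preset_names"]

_PRESET_DIR = resources.files("mdcm") / "presets"


@dataclass(frozen=True)
class RegimePreset:
    """One simulation regime bundled with its calibrated settings."""

    name: str
    kind: str                              # "decision" | "rate"
    params: DecisionModelParams | RateModelParams
    epoch: float
    dt: float
    drive: float | None = None             # constant drive (rate regimes)
    stimulus: StimulusSpec | None = None   # defaults at epsilon = 0
    noise: NoiseProcessSpec | None = None
    threshold: float | None = None         # decision threshold (e1 PSP, mV)


def preset_names() -> list[str]:
    return sorted(p.name.removesuffix(".yaml")
                  for p in _PRESET_DIR.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> RegimePreset:
    """Load a shipped preset (or any YAML file path) into a RegimePreset."""
    path = _PRESET_DIR / f"{name}.yaml"
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raw = yaml.safe_load(open(name).read())
        name = raw.get("name", name)
    kind = raw["kind"]
    if kind == "decision":
        params = DecisionModelParams(**raw["params"])
    elif kind == "rate":
        params = RateModelParams(**raw["params"])
    else:
        raise ValueError(f"unknown preset kind {kind!r}")
    stim = StimulusSpec(**raw["stimulus"]) if "stimulus" in raw else None
    noise = NoiseProcessSpec(**raw["noise"]) if "noise" in raw else None
    return RegimePreset(name=name, kind=kind, params=params,
                        epoch=float(raw.get("epoch", 2.0)),
                        dt=float(raw.get("dt", 1e-3)),
                        drive=raw.get("drive"), stimulus=stim, noise=noise,
                        threshold=raw.get("threshold"))
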