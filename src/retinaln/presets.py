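"""Frozen cell presets: "ONT-like" (transient) and "ONS-like" (sustained).

Each preset bundles the ground-truth LN filter, output nonlinearity and
response noise of a simulated cell with the depressing-synapse parameters
and conductance gains that reproduce the transient/sustained phenotype.
The numbers live in ``presets.yaml`` and were calibrated once against the
published kinetics regimes (see docs/methods.md); code and tests refer to
presets by name, never to magic numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .errors import ParameterError
from .ln import LinearFilter
from .synth import DepressingSynapse, GroundTruthLN, Rectifier, make_ground_truth_filter

__all__ = ["CellPreset", "load_presets", "get_preset", "bipolar_filter", "preset_names"]


@dataclass
class CellPreset:
    """All frozen parameters of one simulated cell type."""

    name: str
    label: str
    filter_params: dict  # ground-truth LN (STA-like) kernel
    inh_filter_params: dict  # kernel shaping the inhibitory conductance
    nonlinearity: dict  # rectifier threshold/gain for the LN output stage
    response_noise_sd: float  # additive output noise, response units
    synapse: dict  # single-pool depression parameters
    epsc: dict  # quantal amplitude (pA) and kernel tau (s)
    conductance: dict  # g_exc/g_inh gains (nS per unit rectified drive)
    spiking: dict  # rate scale (Hz per unit normalized drive), refractory (s)

    def ground_truth_filter(self, dt_s: float = 1e-3, T_filt_s: float = 0.5) -> LinearFilter:
        return make_ground_truth_filter(dt_s=dt_s, T_filt_s=T_filt_s, **self.filter_params)

    def inh_filter(self, dt_s: float = 1e-3, T_filt_s: float = 0.5) -> LinearFilter:
        return make_ground_truth_filter(dt_s=dt_s, T_filt_s=T_filt_s, **self.inh_filter_params)

    def ln_cell(self, dt_s: float = 1e-3, T_filt_s: float = 0.5) -> GroundTruthLN:
        nl = Rectifier(
            threshold=self.nonlinearity["threshold"], gain=self.nonlinearity["gain"]
        )
        return GroundTruthLN(self.ground_truth_filter(dt_s, T_filt_s), nl, "pA")

    def depressing_synapse(self) -> DepressingSynapse:
        return DepressingSynapse(
            pool_size=self.synapse["pool_size"],
            release_rate_k=self.synapse["release_rate_k"],
            threshold=self.synapse["threshold"],
            tau_replenish_s=self.synapse["tau_replenish_s"],
        )


@lru_cache(maxsize=1)
def _raw() -> dict:
    text = resources.files("retinaln").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def load_presets() -> dict[str, CellPreset]:
    raw = _raw()
    return {
        name: CellPreset(name=name, **entry) for name, entry in raw["presets"].items()
    }


def preset_names() -> list[str]:
    return list(_raw()["presets"])


def get_preset(name: str) -> CellPreset:
    presets = load_presets()
    if name not in presets:
        raise ParameterError(f"unknown preset {name!r}; have {sorted(presets)}")
    return presets[name]


def bipolar_filter(dt_s: float = 1e-3, T_filt_s: float = 0.5) -> LinearFilter:
    """Shared presynaptic (bipolar-voltage) kernel: the sustained, mildly
    biphasic stage that drives the synapse model in every preset — the
    emulated bipolar subtypes are kinetically indistinguishable."""
    return make_ground_truth_filter(dt_s=dt_s, T_filt_s=T_filt_s, **_raw()["bipolar"]["filter"])
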