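"""Named, versioned simulation presets.

Presets bundle every parameter of one synthetic experiment family so that
simulations are reproducible from a name and a seed alone.  They live in
``presets.yaml`` inside the package; ``load_presets`` parses them once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Any, Mapping

import yaml

from .errors import ConfigError

_REQUIRED: dict[str, tuple[str, ...]] = {
    "condition_pair": (
        "scale_factor", "scale_target", "length_um", "width_nm", "n_puncta",
        "pixel_size_nm", "psf_fwhm_nm", "photon_scale", "read_noise_sd",
        "background_level", "n_replicates",
    ),
    "contact": (
        "length_um", "width_nm", "n_puncta", "bound_fraction",
        "bind_distance_nm", "er_tubule_radius_nm", "pixel_size_nm",
        "psf_fwhm_nm", "photon_scale", "photon_scale_er", "read_noise_sd",
        "background_level", "dilate_nm", "n_replicates",
    ),
    "branch": (
        "length_um", "width_nm", "n_branches", "branch_window_um",
        "shaft_density_per_um", "branch_enrichment", "pixel_size_nm",
        "psf_fwhm_nm", "photon_scale", "read_noise_sd", "background_level",
        "n_replicates",
    ),
}


@dataclass(frozen=True)
class SimulationPreset:
    """A complete, validated parameter set for one simulated experiment."""

    name: str
    kind: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _REQUIRED:
            raise ConfigError(f"unknown preset kind {self.kind!r}")
        missing = [k for k in _REQUIRED[self.kind] if k not in self.params]
        if missing:
            raise ConfigError(
                f"preset {self.name!r} is missing parameters: {missing}"
            )

    def __getattr__(self, key: str) -> Any:
        try:
            return self.params[key]
        except KeyError:
            raise AttributeError(key) from None

    def get(self, key: str, default: Any = None) -> Any:
        return self.params.get(key, default)


@lru_cache(maxsize=1)
def load_presets() -> dict[str, SimulationPreset]:
    """Parse the packaged ``presets.yaml`` into preset objects."""
    text = resources.files(__package__).joinpath("presets.yaml").read_text()
    raw = yaml.safe_load(text)
    out: dict[str, SimulationPreset] = {}
    for name, entry in raw["presets"].items():
        entry = dict(entry)
        kind = entry.pop("kind")
        out[name] = SimulationPreset(name=name, kind=kind, params=entry)
    return out


def get_preset(name: str) -> SimulationPreset:
    presets = load_presets()
    if name not in presets:
        raise ConfigError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    return presets[name]
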