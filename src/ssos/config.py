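"""Run configuration: one YAML/JSON file describing a whole experiment.

Blocks: ``optics`` (NA, immersion index, wavelengths, voxel sizes — lengths
in nm), ``grid`` (voxel counts), ``pattern`` (raw contrast m, polarization
ratio t or anisotropy r, pattern frequency as a fraction f of the lateral
excitation cutoff, phase offset), ``recon`` (deconvolution options),
``noise`` (photon budget and seed), plus ``output_dir`` and ``verbosity``.
Unknown keys are rejected.  Frequencies are reported in cycles/µm
throughout the package.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import simulate as sim
from .optics import GridSpec, OpticalConfig, lateral_cutoff
from .recon import ReconOptions
from .simulate import NoiseConfig, PatternParams

__all__ = ["RunConfig", "load_config"]

logger = logging.getLogger("ssos")

_DEFAULTS = {
    "optics": {
        "numerical_aperture": 1.49,
        "refr_index": 1.518,
        "wavelength_em": 520.0,
        "wavelength_exc": 488.0,
        "voxel_xy": 40.0,
        "voxel_z": 40.0,
    },
    "grid": {"shape": [128, 8, 256]},
    "pattern": {
        "raw_mod": 0.5,
        "pol_ratio": 3.0,
        "anisotropy": None,
        "freq_fraction": 0.3,
        "phase_offset": 0.0,
    },
    "recon": {
        "deconv_method": "wiener",
        "wiener_w": 1e-3,
        "rl_iterations": 20,
        "support_eps": 1e-3,
        "n_min": 0.01,
    },
    "noise": {"peak_photons": 1e4, "seed": 0},
    "output_dir": "ssos_output",
    "verbosity": "INFO",
}


@dataclass
class RunConfig:
    """Validated, merged experiment configuration."""

    optics: dict
    grid: dict
    pattern: dict
    recon: dict
    noise: dict
    output_dir: str
    verbosity: str

    def optical_config(self) -> OpticalConfig:
        return OpticalConfig(**self.optics)

    def grid_spec(self) -> GridSpec:
        return GridSpec(
            shape=tuple(self.grid["shape"]),
            voxel_xy=self.optics["voxel_xy"],
            voxel_z=self.optics["voxel_z"],
        )

    def pattern_params(self) -> PatternParams:
        cfg = self.optical_config()
        grid = self.grid_spec()
        p = dict(self.pattern)
        t = p["pol_ratio"]
        if p.get("anisotropy") is not None:
            t = sim.anisotropy_ratio(p["anisotropy"])
        f = p["freq_fraction"]
        if f >= 0.5:
            logger.warning(
                "pattern frequency fraction f = %.2f >= 0.5: optical sectioning "
                "performance degrades above half the cutoff", f,
            )
        k_exc = lateral_cutoff(cfg, "excitation")
        dkx = grid.freq_steps()[2]
        freq_px = int(round(f * k_exc / dkx))
        return PatternParams(
            freq_px=freq_px,
            phase_offset=p["phase_offset"],
            mod_contrast=sim.effective_modulation(t, p["raw_mod"]),
            raw_mod=p["raw_mod"],
            pol_ratio=t,
        )

    def recon_options(self) -> ReconOptions:
        return ReconOptions(**self.recon)

    def noise_config(self) -> NoiseConfig:
        # YAML 1.1 reads bare "1e5" as a string; be forgiving about scalars
        return NoiseConfig(
            peak_photons=float(self.noise["peak_photons"]),
            seed=int(self.noise["seed"]),
        )

    def digest(self) -> str:
        """Stable hash of the effective configuration, for provenance."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def echo(self, out_dir) -> Path:
        """Write the effective merged configuration into the output directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "effective_config.json"
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def _merge_block(name: str, defaults: dict, user: dict) -> dict:
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(f"unknown keys in config block '{name}': {sorted(unknown)}")
    merged = dict(defaults)
    merged.update(user)
    return merged


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML/JSON config file, merge with defaults, reject unknown keys."""
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
    if overrides:
        for block, values in overrides.items():
            user.setdefault(block, {})
            if isinstance(values, dict):
                user[block].update(values)
            else:
                user[block] = values
    unknown = set(user) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    blocks = {}
    for name, defaults in _DEFAULTS.items():
        if isinstance(defaults, dict):
            blocks[name] = _merge_block(name, defaults, user.get(name, {}) or {})
        else:
            blocks[name] = user.get(name, defaults)
    return RunConfig(**blocks)
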