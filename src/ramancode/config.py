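"""Run configuration: one YAML document binding every stage's parameters."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .preprocess import PreprocessParams
from .scheme import CodeScheme, default_scheme, scheme_from_dict, scheme_to_dict
from .simulate import NoiseModel, SimulationConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a reproducible run, serializable to YAML bit-exactly."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocessing: PreprocessParams = field(default_factory=PreprocessParams)
    decode_window: float = 20.0
    decode_min_reference: float = 5.0
    calibration_min_sigma: float = 1e-3
    survivability_delta: float = 0.15

    @property
    def scheme(self) -> CodeScheme:
        return self.simulation.scheme

    def to_dict(self) -> dict:
        sim = self.simulation
        return {
            "seed": self.seed,
            "scheme": scheme_to_dict(sim.scheme),
            "simulation": {
                "noise": {
                    "additive_sd": sim.noise.additive_sd,
                    "multiplicative_cv": sim.noise.multiplicative_cv,
                    "baseline_amplitude": sim.noise.baseline_amplitude,
                },
                "base_amplitude": sim.base_amplitude,
                "polystyrene_amplitude": sim.polystyrene_amplitude,
                "coupling_decay": sim.coupling_decay,
                "lineshape": sim.lineshape,
                "wavenumber_start": sim.wavenumber_start,
                "wavenumber_stop": sim.wavenumber_stop,
                "wavenumber_step": sim.wavenumber_step,
                "n_frames": sim.n_frames,
            },
            "preprocessing": {
                **asdict(self.preprocessing),
                "crop_range": list(self.preprocessing.crop_range)
                if self.preprocessing.crop_range
                else None,
            },
            "decoding": {
                "window": self.decode_window,
                "min_reference": self.decode_min_reference,
                "calibration_min_sigma": self.calibration_min_sigma,
            },
            "survivability": {"delta": self.survivability_delta},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        scheme = scheme_from_dict(data["scheme"]) if "scheme" in data else default_scheme()
        sim_data = dict(data.get("simulation", {}))
        noise = NoiseModel(**sim_data.pop("noise", {}))
        simulation = SimulationConfig(scheme=scheme, noise=noise, **sim_data)
        pp_data = dict(data.get("preprocessing", {}))
        if pp_data.get("crop_range") is not None:
            pp_data["crop_range"] = tuple(pp_data["crop_range"])
        preprocessing = PreprocessParams(**pp_data)
        dec = data.get("decoding", {})
        return cls(
            seed=data.get("seed", 0),
            simulation=simulation,
            preprocessing=preprocessing,
            decode_window=dec.get("window", 20.0),
            decode_min_reference=dec.get("min_reference", 5.0),
            calibration_min_sigma=dec.get("calibration_min_sigma", 1e-3),
            survivability_delta=data.get("survivability", {}).get("delta", 0.15),
        )

    def config_hash(self) -> str:
        """Short digest of the serialized config, logged with every run."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
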