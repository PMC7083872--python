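"""Pipeline configuration: validation, YAML round-trip, provenance hash."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kinetics import AcquisitionProtocol, KineticModel

__all__ = ["DetectionSettings", "FitSettings", "SimulationSpec", "PipelineConfig"]


@dataclass(frozen=True)
class DetectionSettings:
    threshold_multiple: float = 8.0
    r_inner: int = 1
    r_outer: int = 3
    link_radius_px: float = 3.0
    min_frames: int = 1

    def __post_init__(self) -> None:
        if self.threshold_multiple <= 0:
            raise ValueError("threshold_multiple must be positive")
        if not (self.r_outer > self.r_inner >= 1):
            raise ValueError("require r_outer > r_inner >= 1")
        if self.link_radius_px <= 0:
            raise ValueError("link_radius_px must be positive")
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")

    def to_dict(self) -> dict:
        return {
            "threshold_multiple": self.threshold_multiple,
            "r_inner": self.r_inner,
            "r_outer": self.r_outer,
            "link_radius_px": self.link_radius_px,
            "min_frames": self.min_frames,
        }


@dataclass(frozen=True)
class FitSettings:
    model_order: int | str = "auto"   # 1 | 2 | "auto" (linearity diagnostic)
    n_boot: int = 10
    frac: float = 0.8
    n_starts: int = 8

    def __post_init__(self) -> None:
        if self.model_order not in (1, 2, "auto"):
            raise ValueError("model_order must be 1, 2 or 'auto'")
        if self.n_boot < 0:
            raise ValueError("n_boot must be non-negative")
        if not (0 < self.frac <= 1):
            raise ValueError("frac must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "model_order": self.model_order,
            "n_boot": self.n_boot,
            "frac": self.frac,
            "n_starts": self.n_starts,
        }


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth model + event budget for a simulated run."""

    model: KineticModel
    n_events_per_tau: int = 2000

    def __post_init__(self) -> None:
        if self.n_events_per_tau < 1:
            raise ValueError("n_events_per_tau must be >= 1")

    def to_dict(self) -> dict:
        return {"model": self.model.to_dict(),
                "n_events_per_tau": self.n_events_per_tau}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproducible pipeline run needs.

    A serialized copy (plus its hash and the seed) is written into every
    output directory, so results always carry their provenance.
    """

    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    fit: FitSettings = field(default_factory=FitSettings)
    simulation: SimulationSpec | None = None
    events_csv: str | None = None
    movie_tiff: str | None = None
    seed: int = 0
    output_dir: str = "intervalkinetics_out"

    def __post_init__(self) -> None:
        sources = [s is not None for s in
                   (self.simulation, self.events_csv, self.movie_tiff)]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one input source required: simulation, events_csv "
                "or movie_tiff"
            )

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol.to_dict(),
            "detection": self.detection.to_dict(),
            "fit": self.fit.to_dict(),
            "simulation": None if self.simulation is None else self.simulation.to_dict(),
            "events_csv": self.events_csv,
            "movie_tiff": self.movie_tiff,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = d.get("simulation")
        return cls(
            protocol=AcquisitionProtocol.from_dict(d["protocol"]),
            detection=DetectionSettings(**d.get("detection", {})),
            fit=FitSettings(**d.get("fit", {})),
            simulation=None if sim is None else SimulationSpec(
                model=KineticModel.from_dict(sim["model"]),
                n_events_per_tau=sim.get("n_events_per_tau", 2000),
            ),
            events_csv=d.get("events_csv"),
            movie_tiff=d.get("movie_tiff"),
            seed=int(d.get("seed", 0)),
            output_dir=d.get("output_dir", "intervalkinetics_out"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
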