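"""YAML run configuration with validation, canonical hashing and round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ValidationError
from .mesh import DEFAULT_LAYERS, TissueLayer

__all__ = ["RunConfig", "MeshConfig", "ElectrodeConfig", "RoiConfig", "StimulationConfig"]


@dataclass
class MeshConfig:
    layers: list = field(
        default_factory=lambda: [
            {"name": la.name, "outer_radius_mm": la.outer_radius,
             "conductivity_S_per_m": la.conductivity}
            for la in DEFAULT_LAYERS
        ]
    )
    edge_length_mm: float = 10.0
    seed: int = 0

    def tissue_layers(self):
        return [
            TissueLayer(d["name"], float(d["outer_radius_mm"]), float(d["conductivity_S_per_m"]))
            for d in self.layers
        ]


@dataclass
class ElectrodeConfig:
    n_candidates: int = 16
    diameter_mm: float = 10.0
    thickness_mm: float = 2.5
    reference_polar_angle_deg: float = 115.0


@dataclass
class RoiConfig:
    target_center_mm: list = field(default_factory=lambda: [0.0, 0.0, 37.0])
    target_radius_mm: float = 6.0


@dataclass
class StimulationConfig:
    f1_hz: float = 2000.0
    f2_hz: float = 2010.0
    alpha_min_mA: float = 0.5
    alpha_max_mA: float = 1.5
    alpha_step_mA: float = 0.05
    total_current_mA: float = 2.0
    constraint_threshold_V_per_m: float = 0.2
    objective_mode: str = "max_pr_with_amplitude_floor"
    pr_floor: float = 1.0
    #: conductivity used for the homogenized-head baseline search
    homogeneous_sigma_S_per_m: float = 0.276


@dataclass
class RunConfig:
    mesh: MeshConfig = field(default_factory=MeshConfig)
    electrodes: ElectrodeConfig = field(default_factory=ElectrodeConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    stimulation: StimulationConfig = field(default_factory=StimulationConfig)
    output_directory: str = "runs/demo"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"mesh", "electrodes", "roi", "stimulation", "output"}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config sections: {sorted(unknown)}")

        def build(klass, section):
            payload = data.get(section, {}) or {}
            fields = {f for f in klass.__dataclass_fields__}
            bad = set(payload) - fields
            if bad:
                raise ValidationError(f"unknown keys in [{section}]: {sorted(bad)}")
            return klass(**payload)

        out_dir = (data.get("output", {}) or {}).get("directory", "runs/demo")
        return cls(
            mesh=build(MeshConfig, "mesh"),
            electrodes=build(ElectrodeConfig, "electrodes"),
            roi=build(RoiConfig, "roi"),
            stimulation=build(StimulationConfig, "stimulation"),
            output_directory=str(out_dir),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "mesh": asdict(self.mesh),
            "electrodes": asdict(self.electrodes),
            "roi": asdict(self.roi),
            "stimulation": asdict(self.stimulation),
            "output": {"directory": self.output_directory},
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    def content_hash(self) -> str:
        """Canonical hash of everything that influences the computation."""
        payload = self.to_dict()
        payload.pop("output")  # output location does not change results
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()
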