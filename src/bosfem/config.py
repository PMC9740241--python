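"""Run configuration for the end-to-end pipeline.

Every default is an implementation decision unless noted: the scan-protocol
defaults (120 kVp / 3 mm slices / pitch 1.5 / 480 mm FOV / 0.9375 mm
in-plane) and the 7.5 / 8.5 risk cuts are the protocolled values; everything
else (thresholds, mesh edge, material constants, load stepping, g) is a
documented choice exposed here.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .materials import MaterialLaw
from .scoring import G_N_PER_KG, HIGH_RISK_CUT, MODERATE_UPPER
from .synthetic_ct import CTProtocol

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # synthetic input
    preset: str = "lytic-small"
    seed: int = 0
    spacing_mm: float = 1.5
    hu_slope: float = 1.0
    hu_intercept: float = -50.0
    noise_sd_hu: float = 0.0
    protocol: CTProtocol = field(default_factory=CTProtocol)
    # segmentation
    density_threshold_mg_cm3: float = 150.0
    closing_radius_mm: float = 2.0
    # meshing
    target_edge_mm: float = 4.5
    # materials
    material_law: MaterialLaw = field(default_factory=MaterialLaw)
    # loading
    cap_angle_deg: float = 30.0
    displacement_increment_mm: float = 0.2
    max_displacement_mm: float = 1.2
    force_drop_fraction: float = 0.95
    newton_tol: float = 1e-6
    max_newton_iter: int = 25
    # scoring
    body_weight_kg: float = 80.0
    g_n_per_kg: float = G_N_PER_KG
    high_risk_cut: float = HIGH_RISK_CUT
    moderate_upper: float = MODERATE_UPPER

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be > 0")
        if self.spacing_mm <= 0 or self.target_edge_mm <= 0:
            raise ValueError("spacings must be > 0")
        if not 0 < self.high_risk_cut <= self.moderate_upper:
            raise ValueError("risk cuts must satisfy 0 < high cut <= moderate upper")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("protocol"), dict):
            d["protocol"] = CTProtocol(**d["protocol"])
        if isinstance(d.get("material_law"), dict):
            d["material_law"] = MaterialLaw(**d["material_law"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from JSON or TOML, keyed by file extension."""
        p = Path(path)
        if p.suffix.lower() == ".toml":
            import tomllib

            d = tomllib.loads(p.read_text())
        else:
            d = json.loads(p.read_text())
        return cls.from_dict(d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
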