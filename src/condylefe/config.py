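"""Run configuration: schema-validated, with the study's load constants
as defaults.

Unknown keys are rejected; every pipeline run re-emits the resolved
configuration verbatim so an output directory is reconstructible from its
config + seed.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Strict):
    voxel_spacing: float = 0.8
    shaft_length: float = 40.0
    condyle_radius: float = 11.0
    condyle_separation: float = 10.0
    ridge_height: float = 1.2
    ridge_half_width: float = 2.5
    cortical_thickness: float = 1.6
    cortical_density: float = 1.8
    trabecular_density_mean: float = 0.6
    trabecular_density_sd: float = 0.15
    lesion_center: Optional[tuple[float, float, float]] = None
    lesion_radius: float = 0.0
    lesion_density_delta: float = 0.0
    joint_angle: float = 170.0
    congruency_gap: float = 0.5
    counterbody_depth: float = 6.0


class CalibrationConfig(_Strict):
    slope: float = 1.0e-3                 # g/cm^3 per HU
    intercept: float = 0.0                # g/cm^3
    ash_to_apparent_ratio: float = 0.6


class MeshingConfig(_Strict):
    threshold: float = 0.2                # g/cm^3 segmentation threshold
    coarsening: int = 2
    element_type: str = "hex8"


class MaterialsConfig(_Strict):
    poisson_ratio: float = 0.3
    target_mass_kg: float = 5.0
    augment_mass: bool = True
    modulus_scale: float = 1.0            # 1.5 = sensitivity variant


class ImpactConfig(_Strict):
    velocity_ms: float = 3.55
    contact_stiffness: float = 12.0       # MPa/mm
    friction_mu: float = 0.007
    duration_ms: float = 3.0
    output_interval_ms: float = 0.25
    safety: float = 0.8
    max_overclosure_factor: float = 10.0


class StaticConfig(_Strict):
    pressure_MPa: float = 19.5            # on dorsal + palmar patches
    fixed_set: str = "proximal_end"


class AnalysisConfig(_Strict):
    grid_rows: int = 8
    grid_cols: int = 20
    slice_offset: float = 5.0             # mm from the transverse ridge
    articular_z_fraction: float = 0.7


class RunConfig(_Strict):
    """Full pipeline configuration."""

    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    meshing: MeshingConfig = Field(default_factory=MeshingConfig)
    materials: MaterialsConfig = Field(default_factory=MaterialsConfig)
    impact: ImpactConfig = Field(default_factory=ImpactConfig)
    static: StaticConfig = Field(default_factory=StaticConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    variants: list[str] = Field(default_factory=lambda: ["healthy"])
    load_cases: list[str] = Field(default_factory=lambda: ["impact"])
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=False)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text
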