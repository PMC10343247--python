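"""Run configuration: constituent materials, bridging parameters, braid
geometry, mesh resolutions and load set.

The schema is strict (unknown keys are rejected) and all user-facing moduli
are in GPa, matching the published materials table; values are converted to
the internal MPa unit system by the accessor methods.  The packaged default
configuration reproduces the Kevlar/PCU study setup.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .materials import (
    BridgingParams,
    IsotropicMaterial,
    TransverselyIsotropicMaterial,
)

__all__ = ["RunConfig", "load_config", "default_config_path"]

_GPA = 1000.0  # MPa per GPa


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class FiberMaterialConfig(_Strict):
    """Transversely isotropic reinforcing fiber (defaults: Kevlar)."""

    longitudinal_modulus_gpa: float = 128.7
    transverse_modulus_gpa: float = 12.87
    longitudinal_poisson_ratio: float = 0.3
    longitudinal_shear_modulus_gpa: float = 12.87
    transverse_shear_modulus_gpa: float = 12.87

    def material(self) -> TransverselyIsotropicMaterial:
        E22 = self.transverse_modulus_gpa * _GPA
        G23 = self.transverse_shear_modulus_gpa * _GPA
        # transverse isotropy fixes v23 from (E22, G23)
        v23 = E22 / (2.0 * G23) - 1.0
        return TransverselyIsotropicMaterial(
            E11=self.longitudinal_modulus_gpa * _GPA,
            E22=E22,
            v12=self.longitudinal_poisson_ratio,
            v23=v23,
            G12=self.longitudinal_shear_modulus_gpa * _GPA,
        )


class MatrixMaterialConfig(_Strict):
    """Isotropic matrix (defaults: polycarbonate polyurethane, PCU)."""

    elastic_modulus_gpa: float = 0.057
    poisson_ratio: float = 0.43

    def material(self) -> IsotropicMaterial:
        return IsotropicMaterial(E=self.elastic_modulus_gpa * _GPA, v=self.poisson_ratio)


class MaterialsConfig(_Strict):
    fiber: FiberMaterialConfig = Field(default_factory=FiberMaterialConfig)
    matrix: MatrixMaterialConfig = Field(default_factory=MatrixMaterialConfig)


class BridgingConfig(_Strict):
    """Bridging-model parameters.  The fiber volume fraction and the two
    bridging parameters are not printed in the source tables; the defaults
    are back-solved so the bundle row is reproduced (Vf from the axial
    rule of mixtures, alpha/beta from the shear/transverse moduli)."""

    Vf: float = 0.70
    alpha: float = 0.30
    beta: float = 0.30

    def params(self) -> BridgingParams:
        return BridgingParams(Vf=self.Vf, alpha=self.alpha, beta=self.beta)


class GeometryConfig(_Strict):
    """Parametric braided-crescent design (defaults: the 32x26x11 mm model).

    Levels are numbered 1..3 bottom-to-top; the five layers follow the
    level stacking (1, 1, 2, 2, 3).
    """

    length_mm: float = 32.0
    width_mm: float = 26.0
    height_mm: float = 11.0
    n_layers: int = 5
    level_of_layer: tuple[int, ...] = (1, 1, 2, 2, 3)
    transverse_counts: tuple[int, ...] = (6, 4, 2)
    longitudinal_counts: tuple[int, ...] = (13, 12, 8)
    transverse_lengths_mm: tuple[float, ...] = (45.0, 40.0, 35.0)
    longitudinal_shortening_mm: tuple[float, ...] = (0.0, 8.0, 6.0)
    fiber_width_mm: float = 2.0
    fiber_height_mm: float = 1.0
    gap_mm: float = 2.0
    fan_angle_deg: float = 15.0
    inner_thickness_mm: float = 3.0
    inner_apex_fraction: float = 10.0 / 26.0
    interlock_diameter_mm: float = 0.5

    @model_validator(mode="after")
    def _check(self) -> "GeometryConfig":
        if len(self.level_of_layer) != self.n_layers:
            raise ValueError("level_of_layer must list one level per layer")
        n_levels = len(self.transverse_counts)
        if len(self.longitudinal_counts) != n_levels:
            raise ValueError("per-level fiber count lists must have equal length")
        if any(c < 0 for c in self.transverse_counts + self.longitudinal_counts):
            raise ValueError("fiber counts must be non-negative")
        return self


class MeshConfig(_Strict):
    macro_resolution_mm: float = 1.5
    rvc_divisions: int = 5
    #: subtract the matrix modulus from embedded bar moduli so the matrix
    #: volume overlapped by the bars is not counted twice
    overlap_correction: bool = True


class LoadsConfig(_Strict):
    newtons: tuple[float, ...] = (400.0, 600.0, 800.0, 1200.0, 1400.0)


class RunConfig(_Strict):
    """Top-level configuration; see the packaged default for the study setup."""

    materials: MaterialsConfig = Field(default_factory=MaterialsConfig)
    bridging: BridgingConfig = Field(default_factory=BridgingConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    mesh: MeshConfig = Field(default_factory=MeshConfig)
    loads: LoadsConfig = Field(default_factory=LoadsConfig)

    # convenience accessors (internal MPa units)
    def fiber(self) -> TransverselyIsotropicMaterial:
        return self.materials.fiber.material()

    def matrix(self) -> IsotropicMaterial:
        return self.materials.matrix.material()

    def bridging_params(self) -> BridgingParams:
        return self.bridging.params()


def default_config_path() -> Path:
    return Path(str(resources.files("braidfe").joinpath("data/default_config.yaml")))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON configuration (default if path is None)."""
    if path is None:
        path = default_config_path()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
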