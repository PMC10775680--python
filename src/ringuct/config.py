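"""Structured run configuration (YAML).

Sections mirror the physical setup: ``grid``, ``medium``, ``ring``,
``pulse``, ``noise`` and ``fwi``.  Unknown keys are rejected (fail fast)
so silently ignored typos cannot alter a study.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .fwi import InversionConfig
from .geometry import RingGeometry
from .grids import CartesianGrid, make_grid
from .media import WATER_DENSITY, WATER_SOS
from .phantoms import Inclusion, PhantomSpec
from .pulses import Pulse, tone_burst_pulse
from .transducer import LensProfile

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    shape: Tuple[int, int, int]
    spacing: float = Field(gt=0, description="voxel edge, m")
    cfl: float = 0.3
    duration: float = Field(gt=0, description="simulation horizon, s")
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def build(self, c_max: float) -> CartesianGrid:
        return make_grid(self.shape, self.spacing, c_max, cfl=self.cfl,
                         duration=self.duration, origin=self.origin)


class InclusionConfig(_Strict):
    kind: str = "gaussian"
    center: Tuple[float, float, float]
    size: Tuple[float, float, float]
    delta_sos: float = 0.0
    delta_density: float = 0.0
    delta_attenuation_db: float = 0.0
    label: str = ""


class MediumConfig(_Strict):
    water_sos: float = WATER_SOS
    water_density: float = WATER_DENSITY
    power_law_exponent: float = 1.5
    outer_center: Optional[Tuple[float, float, float]] = None
    outer_semiaxes: Optional[Tuple[float, float, float]] = None
    outer_sos: float = WATER_SOS
    outer_density: float = WATER_DENSITY
    outer_attenuation_db: float = 0.0
    inclusions: List[InclusionConfig] = []
    hdf5_path: Optional[str] = None
    sos_range: Tuple[float, float] = (1350.0, 1650.0)

    def build_spec(self) -> PhantomSpec:
        return PhantomSpec(
            inclusions=tuple(Inclusion(**i.model_dump()) for i in self.inclusions),
            outer_center=self.outer_center, outer_semiaxes=self.outer_semiaxes,
            outer_sos=self.outer_sos, outer_density=self.outer_density,
            outer_attenuation_db=self.outer_attenuation_db,
            water_sos=self.water_sos, water_density=self.water_density,
            power_law_exponent=self.power_law_exponent,
            sos_range=self.sos_range)


class LensConfig(_Strict):
    curvature: float = 14.0
    offset: float = 0.45e-3
    lens_sos: float = 4500.0
    medium_sos: float = WATER_SOS

    def build(self) -> LensProfile:
        return LensProfile(**self.model_dump())


class RingConfig(_Strict):
    n_emitters: int = 128
    n_receivers: int = 1024
    radius: float = 0.110
    ring_z_positions: Tuple[float, ...] = (0.0,)
    element_height: float = 0.018
    lens: LensConfig = LensConfig()

    def build(self) -> RingGeometry:
        d = self.model_dump()
        d.pop("lens")
        return RingGeometry(**d)


class PulseConfig(_Strict):
    center_frequency: float = 2e6
    max_frequency: Optional[float] = 3.5e6
    n_cycles: Optional[float] = None
    amplitude: float = 1.0

    def build(self, dt: float) -> Pulse:
        return tone_burst_pulse(self.center_frequency, dt,
                                max_frequency=self.max_frequency,
                                n_cycles=self.n_cycles,
                                amplitude=self.amplitude)


class NoiseConfig(_Strict):
    snr_db: float = np.inf
    seed: int = 0


class FwiConfig(_Strict):
    n_iterations: int = 50
    step_size: float = 2.0
    bounds: Tuple[float, float] = (1300.0, 1700.0)
    regularization_weight: float = 0.0
    pml_size: int = 8
    seed: int = 0
    coarse_iterations: int = 0
    coarse_lowpass_fraction: float = 0.5

    def build(self) -> InversionConfig:
        return InversionConfig(**self.model_dump())


class RunConfig(_Strict):
    grid: GridConfig
    medium: MediumConfig = MediumConfig()
    ring: RingConfig = RingConfig()
    pulse: PulseConfig = PulseConfig()
    noise: NoiseConfig = NoiseConfig()
    fwi: FwiConfig = FwiConfig()
    pml_size: int = 10


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig(**raw)
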