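"""Ring-array acquisition geometry.

A circular ring of elevation-focused transducers in the x-y plane.  The
ring is translated vertically (z) between acquisitions; elements are tall,
thin vertical apertures whose axes are parallel to z.  The default layout
mirrors a practical breast-imaging system: 128 emitters and 1024 receivers
evenly spaced on a ring of radius 110 mm, elements 18 mm tall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RingGeometry"]


@dataclass(frozen=True)
class RingGeometry:
    n_emitters: int = 128
    n_receivers: int = 1024
    radius: float = 0.110
    ring_z_positions: tuple = (0.0,)
    element_height: float = 0.018
    emitter_angle_offset: float = 0.0
    receiver_angle_offset: float = 0.0

    def __post_init__(self):
        if self.n_emitters < 1 or self.n_receivers < 1:
            raise ValueError("element counts must be >= 1")
        if not (self.radius > 0):
            raise ValueError("radius must be > 0")
        if not (self.element_height > 0):
            raise ValueError("element_height must be > 0")
        object.__setattr__(self, "ring_z_positions",
                           tuple(float(z) for z in self.ring_z_positions))

    @property
    def emitter_angles(self) -> np.ndarray:
        return self.emitter_angle_offset + 2 * np.pi * np.arange(self.n_emitters) / self.n_emitters

    @property
    def receiver_angles(self) -> np.ndarray:
        return self.receiver_angle_offset + 2 * np.pi * np.arange(self.n_receivers) / self.n_receivers

    def emitter_positions(self, ring_z: float = 0.0, center=(0.0, 0.0)) -> np.ndarray:
        """(n_emitters, 3) element-centre coordinates for one ring elevation."""
        a = self.emitter_angles
        return np.column_stack([
            center[0] + self.radius * np.cos(a),
            center[1] + self.radius * np.sin(a),
            np.full_like(a, float(ring_z)),
        ])

    def receiver_positions(self, ring_z: float = 0.0, center=(0.0, 0.0)) -> np.ndarray:
        a = self.receiver_angles
        return np.column_stack([
            center[0] + self.radius * np.cos(a),
            center[1] + self.radius * np.sin(a),
            np.full_like(a, float(ring_z)),
        ])
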