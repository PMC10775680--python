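"""HDF5 layouts and run manifests.

Channel-data files are single-file and self-describing:

    /traces   float32, (n_emitters, n_receivers, nt)
    /dt       float64, seconds
    /ring/{radius, z, n_emitters, n_receivers}
    /pulse/samples  (+ dt, center_frequency, max_frequency attributes)
    /manifest JSON string

Media volumes are stored as datasets ``c, alpha, rho, y`` with ``spacing``
and ``origin`` attributes.  One channel-data file is written per ring
elevation.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version

import h5py
import numpy as np

from .grids import CartesianGrid
from .media import AcousticMedium
from .pulses import Pulse
from .transducer import ChannelData

__all__ = ["RunManifest", "save_channel_data", "load_channel_data",
           "save_medium", "load_medium", "save_sensitivity_map"]


def _package_version() -> str:
    try:
        return version("ringuct")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    code_version: str = field(default_factory=_package_version)
    runtimes: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    platform: str = field(default_factory=platform.platform)

    def to_json(self) -> str:
        return json.dumps({
            "config": self.config, "seeds": self.seeds,
            "code_version": self.code_version, "runtimes": self.runtimes,
            "outputs": self.outputs, "platform": self.platform,
        }, indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        return cls(config=d.get("config", {}), seeds=d.get("seeds", {}),
                   code_version=d.get("code_version", "unknown"),
                   runtimes=d.get("runtimes", {}),
                   outputs=d.get("outputs", []),
                   platform=d.get("platform", ""))


def save_channel_data(path, data: ChannelData, ring: dict = None,
                      pulse: Pulse = None, manifest: RunManifest = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=np.asarray(data.traces, np.float32))
        f.create_dataset("dt", data=np.float64(data.dt))
        g = f.create_group("ring")
        ring = ring or {}
        g.create_dataset("radius", data=float(ring.get("radius", np.nan)))
        g.create_dataset("z", data=float(ring.get("z", data.ring_z)))
        g.create_dataset("n_emitters", data=int(data.n_emitters))
        g.create_dataset("n_receivers", data=int(data.n_receivers))
        if pulse is not None:
            p = f.create_group("pulse")
            p.create_dataset("samples", data=pulse.samples)
            p.attrs["dt"] = pulse.dt
            p.attrs["center_frequency"] = pulse.center_frequency
            p.attrs["max_frequency"] = pulse.max_frequency
        if manifest is not None:
            f.create_dataset("manifest", data=manifest.to_json())


def load_channel_data(path):
    """Returns (ChannelData, ring dict, Pulse or None, RunManifest or None)."""
    with h5py.File(path, "r") as f:
        traces = f["traces"][...]
        dt = float(f["dt"][()])
        ring = {k: f["ring"][k][()] for k in f["ring"]}
        pulse = None
        if "pulse" in f:
            p = f["pulse"]
            pulse = Pulse(samples=p["samples"][...], dt=float(p.attrs["dt"]),
                          center_frequency=float(p.attrs["center_frequency"]),
                          max_frequency=float(p.attrs["max_frequency"]))
        manifest = None
        if "manifest" in f:
            raw = f["manifest"][()]
            manifest = RunManifest.from_json(
                raw.decode() if isinstance(raw, bytes) else str(raw))
    data = ChannelData(traces, dt=dt, ring_z=float(ring.get("z", 0.0)))
    return data, ring, pulse, manifest


def save_medium(path, medium: AcousticMedium, grid: CartesianGrid):
    with h5py.File(path, "w") as f:
        f.create_dataset("c", data=medium.sos)
        f.create_dataset("alpha", data=medium.attenuation)
        f.create_dataset("rho", data=medium.density)
        f.create_dataset("y", data=np.asarray(medium.power_law_exponent, float))
        f.attrs["spacing"] = grid.spacing
        f.attrs["origin"] = np.asarray(grid.origin)
        f.attrs["ambient_density"] = medium.ambient_density


def load_medium(path):
    """Returns (AcousticMedium, spacing, origin)."""
    with h5py.File(path, "r") as f:
        y = f["y"][...]
        med = AcousticMedium(
            sos=f["c"][...], attenuation=f["alpha"][...], density=f["rho"][...],
            power_law_exponent=(float(y) if y.ndim == 0 else y),
            ambient_density=float(f.attrs.get("ambient_density", 1000.0)))
        return med, float(f.attrs["spacing"]), tuple(f.attrs["origin"])


def save_sensitivity_map(path, smap, csv_path=None):
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=smap.positions)
        f.create_dataset("values", data=smap.values)
        f.create_dataset("config", data=json.dumps(smap.config, default=str))
    if csv_path is not None:
        arr = np.column_stack([smap.positions, smap.values])
        np.savetxt(csv_path, arr, delimiter=",", header="x,y,z,S", comments="")
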