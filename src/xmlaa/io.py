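"""File formats and run configuration.

Volumes are NIfTI (spacing carried in the affine); sinogram sets are HDF5
containers with one dataset per component (``prompts``, ``norm``,
``scatter``, ``randoms``) and the geometry stored as attributes.  Run
configuration is a single YAML file; every run writes the fully resolved
configuration next to its outputs so that (config, seed) reproduces the run
byte for byte.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .geometry import ImageVolume, ScannerGeometry
from .forward_model import SinogramSet
from .phantoms import PhantomSpec
from .priors import PriorConfig
from .recon import ReconConfig

__all__ = [
    "read_volume",
    "write_volume",
    "read_sinograms",
    "write_sinograms",
    "RunConfig",
    "load_config",
    "save_config",
    "substream_seed",
]

_GEOM_ATTRS = ("n_views", "n_radial", "n_planes", "fov_mm")


def write_volume(vol: ImageVolume, path) -> None:
    affine = np.diag(list(vol.voxel_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.values.astype(np.float64), affine), str(path))


def read_volume(path, geometry: ScannerGeometry | None = None) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    vol = ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing)
    if geometry is not None:
        if vol.shape != geometry.grid_shape:
            raise ValueError(
                f"volume grid {vol.shape} does not match geometry {geometry.grid_shape}"
            )
        if not np.allclose(spacing, geometry.voxel_mm, rtol=1e-5):
            raise ValueError(
                f"volume spacing {spacing} does not match geometry voxels {geometry.voxel_mm}"
            )
    return vol


def write_sinograms(sino: SinogramSet, geom: ScannerGeometry, path) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("prompts", data=sino.prompts)
        f.create_dataset("norm", data=sino.norm)
        f.create_dataset("scatter", data=sino.scatter)
        f.create_dataset("randoms", data=sino.randoms)
        for a in _GEOM_ATTRS:
            f.attrs[a] = getattr(geom, a)


def read_sinograms(path, geom: ScannerGeometry | None = None) -> SinogramSet:
    """Load a sinogram container; a prompts-only file gets the documented
    defaults n = 1, s = r = 0."""
    with h5py.File(str(path), "r") as f:
        prompts = f["prompts"][()]
        kwargs = {}
        for name in ("norm", "scatter", "randoms"):
            if name in f:
                kwargs[name] = f[name][()]
        if geom is not None:
            for a in _GEOM_ATTRS:
                if a in f.attrs and not np.isclose(f.attrs[a], getattr(geom, a)):
                    raise ValueError(
                        f"sinogram attribute {a}={f.attrs[a]} does not match "
                        f"geometry {getattr(geom, a)}"
                    )
    sino = SinogramSet(prompts, **kwargs)
    if geom is not None and sino.shape != geom.sino_shape:
        raise ValueError(f"sinogram shape {sino.shape} != geometry {geom.sino_shape}")
    return sino


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a run needs, resolved to concrete values."""

    geometry: ScannerGeometry = field(default_factory=ScannerGeometry)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    priors: PriorConfig = field(default_factory=PriorConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    noiseless: bool = True
    total_prompts: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "geometry": asdict(self.geometry),
            "phantom": asdict(self.phantom),
            "priors": asdict(self.priors),
            "recon": asdict(self.recon),
            "noiseless": self.noiseless,
            "total_prompts": self.total_prompts,
            "seed": self.seed,
        }
        d["geometry"]["grid_shape"] = list(self.geometry.grid_shape)
        d["geometry"]["voxel_mm"] = list(self.geometry.voxel_mm)
        d["phantom"]["earpad_semi_axes"] = list(self.phantom.earpad_semi_axes)
        return d


def _apply_overrides(d: dict, overrides: dict) -> None:
    for key, value in overrides.items():
        node = d
        parts = key.split(".")
        for p in parts[:-1]:
            node = node[p]
        node[parts[-1]] = yaml.safe_load(str(value))


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    d = RunConfig().to_dict()
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        for section, val in user.items():
            if isinstance(val, dict) and section in d:
                d[section].update(val)
            else:
                d[section] = val
    if overrides:
        _apply_overrides(d, overrides)
    g = d["geometry"]
    g["grid_shape"] = tuple(g["grid_shape"])
    g["voxel_mm"] = tuple(g["voxel_mm"])
    p = d["phantom"]
    p["earpad_semi_axes"] = tuple(p["earpad_semi_axes"])
    return RunConfig(
        geometry=ScannerGeometry(**g),
        phantom=PhantomSpec(**p),
        priors=PriorConfig(**d["priors"]),
        recon=ReconConfig(**d["recon"]),
        noiseless=bool(d["noiseless"]),
        total_prompts=None if d["total_prompts"] is None else float(d["total_prompts"]),
        seed=int(d["seed"]),
    )


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)


def substream_seed(seed: int, stream: str) -> np.random.SeedSequence:
    """Named, independent random substreams from one global seed: adding a
    stage never perturbs another stage's draws."""
    order = {"phantom": 0, "noise": 1, "recon": 2}
    return np.random.SeedSequence(seed).spawn(max(order.values()) + 1)[order[stream]]
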