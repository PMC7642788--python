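"""Containers and file I/O for pattern stacks and 3D volumes.

Pattern stacks live in an HDF5 container with a CXI-like tree::

    /entry/data/counts                [frames, rows, cols]
    /entry/geometry/distance_m        scalar
    /entry/geometry/pixel_size_um     scalar
    /entry/geometry/beam_center_px    (row, col)
    /entry/geometry/photon_energy_keV scalar
    /entry/mask                       [rows, cols] uint8, 1 = valid
    /entry/frame_id                   [frames] int64
    /entry/annotations/*              optional per-frame arrays

Real-space densities are written as MRC/CCP4 maps (float32, voxel size in
the header).  Reciprocal-space intensity volumes carry a per-voxel validity
flag, so they use a small HDF5 layout instead.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import gemmi
import h5py
import numpy as np

from .geometry import DetectorGeometry


class FormatError(RuntimeError):
    """A container file is missing a required field or is malformed."""


@dataclass
class PatternStack:
    """A stack of diffraction frames sharing one detector geometry.

    ``counts`` is (frames, rows, cols); integer dtypes represent raw photon
    counts (non-negative), float dtypes represent photonized signal after
    baseline handling and may dip below zero.  ``annotations`` holds
    optional per-frame arrays (fitted size, class label, truth orientation
    quaternions for synthetic data, ...).
    """

    counts: np.ndarray
    geometry: DetectorGeometry
    mask: np.ndarray = None
    frame_id: np.ndarray = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (frames, rows, cols)")
        if self.counts.shape[1:] != tuple(self.geometry.panel_shape):
            raise ValueError("counts shape does not match geometry panel_shape")
        if np.issubdtype(self.counts.dtype, np.integer) and self.counts.size \
                and self.counts.min() < 0:
            raise ValueError("integer photon counts must be non-negative")
        if self.mask is None:
            self.mask = np.ones(self.counts.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.frame_id is None:
            self.frame_id = np.arange(self.counts.shape[0], dtype=np.int64)
        else:
            self.frame_id = np.asarray(self.frame_id, dtype=np.int64)
            if len(np.unique(self.frame_id)) != len(self.frame_id):
                raise ValueError("frame_id entries must be unique")
        for key, val in self.annotations.items():
            arr = np.asarray(val)
            if arr.shape[0] != self.n_frames:
                raise ValueError(f"annotation {key!r} length mismatch")
            self.annotations[key] = arr

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    def subset(self, index) -> "PatternStack":
        """New stack restricted to the given frame indices (order kept)."""
        index = np.asarray(index)
        ann = {k: v[index] for k, v in self.annotations.items()}
        return PatternStack(counts=self.counts[index], geometry=self.geometry,
                            mask=self.mask.copy(), frame_id=self.frame_id[index],
                            annotations=ann)

    def copy(self) -> "PatternStack":
        return PatternStack(counts=self.counts.copy(), geometry=self.geometry,
                            mask=self.mask.copy(), frame_id=self.frame_id.copy(),
                            annotations={k: v.copy() for k, v in self.annotations.items()})


@dataclass
class IntensityVolume:
    """Cubic 3D reciprocal-space intensity grid.

    The voxel at index ``n // 2`` along each axis is q = 0; ``voxel_q`` is
    the q step per voxel edge in nm^-1.  ``valid`` flags voxels that carry
    measured (or simulated) information.
    """

    values: np.ndarray
    voxel_q: float
    valid: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise ValueError("values must be a cubic 3D grid")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def center(self) -> int:
        return self.values.shape[0] // 2

    def qmag_grid(self) -> np.ndarray:
        """|q| of every voxel centre, in nm^-1."""
        n = self.n
        ax = (np.arange(n) - n // 2) * self.voxel_q
        return np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                       + ax[None, None, :] ** 2)

    def copy(self) -> "IntensityVolume":
        return IntensityVolume(self.values.copy(), self.voxel_q, self.valid.copy())


@dataclass
class DensityField:
    """Real-space 3D field (electron density), real or complex valued."""

    values: np.ndarray
    voxel_nm: float

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be 3D")

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# HDF5 pattern container


def write_stack(stack: PatternStack, path) -> str:
    """Write a PatternStack to the HDF5 container layout; returns the path."""
    if np.issubdtype(stack.counts.dtype, np.integer):
        counts = stack.counts.astype(np.uint32)
    else:
        counts = stack.counts.astype(np.float32)
    with h5py.File(path, "w") as fh:
        g = fh.create_group("entry")
        g.create_dataset("data/counts", data=counts, compression="gzip")
        geo = g.create_group("geometry")
        geo["distance_m"] = stack.geometry.distance_m
        geo["pixel_size_um"] = stack.geometry.pixel_size_um
        geo["beam_center_px"] = np.asarray(stack.geometry.beam_center, dtype=np.float64)
        geo["photon_energy_keV"] = stack.geometry.photon_energy_kev
        g.create_dataset("mask", data=stack.mask.astype(np.uint8))
        g.create_dataset("frame_id", data=stack.frame_id)
        ann = g.create_group("annotations")
        for key, val in stack.annotations.items():
            if val.dtype.kind == "U":
                val = val.astype("S")
            ann.create_dataset(key, data=val)
    return str(path)


def read_stack(path) -> PatternStack:
    """Read a PatternStack written by :func:`write_stack`.

    Raises :class:`FormatError` naming the missing field for malformed
    containers; negative integer counts raise a validation error.
    """
    with h5py.File(path, "r") as fh:
        for req in ("entry/data/counts", "entry/geometry"):
            if req not in fh:
                raise FormatError(f"container lacks required field {req!r}")
        geo = fh["entry/geometry"]
        for req in ("distance_m", "pixel_size_um", "beam_center_px",
                    "photon_energy_keV"):
            if req not in geo:
                raise FormatError(f"container lacks required field entry/geometry/{req!r}")
        geom = DetectorGeometry(
            distance_m=float(geo["distance_m"][()]),
            pixel_size_um=float(geo["pixel_size_um"][()]),
            panel_shape=fh["entry/data/counts"].shape[1:],
            beam_center=tuple(geo["beam_center_px"][()]),
            photon_energy_kev=float(geo["photon_energy_keV"][()]),
        )
        counts = fh["entry/data/counts"][()]
        mask = fh["entry/mask"][()].astype(bool) if "entry/mask" in fh else None
        frame_id = fh["entry/frame_id"][()] if "entry/frame_id" in fh else None
        ann = {}
        if "entry/annotations" in fh:
            for key, ds in fh["entry/annotations"].items():
                val = ds[()]
                if val.dtype.kind == "S":
                    val = val.astype("U")
                ann[key] = val
    return PatternStack(counts=counts, geometry=geom, mask=mask,
                        frame_id=frame_id, annotations=ann)


# ---------------------------------------------------------------------------
# MRC / CCP4 density maps and HDF5 intensity volumes


def write_density_mrc(density: DensityField, path) -> str:
    """Write a real density field as an MRC/CCP4 map (float32, voxel in header).

    Complex fields are written as their modulus.
    """
    values = density.values
    if np.iscomplexobj(values):
        values = np.abs(values)
    grid = gemmi.FloatGrid(np.ascontiguousarray(values, dtype=np.float32))
    n = values.shape
    # angstrom cell so generic MRC tools show sensible spacing (1 nm = 10 A)
    grid.set_unit_cell(gemmi.UnitCell(n[0] * density.voxel_nm * 10.0,
                                      n[1] * density.voxel_nm * 10.0,
                                      n[2] * density.voxel_nm * 10.0,
                                      90, 90, 90))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))
    return str(path)


def read_density_mrc(path) -> DensityField:
    ccp4 = gemmi.read_ccp4_map(str(path))
    values = np.array(ccp4.grid, copy=True)
    voxel_nm = ccp4.grid.unit_cell.a / ccp4.grid.nu / 10.0
    return DensityField(values=values.astype(np.float64), voxel_nm=voxel_nm)


def write_intensity_h5(volume: IntensityVolume, path) -> str:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("intensity/values", data=volume.values.astype(np.float32),
                          compression="gzip")
        fh.create_dataset("intensity/valid", data=volume.valid.astype(np.uint8),
                          compression="gzip")
        fh["intensity/voxel_q"] = volume.voxel_q
    return str(path)


def read_intensity_h5(path) -> IntensityVolume:
    with h5py.File(path, "r") as fh:
        if "intensity/values" not in fh:
            raise FormatError("container lacks required field 'intensity/values'")
        values = fh["intensity/values"][()].astype(np.float64)
        valid = fh["intensity/valid"][()].astype(bool)
        voxel_q = float(fh["intensity/voxel_q"][()])
    return IntensityVolume(values=values, voxel_q=voxel_q, valid=valid)
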