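"""Detector geometry and reciprocal-space mapping.

A single flat detector panel sits downstream of the interaction region,
normal to the beam.  Each pixel is mapped to a momentum-transfer vector
``q`` on the Ewald sphere through the origin, with the convention

    |q| = (4 pi / lambda) sin(theta),   2*theta = atan(r / distance),

where ``r`` is the transverse distance of the pixel from the beam axis.
Real-space resolution corresponding to a momentum transfer is ``d = 2 pi / q``.
All q values are in inverse nanometres, wavelengths in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: hc in keV * nm, used for photon energy <-> wavelength conversion.
HC_KEV_NM = 1.239842


def energy_to_wavelength(energy_kev: float) -> float:
    """Photon energy (keV) to wavelength (nm): lambda = hc / E."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_NM / energy_kev


def wavelength_to_energy(wavelength_nm: float) -> float:
    """Wavelength (nm) to photon energy (keV): E = hc / lambda."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    return HC_KEV_NM / wavelength_nm


def q_to_resolution(q_inv_nm):
    """Momentum transfer (nm^-1) to real-space resolution (nm): d = 2 pi / q."""
    q = np.asarray(q_inv_nm, dtype=float)
    if np.any(q <= 0):
        raise ValueError("momentum transfer must be positive")
    out = 2.0 * np.pi / q
    return float(out) if np.isscalar(q_inv_nm) else out


def resolution_to_q(d_nm):
    """Real-space length (nm) to momentum transfer (nm^-1): q = 2 pi / d."""
    d = np.asarray(d_nm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("resolution must be positive")
    out = 2.0 * np.pi / d
    return float(out) if np.isscalar(d_nm) else out


@dataclass(frozen=True)
class DetectorGeometry:
    """Single flat panel normal to the beam.

    Parameters
    ----------
    distance_m
        Sample-to-detector distance in metres.
    pixel_size_um
        Square pixel edge in micrometres.
    panel_shape
        (rows, cols) of the panel.
    beam_center
        (row, col) of the beam axis in fractional pixel units; pixel (0, 0)
        has its centre at coordinate (0.0, 0.0), row-major.
    photon_energy_kev
        Photon energy in keV.
    """

    distance_m: float
    pixel_size_um: float
    panel_shape: tuple
    beam_center: tuple
    photon_energy_kev: float

    def __post_init__(self):
        if self.distance_m <= 0:
            raise ValueError("detector distance must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        rows, cols = self.panel_shape
        if rows < 1 or cols < 1:
            raise ValueError("panel_shape entries must be >= 1")
        if self.photon_energy_kev <= 0:
            raise ValueError("photon energy must be positive")
        object.__setattr__(self, "panel_shape", (int(rows), int(cols)))
        object.__setattr__(self, "beam_center",
                           (float(self.beam_center[0]), float(self.beam_center[1])))

    @property
    def wavelength_nm(self) -> float:
        return energy_to_wavelength(self.photon_energy_kev)


@dataclass
class PixelMap:
    """Per-pixel momentum-transfer vectors for one geometry.

    ``qvec`` has shape (rows, cols, 3) in nm^-1, ``qmag`` is its elementwise
    norm, and ``mask`` flags valid pixels.  The third q component points
    along the beam (zero for the flat-Ewald mapping).
    """

    qvec: np.ndarray
    qmag: np.ndarray
    mask: np.ndarray = field(default=None)
    geometry: DetectorGeometry = None

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.ones(self.qmag.shape, dtype=bool)

    @property
    def q_max(self) -> float:
        """Largest |q| over valid pixels."""
        return float(self.qmag[self.mask].max())


def build_pixel_map(geom: DetectorGeometry, mask=None, curved: bool = True) -> PixelMap:
    """Map every pixel of ``geom`` to a momentum-transfer vector.

    With ``curved=True`` (default) q vectors lie on the Ewald sphere through
    the origin: q = k (s_hat - z_hat) with k = 2 pi / lambda.  With
    ``curved=False`` the same |q| is assigned but projected into the qz = 0
    plane, so a diffraction frame samples a central planar cut of the 3D
    intensity.  Both mappings give |q| = (4 pi / lambda) sin(theta) exactly.
    """
    rows, cols = geom.panel_shape
    lam = geom.wavelength_nm
    k = 2.0 * np.pi / lam  # nm^-1
    pix_m = geom.pixel_size_um * 1e-6
    yy = (np.arange(rows)[:, None] - geom.beam_center[0]) * pix_m
    xx = (np.arange(cols)[None, :] - geom.beam_center[1]) * pix_m
    y = np.broadcast_to(yy, (rows, cols))
    x = np.broadcast_to(xx, (rows, cols))
    r = np.hypot(x, y)
    norm = np.sqrt(r * r + geom.distance_m ** 2)
    qvec = np.empty((rows, cols, 3), dtype=np.float64)
    if curved:
        qvec[..., 0] = k * y / norm
        qvec[..., 1] = k * x / norm
        qvec[..., 2] = k * (geom.distance_m / norm - 1.0)
    else:
        # same scattering magnitude, flattened onto the transverse plane
        two_theta = np.arctan2(r, geom.distance_m)
        qperp = 2.0 * k * np.sin(0.5 * two_theta)
        with np.errstate(invalid="ignore", divide="ignore"):
            uy = np.where(r > 0, y / r, 0.0)
            ux = np.where(r > 0, x / r, 0.0)
        qvec[..., 0] = qperp * uy
        qvec[..., 1] = qperp * ux
        qvec[..., 2] = 0.0
    qmag = np.linalg.norm(qvec, axis=-1)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (rows, cols):
            raise ValueError("mask shape does not match panel shape")
    return PixelMap(qvec=qvec, qmag=qmag, mask=mask, geometry=geom)
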