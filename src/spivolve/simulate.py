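"""Synthetic SPI data: virus-like phantoms and diffraction frame generation.

The generator emulates the statistical structure of an XFEL single-particle
imaging run on ~70 nm virus particles: a far-field diffraction volume from
a phantom (solid sphere or icosahedral shell with a thin dense capsid and
reduced interior), frames drawn at uniformly random orientations with
per-frame particle-size jitter, Poisson photon statistics, a constant
diffuse background, fixed per-pixel baseline offsets with Gaussian readout
noise, multi-particle frames built as incoherent sums, and a half-panel
detector mask.

It does not model atomistic structure, radiation damage, pulse-duration
effects or detector saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull

from .geometry import DetectorGeometry, build_pixel_map
from .gridtools import trilinear_gather
from .io import DensityField, IntensityVolume, PatternStack
from .rotation import quat_to_matrix, random_quaternions


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric phantom standing in for the imaged virus particle.

    ``outer_diameter_nm`` is vertex-to-vertex for the icosahedral shell.
    ``interior_fill`` is the interior density as a fraction of the shell
    density (viruses that released their genome show a reduced core).
    """

    shape: str = "icosahedral_shell"
    outer_diameter_nm: float = 70.0
    capsid_thickness_nm: float = 8.0
    interior_fill: float = 0.4

    def __post_init__(self):
        if self.shape not in ("sphere", "icosahedral_shell"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if not (self.outer_diameter_nm > 2.0 * self.capsid_thickness_nm > 0.0):
            raise ValueError("need outer_diameter > 2 * capsid_thickness > 0")
        if not 0.0 <= self.interior_fill <= 1.0:
            raise ValueError("interior_fill must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic run.

    ``fluence_scale`` is the expected photon count in the brightest
    (central-speckle) pixel of a noise-free single hit; the frame-to-frame
    intensity is proportional to the sliced diffraction volume.  Hit-type
    fractions must sum to one.  ``size_jitter_sd`` (nm) broadens the
    apparent particle size the way hydration-layer variation and beam-focus
    position do in the experiment.  ``pixel_offset_sd`` sets fixed per-pixel
    baseline offsets (instrumental background), ``readout_noise_sd`` the
    per-sample Gaussian detector noise around that baseline.
    """

    n_frames: int = 200
    fluence_scale: float = 2000.0
    size_jitter_sd: float = 3.0
    single_fraction: float = 0.8
    multi_fraction: float = 0.1
    blank_fraction: float = 0.1
    background_level: float = 0.05
    pixel_offset_sd: float = 0.1
    readout_noise_sd: float = 0.1
    particle_diameter_nm: float = 70.0
    poisson: bool = True
    seed: int = 0

    def __post_init__(self):
        fr = (self.single_fraction, self.multi_fraction, self.blank_fraction)
        if min(fr) < 0 or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("hit-type fractions must be >= 0 and sum to 1")
        for name in ("fluence_scale", "size_jitter_sd", "background_level",
                     "pixel_offset_sd", "readout_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# phantoms

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def icosahedron_geometry():
    """Unit-circumradius icosahedron: vertices (12, 3) and face planes.

    Returns (vertices, normals, plane_offset) with faces satisfying
    ``n . x <= plane_offset`` inside; ``plane_offset`` equals the inradius.
    """
    v = []
    for a in (-1.0, 1.0):
        for b in (-_GOLDEN, _GOLDEN):
            v += [(0, a, b), (a, b, 0), (b, 0, a)]
    verts = np.array(v) / np.sqrt(1.0 + _GOLDEN ** 2)
    hull = ConvexHull(verts)
    normals = hull.equations[:, :3]
    offsets = -hull.equations[:, 3]
    return verts, normals, float(offsets.mean())


def make_phantom(spec: PhantomSpec, grid_n: int, voxel_nm: float) -> DensityField:
    """Voxelize a phantom onto a cubic grid with partial-volume anti-aliasing.

    The particle must fit with at least 2x linear oversampling (field of
    view >= twice the outer diameter), which downstream phasing requires.
    """
    fov = grid_n * voxel_nm
    if fov < 2.0 * spec.outer_diameter_nm:
        raise ValueError(
            f"grid too small: field of view {fov:.1f} nm < 2x outer diameter")
    ax = (np.arange(grid_n) - grid_n // 2) * voxel_nm
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)

    def solid_fraction_sphere(radius):
        r = np.linalg.norm(pts, axis=-1)
        return np.clip(0.5 + (radius - r) / voxel_nm, 0.0, 1.0)

    def solid_fraction_icosa(circumradius):
        _, normals, inrad = icosahedron_geometry()
        # signed distance to the nearest face plane (exact near facets)
        sd = np.max(pts @ normals.T, axis=-1) - inrad * circumradius
        return np.clip(0.5 - sd / voxel_nm, 0.0, 1.0)

    r_out = spec.outer_diameter_nm / 2.0
    if spec.shape == "sphere":
        outer = solid_fraction_sphere(r_out)
        inner = solid_fraction_sphere(r_out - spec.capsid_thickness_nm)
    else:
        _, _, inrad_unit = icosahedron_geometry()
        outer = solid_fraction_icosa(r_out)
        # shrink so the inradius (facet distance) drops by the capsid thickness
        shrink = 1.0 - spec.capsid_thickness_nm / (inrad_unit * r_out)
        inner = solid_fraction_icosa(r_out * max(shrink, 0.0))
    density = outer - (1.0 - spec.interior_fill) * inner
    return DensityField(values=density, voxel_nm=voxel_nm)


# ---------------------------------------------------------------------------
# far-field intensity and frame sampling


def render_intensity(density: DensityField, oversampling: int = 2) -> IntensityVolume:
    """Far-field diffraction volume: |FFT|^2 of the zero-padded density.

    Zero-padding by ``oversampling`` refines the q grid; the origin voxel
    carries (sum density)^2.  The q step is 2*pi / (n_pad * voxel_nm).
    """
    if oversampling < 2:
        raise ValueError("oversampling must be >= 2")
    n = density.n
    n_pad = n * int(oversampling)
    pad = np.zeros((n_pad, n_pad, n_pad))
    lo = (n_pad - n) // 2
    pad[lo:lo + n, lo:lo + n, lo:lo + n] = density.values.real
    f = np.fft.fftn(np.fft.ifftshift(pad))
    intensity = np.fft.fftshift(np.abs(f) ** 2)
    voxel_q = 2.0 * np.pi / (n_pad * density.voxel_nm)
    return IntensityVolume(values=intensity, voxel_q=voxel_q)


def _slice_expected(volume: IntensityVolume, qvec_flat: np.ndarray,
                    rot_matrix: np.ndarray, scale: float) -> np.ndarray:
    """Expected (relative) intensity on detector pixels for one orientation."""
    coords = (qvec_flat @ rot_matrix.T) * scale / volume.voxel_q + volume.center
    return trilinear_gather(volume.values, coords)


def sample_patterns(volume: IntensityVolume, geom: DetectorGeometry,
                    cfg: SimConfig, curved: bool = True) -> PatternStack:
    """Draw diffraction frames at uniformly random orientations.

    Expected counts are ``fluence_scale`` times the interpolated Ewald
    slice through the diffraction volume, normalized to the volume maximum;
    counts are Poisson unless ``cfg.poisson`` is off.  Blank frames carry no
    particle signal.  Truth orientation, apparent size and hit type are
    recorded in the annotations.  All randomness flows from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    pm = build_pixel_map(geom, curved=curved)
    q_flat = pm.qvec.reshape(-1, 3)
    d0 = cfg.particle_diameter_nm
    jitter_frac = cfg.size_jitter_sd / d0 if d0 > 0 else 0.0
    q_need = pm.qmag.max() * (1.0 + 3.5 * jitter_frac)
    q_have = volume.voxel_q * (volume.center - 1)
    if q_have < q_need:
        raise ValueError(
            f"volume q-extent {q_have:.3f} nm^-1 below detector need {q_need:.3f}")
    peak = volume.values.max()
    shape = geom.panel_shape
    counts = np.zeros((cfg.n_frames,) + tuple(shape))
    quats = np.zeros((cfg.n_frames, 4))
    quats[:, 0] = 1.0
    sizes = np.full(cfg.n_frames, d0)
    types = np.array(["blank"] * cfg.n_frames, dtype="U6")
    is_blank = rng.random(cfg.n_frames) < cfg.blank_fraction
    for i in range(cfg.n_frames):
        if is_blank[i]:
            sizes[i] = 0.0
            continue
        types[i] = "single"
        quats[i] = random_quaternions(1, rng)[0]
        # size jitter truncated at 3.5 sigma (keeps sampled q inside the volume)
        s = 1.0 + rng.normal(0.0, jitter_frac) if jitter_frac > 0 else 1.0
        s = float(np.clip(s, max(1.0 - 3.5 * jitter_frac, 0.2),
                          1.0 + 3.5 * jitter_frac))
        sizes[i] = d0 * s
        # a particle scaled by s in real space scales its transform by 1/s:
        # sample the reference volume at q * s
        expected = _slice_expected(volume, q_flat, quat_to_matrix(quats[i]), s)
        expected = cfg.fluence_scale * expected / peak
        frame = rng.poisson(expected) if cfg.poisson else expected
        counts[i] = frame.reshape(shape)
    ann = {"true_quat": quats, "size_nm": sizes, "hit_type": types}
    return PatternStack(counts=counts, geometry=geom, annotations=ann)


def corrupt_stack(stack: PatternStack, cfg: SimConfig,
                  mask: np.ndarray = None) -> PatternStack:
    """Add instrumental corruption to a clean stack.

    Converts a ``multi_fraction`` share of non-blank frames into
    multi-particle hits by incoherently summing 1-2 other non-blank frames,
    then adds a constant Poisson background, fixed per-pixel Gaussian
    baseline offsets (sd ``pixel_offset_sd``) with per-sample readout noise,
    and applies the detector mask (masked pixels zeroed).  Deterministic
    given ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 0xC0FFEE])
    out = stack.copy()
    counts = out.counts.astype(np.float64)
    types = out.annotations.get(
        "hit_type", np.array(["single"] * out.n_frames, dtype="U6")).copy()
    nonblank = np.flatnonzero(types != "blank")
    denom = cfg.single_fraction + cfg.multi_fraction
    multi_share = cfg.multi_fraction / denom if denom > 0 else 0.0
    if multi_share > 0 and len(nonblank) > 1:
        n_multi = int(round(multi_share * len(nonblank)))
        multi_idx = rng.choice(nonblank, size=n_multi, replace=False)
        for i in multi_idx:
            others = nonblank[nonblank != i]
            extra = rng.choice(others, size=rng.integers(1, 3), replace=False)
            counts[i] = counts[i] + counts[extra].sum(axis=0)
            types[i] = "multi"
    if cfg.background_level > 0:
        counts += rng.poisson(cfg.background_level, size=counts.shape)
    if cfg.pixel_offset_sd > 0 or cfg.readout_noise_sd > 0:
        offsets = rng.normal(0.0, cfg.pixel_offset_sd, size=counts.shape[1:])
        counts += offsets[None]
        if cfg.readout_noise_sd > 0:
            counts += rng.normal(0.0, cfg.readout_noise_sd, size=counts.shape)
        # ground-truth baseline map, attached for simulation studies only
        out.pixel_offset_truth = offsets
    if mask is not None:
        out.mask = np.asarray(mask, dtype=bool)
    counts[:, ~out.mask] = 0.0
    out.counts = counts
    out.annotations["hit_type"] = types
    return out


def half_panel_mask(panel_shape, dead: str = "bottom") -> np.ndarray:
    """Mask emulating a dead detector half (rows masked invalid)."""
    rows, cols = panel_shape
    mask = np.ones((rows, cols), dtype=bool)
    if dead == "bottom":
        mask[rows // 2:] = False
    elif dead == "top":
        mask[: rows // 2] = False
    else:
        raise ValueError("dead must be 'bottom' or 'top'")
    return mask


def central_mask(pixel_map, q_min: float) -> np.ndarray:
    """Mask out the central region |q| < q_min (beamstop / saturation)."""
    return pixel_map.qmag >= q_min
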