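"""Shared fixtures: small geometries and pre-rendered diffraction volumes.

Session-scoped fixtures hold the expensive renders so unit and
integration tests share one copy.
"""

import numpy as np
import pytest

from spivolve.geometry import DetectorGeometry, build_pixel_map
from spivolve.simulate import PhantomSpec, make_phantom, render_intensity


@pytest.fixture(scope="session")
def wide_geometry():
    """128 x 256 panel at 0.075 m: q to ~1.1 nm^-1 at the long edge."""
    return DetectorGeometry(distance_m=0.075, pixel_size_um=75.0,
                            panel_shape=(128, 256), beam_center=(64.0, 128.0),
                            photon_energy_kev=1.7)


@pytest.fixture(scope="session")
def wide_pixel_map(wide_geometry):
    return build_pixel_map(wide_geometry)


@pytest.fixture(scope="session")
def square_geometry():
    """Centered square panel (full azimuth coverage) for classification."""
    return DetectorGeometry(distance_m=0.075, pixel_size_um=75.0,
                            panel_shape=(128, 128), beam_center=(63.5, 63.5),
                            photon_energy_kev=1.7)


@pytest.fixture(scope="session")
def binned_geometry():
    """2x2-binned square panel: same q coverage, 4x fewer pixels."""
    return DetectorGeometry(distance_m=0.075, pixel_size_um=150.0,
                            panel_shape=(64, 64), beam_center=(31.5, 31.5),
                            photon_energy_kev=1.7)


@pytest.fixture(scope="session")
def sphere70_phantom():
    return make_phantom(PhantomSpec("sphere", 70.0, 8.0, 1.0), 72, 2.0)


@pytest.fixture(scope="session")
def sphere70_volume(sphere70_phantom):
    """Finely sampled diffraction volume of a 70 nm solid sphere."""
    return render_intensity(sphere70_phantom, 4)


@pytest.fixture(scope="session")
def icosa70_phantom():
    return make_phantom(
        PhantomSpec("icosahedral_shell", 70.0, 8.0, 0.4), 72, 2.0)


@pytest.fixture(scope="session")
def icosa70_volume(icosa70_phantom):
    return render_intensity(icosa70_phantom, 4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dumbbell_volume():
    """Asymmetric two-sphere phantom: orientation recovery is non-trivial."""
    from spivolve.io import DensityField
    n, vox = 72, 2.0
    ax = (np.arange(n) - n // 2) * vox
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    r1 = np.sqrt((zz - 18) ** 2 + yy ** 2 + xx ** 2)
    r2 = np.sqrt((zz + 14) ** 2 + yy ** 2 + xx ** 2)
    dens = np.clip(0.5 + (16 - r1) / vox, 0, 1) \
        + np.clip(0.5 + (22 - r2) / vox, 0, 1)
    return render_intensity(DensityField(dens, vox), 4)


@pytest.fixture(scope="session")
def emc_run(dumbbell_volume, binned_geometry):
    """Seeded EMC reconstruction from 400 noise-free frames (64-cube)."""
    from spivolve.emc3d import EMC3DConfig, emc_reconstruct
    from spivolve.geometry import build_pixel_map
    from spivolve.rotation import make_rotation_samples
    from spivolve.simulate import SimConfig, sample_patterns
    pm = build_pixel_map(binned_geometry)
    cfg = SimConfig(n_frames=400, fluence_scale=400.0, size_jitter_sd=0.0,
                    single_fraction=1.0, multi_fraction=0.0,
                    blank_fraction=0.0, seed=21, poisson=False)
    stack = sample_patterns(dumbbell_volume, binned_geometry, cfg)
    rot = make_rotation_samples(500)
    res = emc_reconstruct(stack, pm, rot, n_iter=14,
                          cfg=EMC3DConfig(grid_n=64, seed=2))
    return stack, pm, rot, res
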