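"""Iterative phase retrieval: central-gap filling, HIO/ER with shrink-wrap
support, Richardson-Lucy contrast enhancement, and multi-start ensembles.

The measured quantity is the 3D intensity on valid voxels; its square root
constrains Fourier magnitudes while invalid voxels (the trimmed central
gap and out-of-band regions) evolve freely.  Real-space constraints are a
finite support, re-estimated periodically by blurring the current modulus
and thresholding at a fraction of its maximum (shrink-wrap).  The complex
field is not forced real or positive, matching the usual practice for
partially coherent single-particle data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import IntensityVolume


@dataclass
class PhasingSchedule:
    """Algorithm interleaving and support handling for one retrieval."""

    steps: tuple = (("HIO", 150), ("ER", 50))
    hio_beta: float = 0.9
    shrinkwrap_interval: int = 20
    shrinkwrap_sigma: float = 1.5      # voxels
    shrinkwrap_threshold: float = 0.2  # fraction of blurred maximum
    initial_support_radius: float = 0.3  # fraction of grid edge
    real_positive: bool = False        # constrain the object real, >= 0
    seed: int = 0

    def __post_init__(self):
        for name, it in self.steps:
            if name not in ("HIO", "ER"):
                raise ValueError(f"unknown algorithm {name!r}")
            if it < 1:
                raise ValueError("iterations per step must be >= 1")
        if not 0.0 < self.shrinkwrap_threshold < 1.0:
            raise ValueError("shrinkwrap threshold must be in (0, 1)")


@dataclass
class ReconstructionSet:
    """Aligned ensemble of complex real-space reconstructions."""

    fields: list                      # complex (n, n, n) arrays, common grid
    error_metrics: np.ndarray         # normalized Fourier residual per run
    voxel_nm: float
    aligned: bool = False


def _ball_support(n: int, radius_frac: float) -> np.ndarray:
    ax = np.arange(n) - n // 2
    r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                + ax[None, None, :] ** 2)
    return r <= radius_frac * n


def _fourier_residual(f_hat, amp, valid):
    num = np.sum((np.abs(f_hat[valid]) - amp[valid]) ** 2)
    den = np.sum(amp[valid] ** 2)
    return float(np.sqrt(num / max(den, 1e-300)))


def phase_retrieval(volume: IntensityVolume, schedule: PhasingSchedule = None,
                    initial_support: np.ndarray = None,
                    initial_field: np.ndarray = None,
                    track_residual: bool = False):
    """Run one HIO/ER/shrink-wrap phase retrieval.

    Returns ``(field, residual)`` — the final complex real-space field
    (centered grid) and the normalized Fourier-magnitude residual over
    valid voxels.  With ``track_residual`` a per-iteration residual list is
    appended to the return tuple.  A run whose residual exceeds 10x its
    initial value is flagged by a RuntimeWarning but still returned.
    """
    if schedule is None:
        schedule = PhasingSchedule()
    n = volume.n
    amp = np.sqrt(np.maximum(volume.values, 0.0))
    valid = volume.valid
    support = (initial_support.astype(bool) if initial_support is not None
               else _ball_support(n, schedule.initial_support_radius))
    rng = np.random.default_rng(schedule.seed)
    if initial_field is None:
        # random phases on the measured magnitudes
        phases = rng.uniform(0, 2 * np.pi, size=amp.shape)
        f_hat = np.where(valid, amp * np.exp(1j * phases), 0.0)
        g = _ifft_centered(f_hat)
    else:
        g = initial_field.astype(np.complex128)
    residuals = []
    it_global = 0
    first_residual = None
    for algo, n_it in schedule.steps:
        for _ in range(n_it):
            f_hat = _fft_centered(g)
            res = _fourier_residual(f_hat, amp, valid)
            residuals.append(res)
            # reference residual taken after the first real-space projection
            # (the very first one is ~0 by construction of the start field)
            if first_residual is None and it_global == 1:
                first_residual = res
            f_proj = np.where(valid,
                              amp * np.exp(1j * np.angle(f_hat)), f_hat)
            g_proj = _ifft_centered(f_proj)
            if schedule.real_positive:
                ok = support & (g_proj.real > 0)
                inside = g_proj.real.astype(np.complex128)
            else:
                ok = support
                inside = g_proj
            if algo == "ER":
                g = np.where(ok, inside, 0.0)
            else:
                g = np.where(ok, inside, g - schedule.hio_beta * g_proj)
            it_global += 1
            if schedule.shrinkwrap_interval and \
                    it_global % schedule.shrinkwrap_interval == 0:
                blur = gaussian_filter(np.abs(g_proj), schedule.shrinkwrap_sigma)
                support = blur >= schedule.shrinkwrap_threshold * blur.max()
    f_hat = _fft_centered(g)
    final_res = _fourier_residual(f_hat, amp, valid)
    if first_residual and final_res > 10 * first_residual:
        import warnings
        warnings.warn("phase retrieval diverged (residual grew > 10x)")
    out = (g, final_res)
    return out + (residuals,) if track_residual else out


def _fft_centered(g):
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(g)))


def _ifft_centered(f_hat):
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(f_hat)))


def fill_central_gap(volume: IntensityVolume, n_runs: int = 5,
                     schedule: PhasingSchedule = None) -> IntensityVolume:
    """Fill the invalid central region with model intensities.

    Runs ``n_runs`` seeded phase retrievals in which invalid voxels evolve
    freely, then replaces the central invalid connected component by the
    mean of the runs' model intensities |F|^2 there.  Valid voxels are
    untouched.  Returns the input unchanged (a copy) if nothing is
    invalid.
    """
    if schedule is None:
        schedule = PhasingSchedule()
    out = volume.copy()
    gap = central_gap_mask(volume)
    if not gap.any():
        return out
    acc = np.zeros(volume.values.shape)
    for run in range(n_runs):
        sched = PhasingSchedule(**{**schedule.__dict__,
                                   "seed": schedule.seed + 7919 * run})
        g, _ = phase_retrieval(volume, sched)
        model_i = np.abs(_fft_centered(g)) ** 2
        acc += model_i
    out.values[gap] = acc[gap] / n_runs
    out.valid |= gap
    return out


def central_gap_mask(volume: IntensityVolume) -> np.ndarray:
    """Invalid voxels inside the innermost valid shell (the central gap).

    The trimmed low-q region is a ball of invalid voxels surrounded by
    measured data; everything invalid beyond the innermost valid |q| (the
    out-of-band exterior) is left free and is NOT part of the gap.
    """
    if volume.valid.all():
        return np.zeros(volume.values.shape, dtype=bool)
    if not volume.valid.any():
        raise ValueError("volume has no valid voxels")
    qmag = volume.qmag_grid()
    q_inner = qmag[volume.valid].min()
    return (~volume.valid) & (qmag < q_inner)


def fill_gap_form_factor(volume: IntensityVolume, diameter_nm: float) -> IntensityVolume:
    """Fill the central gap with a solid-sphere form-factor extrapolation.

    At momentum transfers inside the central speckle a compact particle's
    intensity is well approximated by the form factor of its equivalent
    sphere; the fitted particle diameter from the sizing stage anchors the
    shape and the level is matched to the innermost measured shell.  This
    removes the free-evolution ambiguity of the unconstrained gap (the
    total-density term is otherwise undetermined).  Voxels outside the gap
    are untouched.
    """
    from .sizing import sphere_form_factor_psd
    out = volume.copy()
    gap = central_gap_mask(volume)
    if not gap.any():
        return out
    qmag = volume.qmag_grid()
    q_inner = qmag[volume.valid].min()
    # level match on the innermost measured shell
    shell = volume.valid & (qmag < q_inner + 2.0 * volume.voxel_q)
    ff_shell = sphere_form_factor_psd(qmag[shell], diameter_nm)
    level = volume.values[shell].mean() / max(ff_shell.mean(), 1e-300)
    out.values[gap] = level * sphere_form_factor_psd(qmag[gap], diameter_nm)
    out.valid |= gap
    return out


def gap_fill_models(volume: IntensityVolume, n_runs: int,
                    schedule: PhasingSchedule = None):
    """Per-run model intensities over the central gap (diagnostics)."""
    if schedule is None:
        schedule = PhasingSchedule()
    gap = central_gap_mask(volume)
    models = []
    for run in range(n_runs):
        sched = PhasingSchedule(**{**schedule.__dict__,
                                   "seed": schedule.seed + 7919 * run})
        g, _ = phase_retrieval(volume, sched)
        models.append(np.abs(_fft_centered(g))[gap] ** 2)
    return gap, models


def richardson_lucy_enhance(data: np.ndarray, kernel_sigma: float,
                            n_iter: int = 50, eps: float = 1e-12) -> np.ndarray:
    """Richardson-Lucy deconvolution with an isotropic Gaussian kernel.

    Multiplicative updates preserve non-negativity and (with the periodic
    kernel used here) total intensity to numerical precision.  Works on
    profiles (1D) or volumes (3D).
    """
    if kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be positive")
    d = np.asarray(data, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("input must be non-negative")
    u = d.copy()

    def blur(x):
        return gaussian_filter(x, kernel_sigma, mode="wrap")

    for _ in range(n_iter):
        conv = blur(u)
        ratio = d / np.maximum(conv, eps)
        u = u * blur(ratio)
    return u


def enhance_contrast_rl(psd_value: np.ndarray, n_iter: int = 50,
                        sigma_grid=(0.5, 1.0, 1.5, 2.0, 3.0), n_pairs: int = 6):
    """Deconvolve a PSD profile, choosing the kernel width that maximizes
    the average fringe visibility; returns (enhanced, ContrastReport, sigma)."""
    from .background import fringe_contrast
    from .sizing import PSDProfile

    best = None
    q_dummy = np.arange(len(psd_value), dtype=float) + 0.5
    for sigma in sigma_grid:
        enhanced = richardson_lucy_enhance(psd_value, sigma, n_iter=n_iter)
        try:
            rep = fringe_contrast(PSDProfile(q_centers=q_dummy, value=enhanced,
                                             n_pixels=np.ones(len(enhanced), int)),
                                  n_pairs=n_pairs)
        except ValueError:
            continue
        if best is None or rep.gamma_mean > best[1].gamma_mean:
            best = (enhanced, rep, sigma)
    if best is None:
        raise ValueError("no kernel width produced the requested fringe pairs")
    return best


def run_multistart(volume: IntensityVolume, schedule: PhasingSchedule = None,
                   n: int = 50, voxel_nm: float = None) -> ReconstructionSet:
    """Run ``n`` independently seeded retrievals and align the ensemble.

    Trivial ambiguities are resolved against the first field: the
    conjugate-inversion twin is chosen to maximize correlation, the
    integer-voxel translation comes from cross-correlation, and the global
    phase from the inner product.
    """
    if schedule is None:
        schedule = PhasingSchedule()
    if voxel_nm is None:
        voxel_nm = 2.0 * np.pi / (volume.n * volume.voxel_q)
    fields = []
    errors = []
    for run in range(n):
        sched = PhasingSchedule(**{**schedule.__dict__,
                                   "seed": schedule.seed + 104729 * run})
        g, res = phase_retrieval(volume, sched)
        fields.append(g)
        errors.append(res)
    aligned = align_fields(fields, ref_index=int(np.argmin(errors)))
    return ReconstructionSet(fields=aligned, error_metrics=np.array(errors),
                             voxel_nm=voxel_nm, aligned=True)


def anchored_multistart(volume: IntensityVolume, schedule: PhasingSchedule,
                        diameter_nm: float, n_stage_a: int = 6, n: int = 8,
                        two_stage: bool = True):
    """Multi-start retrieval with a stabilized central gap.

    The central gap is first filled with the sphere-form-factor
    extrapolation anchored by the fitted particle diameter (pinning the
    otherwise-free total-density term), a first ensemble is phased, and
    the gap is then re-filled from that ensemble's mean model intensity —
    restoring the particle's own (non-spherical) speckle — before the
    final ensemble runs.  Returns (ReconstructionSet, constrained volume).
    """
    gap = central_gap_mask(volume)
    if not gap.any():
        stage_b = volume.copy()
        return run_multistart(stage_b, schedule, n=n), stage_b
    filled = fill_gap_form_factor(volume, diameter_nm)
    if two_stage:
        recon_a = run_multistart(filled, schedule, n=n_stage_a)
        acc = np.zeros(volume.values.shape)
        for f in recon_a.fields:
            acc += np.abs(_fft_centered(f)) ** 2
        stage_b = volume.copy()
        stage_b.values[gap] = acc[gap] / len(recon_a.fields)
        stage_b.valid |= gap
    else:
        stage_b = filled
    sched2 = PhasingSchedule(**{**schedule.__dict__,
                                "seed": schedule.seed + 5000})
    return run_multistart(stage_b, sched2, n=n), stage_b


def align_fields(fields, ref_index: int = 0):
    """Resolve global phase, sub-voxel shift and twin against a reference
    field (the lowest-residual run when called from run_multistart)."""
    ref = fields[ref_index]
    out = []
    for i, f in enumerate(fields):
        out.append(ref.copy() if i == ref_index else _align_pair(ref, f))
    return out


def _subpixel_shift(field, shift):
    """Shift a complex field by a (possibly fractional) vector, periodic."""
    n = field.shape
    f_hat = np.fft.fftn(field)
    for ax in range(3):
        k = np.fft.fftfreq(n[ax])
        ramp = np.exp(-2j * np.pi * k * shift[ax])
        shape = [1, 1, 1]
        shape[ax] = n[ax]
        f_hat *= ramp.reshape(shape)
    return np.fft.ifftn(f_hat)


def _align_pair(ref, f):
    from skimage.registration import phase_cross_correlation
    best = None
    for cand in (f, np.conj(f[::-1, ::-1, ::-1])):
        # translation from modulus cross-correlation, to sub-voxel precision
        shift, _, _ = phase_cross_correlation(np.abs(ref), np.abs(cand),
                                              upsample_factor=20,
                                              normalization=None)
        shifted = _subpixel_shift(cand, shift)
        ip = np.vdot(shifted, ref)
        phase = ip / max(abs(ip), 1e-300)
        shifted = shifted * phase
        score = abs(ip) / max(np.linalg.norm(shifted) * np.linalg.norm(ref), 1e-300)
        if best is None or score > best[0]:
            best = (score, shifted)
    return best[1]


def complex_correlation(a, b) -> float:
    """|<a, b>| / (|a| |b|) — magnitude of the normalized inner product."""
    return float(abs(np.vdot(a, b))
                 / max(np.linalg.norm(a) * np.linalg.norm(b), 1e-300))
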