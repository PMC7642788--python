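"""Unsupervised EM clustering of diffraction patterns over classes and
in-plane rotations, with repeated runs and intersection-based selection.

Frames are resampled onto a polar grid about the beam center so that an
in-plane rotation becomes a cyclic shift of the angle axis — the rotation
group acts exactly on the sampling grid and the E-step reduces to matrix
products.  The likelihood is Poisson per polar pixel, as in
orientation-recovery EM, but with in-plane rotation and class assignment
as the latent variables instead of a 3D orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.special import logsumexp

from .io import PatternStack

_W_FLOOR = 1e-10  # additive floor on class models inside logs


@dataclass(frozen=True)
class EMConfig:
    """Settings for one EM clustering run."""

    n_classes: int = 20
    n_rotations: int = 36     # in-plane angle grid (= polar angle bins)
    max_iter: int = 60
    tol: float = 1e-4         # relative log-likelihood change
    seed: int = 0
    n_radial: int = None      # polar radius bins (default: 1 px spacing)
    r_min_px: float = 4.0
    r_max_px: float = None    # default: largest radius inside the panel

    def __post_init__(self):
        if self.n_classes < 1 or self.n_rotations < 1:
            raise ValueError("n_classes and n_rotations must be >= 1")


@dataclass
class ClusterModel:
    """Converged class models on the polar grid (expected photons/pixel)."""

    class_images: np.ndarray   # (K, n_ang, n_rad)
    occupancy: np.ndarray      # (K,), sums to 1
    loglik_trace: list
    r_centers: np.ndarray = None
    polar_mask: np.ndarray = None


def polar_coordinates(center, n_ang: int, n_rad: int, r_min: float, r_max: float):
    """Sampling coordinates (2, n_ang, n_rad) for a polar grid."""
    ang = np.arange(n_ang) * (2.0 * np.pi / n_ang)
    rad = np.linspace(r_min, r_max, n_rad)
    rr = rad[None, :]
    aa = ang[:, None]
    rows = center[0] + rr * np.sin(aa)
    cols = center[1] + rr * np.cos(aa)
    return np.stack([np.broadcast_to(rows, (n_ang, n_rad)),
                     np.broadcast_to(cols, (n_ang, n_rad))]), rad


def polar_resample(images: np.ndarray, mask: np.ndarray, center,
                   n_ang: int, n_rad: int, r_min: float, r_max: float):
    """Bilinear polar resampling of frames and (conservative) mask."""
    coords, rad = polar_coordinates(center, n_ang, n_rad, r_min, r_max)
    single = images.ndim == 2
    stackd = images[None] if single else images
    out = np.stack([map_coordinates(f.astype(np.float64), coords, order=1,
                                    mode="constant", cval=0.0) for f in stackd])
    m = map_coordinates(mask.astype(np.float64), coords, order=1,
                        mode="constant", cval=0.0) > 0.99
    rows, cols = mask.shape
    inside = (coords[0] >= 0) & (coords[0] <= rows - 1) \
        & (coords[1] >= 0) & (coords[1] <= cols - 1)
    m &= inside
    return (out[0] if single else out), m, rad


def _prepare_polar(stack: PatternStack, cfg: EMConfig):
    center = stack.geometry.beam_center
    rows, cols = stack.geometry.panel_shape
    r_max = cfg.r_max_px
    if r_max is None:
        r_max = max(np.hypot(rows - 1 - center[0], cols - 1 - center[1]),
                    np.hypot(center[0], center[1]))
    n_rad = cfg.n_radial or max(int(r_max - cfg.r_min_px), 8)
    data, pmask, rad = polar_resample(stack.counts, stack.mask, center,
                                      cfg.n_rotations, n_rad,
                                      cfg.r_min_px, r_max)
    return data, pmask, rad


def em_cluster_polar(data: np.ndarray, pmask: np.ndarray, cfg: EMConfig):
    """EM over (class, in-plane rotation) on polar-resampled frames.

    ``data`` is (frames, n_ang, n_rad); rotation by one grid step is a
    cyclic shift of axis 1.  Returns (class models, occupancy, trace,
    responsibilities (frames, K, n_ang)).
    """
    n_f, n_ang, n_rad = data.shape
    k = cfg.n_classes
    if k > n_f:
        raise ValueError("more classes than frames")
    p = n_ang * n_rad
    m = pmask.reshape(p).astype(np.float64)
    frame_ok = np.ones(n_f, dtype=bool)
    flat = data.reshape(n_f, p) * m[None]
    if not pmask.any():
        raise ValueError("all polar pixels masked")
    dead = ~np.isfinite(flat).all(axis=1)
    if dead.any():
        warnings.warn(f"dropping {dead.sum()} non-finite frames")
        frame_ok &= ~dead
        flat = flat[frame_ok]
        n_f = flat.shape[0]

    rng = np.random.default_rng(cfg.seed)
    mean_img = flat.mean(axis=0)
    w = mean_img[None] * rng.uniform(0.5, 1.5, size=(k, p))
    w = np.maximum(w, _W_FLOOR)
    occ = np.full(k, 1.0 / k)
    trace = []
    resp = None
    log_rot_prior = -np.log(n_ang)
    for it in range(cfg.max_iter):
        # build all rotated models: (k, n_ang shifts, p)
        wk = w.reshape(k, n_ang, n_rad)
        rot = np.stack([np.roll(wk, s, axis=1).reshape(k, p)
                        for s in range(n_ang)], axis=1)  # (k, S, p)
        rot_m = rot * m[None, None]
        logw = np.where(m[None, None] > 0, np.log(np.maximum(rot, _W_FLOOR)), 0.0)
        sum_w = rot_m.sum(axis=2)                        # (k, S)
        ll = flat @ logw.reshape(k * n_ang, p).T - sum_w.reshape(-1)[None]
        ll = ll.reshape(n_f, k, n_ang)
        ll += np.log(occ)[None, :, None] + log_rot_prior
        norm = logsumexp(ll.reshape(n_f, -1), axis=1)
        trace.append(float(norm.sum()))
        resp = np.exp(ll - norm[:, None, None])
        # M-step
        num = np.zeros((k, n_ang, n_rad))
        den = np.zeros((k, n_ang, n_rad))
        mm = m.reshape(n_ang, n_rad)
        for s in range(n_ang):
            a_s = resp[:, :, s].T @ flat                 # (k, p)
            num += np.roll(a_s.reshape(k, n_ang, n_rad), -s, axis=1)
            den += resp[:, :, s].sum(axis=0)[:, None, None] \
                * np.roll(mm, -s, axis=0)[None]
        w = np.where(den > 1e-12, num / np.maximum(den, 1e-12),
                     mean_img.reshape(n_ang, n_rad)[None])
        w = np.maximum(w.reshape(k, p), _W_FLOOR)
        occ = resp.sum(axis=(0, 2)) / n_f
        occ = np.maximum(occ, 1e-12)
        occ /= occ.sum()
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-30)
            if rel < cfg.tol:
                break
    return w.reshape(k, n_ang, n_rad), occ, trace, resp


def em_cluster(stack: PatternStack, cfg: EMConfig):
    """Cluster a stack; returns (ClusterModel, responsibilities (F, K, S))."""
    data, pmask, rad = _prepare_polar(stack, cfg)
    w, occ, trace, resp = em_cluster_polar(data, pmask, cfg)
    model = ClusterModel(class_images=w, occupancy=occ, loglik_trace=trace,
                         r_centers=rad, polar_mask=pmask)
    return model, resp


def hard_assignments(resp: np.ndarray) -> np.ndarray:
    """Max-responsibility class per frame; ties broken by lowest class id."""
    per_class = resp.sum(axis=2)
    return per_class.argmax(axis=1)


def select_classes(model: ClusterModel, rule="auto", min_fringes: int = 3,
                   min_gamma: float = 0.2):
    """Class ids to keep.

    An explicit iterable of ids is returned as-is (the expert-selection
    path).  ``rule="auto"`` applies a heuristic NOT taken from any
    reference procedure: a class is proposed when the radial profile of
    its model shows at least ``min_fringes`` fringe pairs with visibility
    >= ``min_gamma`` — i.e. the class image looks like a fringed
    single-particle pattern rather than diffuse background.
    """
    if rule != "auto":
        ids = set(int(i) for i in rule)
        if not ids:
            warnings.warn("empty class selection")
        return ids
    from .background import fringe_contrast
    from .sizing import PSDProfile
    ids = set()
    for kid, img in enumerate(model.class_images):
        mask = model.polar_mask
        with np.errstate(invalid="ignore"):
            prof = np.where(mask.any(axis=0),
                            np.nansum(np.where(mask, img, np.nan), axis=0)
                            / np.maximum(mask.sum(axis=0), 1), np.nan)
        ok = np.isfinite(prof)
        if ok.sum() < 8:
            continue
        psd = PSDProfile(q_centers=model.r_centers[ok], value=prof[ok],
                         n_pixels=np.ones(ok.sum(), dtype=int))
        try:
            rep = fringe_contrast(psd, n_pairs=min_fringes)
        except ValueError:
            continue
        if np.all(rep.gamma_i >= min_gamma):
            ids.add(kid)
    if not ids:
        warnings.warn("auto rule selected no classes")
    return ids


def frames_for_classes(stack: PatternStack, resp: np.ndarray, class_ids):
    """Frame ids whose max-responsibility class is in ``class_ids``."""
    hard = hard_assignments(resp)
    keep = np.isin(hard, list(class_ids))
    return set(int(i) for i in stack.frame_id[keep])


def stable_intersection(stack: PatternStack, cfg: EMConfig, n_runs: int = 5,
                        per_run_selection="auto", return_report: bool = False):
    """Intersect the selections of ``n_runs`` independently seeded runs.

    ``per_run_selection`` is either "auto", an explicit iterable of class
    ids applied to every run, or a callable (model, resp) -> class id set.
    Returns the frame-id intersection (and per-run accounting when
    ``return_report``).
    """
    selections = []
    sizes = []
    for run in range(n_runs):
        run_cfg = EMConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * run})
        model, resp = em_cluster(stack, run_cfg)
        if callable(per_run_selection):
            ids = per_run_selection(model, resp)
        else:
            ids = select_classes(model, rule=per_run_selection)
        frames = frames_for_classes(stack, resp, ids)
        selections.append(frames)
        sizes.append(len(frames))
    stable = set.intersection(*selections) if selections else set()
    report = {"per_run_sizes": sizes, "intersection_size": len(stable),
              "n_runs": n_runs}
    return (stable, report) if return_report else stable
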