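"""Expand-maximize-compress (EMC) assembly of 2D diffraction patterns of
unknown orientation into a 3D reciprocal-space intensity.

Each iteration: Expand extracts model slices on the Ewald surface at every
rotation sample (trilinear interpolation); Maximize computes per-frame
Poisson posteriors over rotations and accumulates posterior-weighted
photons per rotation; Compress scatters the accumulated tomograms back
into the 3D grid with the adjoint trilinear weights and re-normalizes.
Friedel symmetry is imposed after every compress.  All randomness (the
positive random initial model) flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .geometry import PixelMap
from .gridtools import gather_cached, precompute_weights
from .io import IntensityVolume, PatternStack
from .rotation import RotationSet

_W_FLOOR = 1e-10


@dataclass(frozen=True)
class EMC3DConfig:
    grid_n: int = 64
    voxel_q: float = None      # nm^-1 per voxel; default fits the detector
    seed: int = 0
    friedel: bool = True
    min_voxel_weight: float = 1e-6


@dataclass
class EMCResult:
    volume: IntensityVolume
    posteriors: np.ndarray         # (frames, rotations), final iteration
    rotations: RotationSet
    loglik_trace: list
    info_trace: list               # mutual-information diagnostic per iter


def _default_voxel_q(pixel_map: PixelMap, grid_n: int) -> float:
    return float(pixel_map.q_max / (grid_n // 2 - 1.5))


def emc_reconstruct(stack: PatternStack, pixel_map: PixelMap,
                    rotations: RotationSet, n_iter: int = 20,
                    cfg: EMC3DConfig = None,
                    initial_model: np.ndarray = None) -> EMCResult:
    """Run EMC on a classified single-hit stack.

    Masked pixels are excluded from likelihoods and insertion.  Voxels
    that never receive interpolation weight are flagged invalid.  The
    returned posteriors are over the provided rotation samples.
    ``initial_model`` warm-starts the intensity grid (used for annealed
    coarse-to-fine rotation refinement); by default the model starts from
    seeded positive noise.
    """
    if cfg is None:
        cfg = EMC3DConfig()
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    n = cfg.grid_n
    mask = stack.mask & pixel_map.mask
    voxel_q = cfg.voxel_q or _default_voxel_q(pixel_map, n)
    qvec = pixel_map.qvec[mask]                      # (P, 3)
    if qvec.shape[0] == 0:
        raise ValueError("no valid pixels")
    if np.linalg.norm(qvec, axis=1).max() / voxel_q > n // 2 - 1:
        raise ValueError("volume q-extent insufficient for the detector")
    counts = stack.counts[:, mask].astype(np.float64)  # (F, P)
    n_rot = len(rotations)
    mats = rotations.matrices()
    center = n // 2

    chunk = max(1, int(2e6 // max(qvec.shape[0], 1)))

    def weight_chunks():
        # trilinear corner indices/weights, recomputed per sweep in chunks
        # to keep the memory footprint bounded for dense rotation sampling
        for r0 in range(0, n_rot, chunk):
            r1 = min(r0 + chunk, n_rot)
            coords = np.einsum("rij,pj->rpi", mats[r0:r1], qvec) / voxel_q + center
            idx, wts = precompute_weights(coords, n)
            yield r0, r1, idx, wts

    rng = np.random.default_rng(cfg.seed)
    mean_count = counts.mean()
    if initial_model is not None:
        model = np.asarray(initial_model, dtype=np.float64).copy()
    else:
        model = rng.uniform(0.5, 1.5, size=(n, n, n)) * max(mean_count, 1e-3)
    log_wr = np.log(rotations.weights)
    loglik_trace = []
    info_trace = []
    post = None
    valid = np.zeros((n, n, n), dtype=bool)
    for it in range(n_iter):
        # Expand
        w = np.empty((n_rot, counts.shape[1]), dtype=np.float32)
        for r0, r1, idx, wts in weight_chunks():
            w[r0:r1] = np.sum(model.reshape(-1)[idx] * wts, axis=-1)
        np.maximum(w, _W_FLOOR, out=w)
        # Maximize: Poisson log-likelihood and rotation posteriors
        ll = counts @ np.log(w).T.astype(np.float64)
        ll -= w.sum(axis=1, dtype=np.float64)[None]     # (F, R)
        ll += log_wr[None]
        norm = logsumexp(ll, axis=1)
        loglik_trace.append(float(norm.sum()))
        post = np.exp(ll - norm[:, None])
        info_trace.append(mutual_information(post, rotations.weights))
        tomo = post.T @ counts                          # (R, P)
        wsum = post.sum(axis=0)                         # (R,)
        # Compress with adjoint weights
        num = np.zeros(n ** 3)
        den = np.zeros(n ** 3)
        for r0, r1, idx, wts in weight_chunks():
            flat_idx = idx.reshape(-1)
            den += np.bincount(
                flat_idx, weights=(wsum[r0:r1, None, None] * wts).reshape(-1),
                minlength=n ** 3)
            num += np.bincount(
                flat_idx, weights=(tomo[r0:r1, :, None] * wts).reshape(-1),
                minlength=n ** 3)
        num = num.reshape(n, n, n)
        den = den.reshape(n, n, n)
        if cfg.friedel:
            num = _friedel_symmetrize(num)
            den = _friedel_symmetrize(den)
        valid = den > cfg.min_voxel_weight
        model = np.where(valid, num / np.maximum(den, 1e-300), model)
        model = np.maximum(model, 0.0)
    volume = IntensityVolume(values=model, voxel_q=voxel_q, valid=valid)
    return EMCResult(volume=volume, posteriors=post, rotations=rotations,
                     loglik_trace=loglik_trace, info_trace=info_trace)


def _friedel_symmetrize(vol: np.ndarray) -> np.ndarray:
    """Average V(q) with V(-q) about the center voxel n//2 (even grids:
    the zero-index hyperplanes have no partner and are left unchanged)."""
    out = vol.copy()
    core = vol[1:, 1:, 1:]
    out[1:, 1:, 1:] = 0.5 * (core + core[::-1, ::-1, ::-1])
    return out


def mutual_information(post: np.ndarray, weights: np.ndarray) -> float:
    """Average orientation information content, in bits.

    Zero for posteriors equal to the prior; log2(R) for delta posteriors
    under a uniform prior over R rotations.
    """
    p = np.asarray(post, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log2(p) - np.log2(w)[None]), 0.0)
    return float(terms.sum(axis=1).mean())


def mutual_information_trace(result: EMCResult) -> list:
    """Per-iteration orientation-information diagnostic of a run."""
    return list(result.info_trace)


def refine_orientations(stack: PatternStack, pixel_map: PixelMap,
                        result: EMCResult, cfg: EMC3DConfig = None,
                        n_passes: int = 2,
                        refine_scale: bool = True) -> EMCResult:
    """Continuous per-frame orientation (and size-scale) refinement after
    grid-based EMC.

    The rotation-sample grid quantizes orientations to its covering
    radius, which blurs the assembled volume azimuthally at high |q|.
    Starting from each frame's maximum-posterior rotation, the Poisson
    log-likelihood is maximized over a continuous local rotation
    perturbation (simplex search on the rotation vector); the volume is
    then rebuilt by inserting every frame at its refined orientation with
    a delta (hard-assignment) posterior.

    With ``refine_scale`` a per-frame radial q-scale is optimized jointly,
    which normalizes apparent-size jitter (hydration-layer and focus
    variation) before insertion — the diffraction of a particle scaled by
    s samples the reference intensity at q*s.  Two refine/rebuild passes
    are usually enough for the refinement to see its own sharpened model.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation as _R

    if cfg is None:
        cfg = EMC3DConfig()
    n = result.volume.n
    voxel_q = result.volume.voxel_q
    mask = stack.mask & pixel_map.mask
    qvec = pixel_map.qvec[mask]
    counts = stack.counts[:, mask].astype(np.float64)
    center = n // 2
    mats = result.rotations.matrices()[result.posteriors.argmax(axis=1)]
    scales = np.ones(stack.n_frames)
    model = result.volume.values
    valid = result.volume.valid
    info = list(result.info_trace)
    ll_trace = list(result.loglik_trace)
    n_par = 4 if refine_scale else 3

    for _ in range(n_passes):
        refined = np.empty_like(mats)
        total_ll = 0.0
        for i in range(stack.n_frames):
            base = mats[i]
            s_base = scales[i]

            def neg_ll(v):
                rot = _R.from_rotvec(v[:3]).as_matrix() @ base
                s = s_base * np.exp(v[3]) if refine_scale else s_base
                coords = (qvec @ rot.T) * s / voxel_q + center
                w = np.maximum(_gather(model, coords, n), _W_FLOOR)
                return -(counts[i] @ np.log(w) - w.sum())

            res = minimize(neg_ll, np.zeros(n_par), method="Nelder-Mead",
                           options={"xatol": 5e-4, "fatol": 1e-3,
                                    "maxiter": 40 * n_par})
            refined[i] = _R.from_rotvec(res.x[:3]).as_matrix() @ base
            if refine_scale:
                scales[i] = float(np.clip(s_base * np.exp(res.x[3]),
                                          0.8, 1.25))
            total_ll -= res.fun
        mats = refined
        ll_trace.append(total_ll)
        # hard-assignment rebuild at refined orientations and scales
        num = np.zeros(n ** 3)
        den = np.zeros(n ** 3)
        for i in range(stack.n_frames):
            coords = (qvec @ mats[i].T) * scales[i] / voxel_q + center
            idx, wts = precompute_weights(coords, n)
            flat = idx.reshape(-1)
            num += np.bincount(flat, weights=(counts[i][:, None] * wts).reshape(-1),
                               minlength=n ** 3)
            den += np.bincount(flat, weights=wts.reshape(-1).astype(np.float64),
                               minlength=n ** 3)
        num = num.reshape(n, n, n)
        den = den.reshape(n, n, n)
        if cfg.friedel:
            num = _friedel_symmetrize(num)
            den = _friedel_symmetrize(den)
        valid = den > cfg.min_voxel_weight
        model = np.where(valid, num / np.maximum(den, 1e-300), model)
    volume = IntensityVolume(values=model, voxel_q=voxel_q, valid=valid)
    return EMCResult(volume=volume, posteriors=result.posteriors,
                     rotations=result.rotations, loglik_trace=ll_trace,
                     info_trace=info)


def _gather(model, coords, n):
    from .gridtools import trilinear_gather
    return trilinear_gather(model, coords)


def align_volume_correlation(volume: IntensityVolume, reference: IntensityVolume,
                             rotations: RotationSet = None, refine: bool = True,
                             max_voxels: int = 60000, seed: int = 0) -> float:
    """Pearson correlation with a reference volume after global-rotation
    alignment.

    EMC recovers the intensity up to an arbitrary global rotation; this
    searches the provided rotation samples (a deterministic 400-sample
    cover by default) for the rotation of the reference that best matches,
    then refines it with a local simplex search.  Sampling is restricted
    to valid voxels of ``volume`` (optionally subsampled for speed).
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation as _R

    from .rotation import make_rotation_samples as _mrs

    if rotations is None:
        rotations = _mrs(400)
    idx = np.argwhere(volume.valid)
    if len(idx) > max_voxels:
        rng = np.random.default_rng(seed)
        idx = idx[rng.choice(len(idx), size=max_voxels, replace=False)]
    qc = (idx - volume.center) * volume.voxel_q
    mv = volume.values[tuple(idx.T)]

    def corr_for(mat):
        coords = (qc @ mat.T) / reference.voxel_q + reference.center
        tv = gather_cached(reference.values,
                           *precompute_weights(coords, reference.n))
        c = np.corrcoef(mv, tv)[0, 1]
        return -1.0 if not np.isfinite(c) else float(c)

    mats = np.concatenate([np.eye(3)[None], rotations.matrices()])
    scores = [corr_for(m) for m in mats]
    best = int(np.argmax(scores))
    best_mat = mats[best]
    best_corr = scores[best]
    if refine:
        res = minimize(lambda v: -corr_for(_R.from_rotvec(v).as_matrix() @ best_mat),
                       np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 300})
        best_corr = max(best_corr, -float(res.fun))
    return best_corr
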