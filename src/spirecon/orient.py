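"""Correlation-maximization (CM) orientation determination.

The engine alternates two steps until the mean best correlation plateaus:

1. *Assignment*: for every pattern, find the Euler triplet whose Fourier
   slice of the current volume correlates best with the pattern.  Slices are
   compared on a polar grid (rings of 1 binned pixel, uniform azimuths);
   every ring is normalized to zero mean / unit variance so low-resolution
   intensity cannot dominate; the in-plane angle gamma is searched for all
   azimuthal shifts at once with a 1D FFT (cross-correlation theorem), while
   the slice-normal directions (alpha, beta) come from a quasi-uniform grid.
2. *Merge*: every measured binned pixel is deposited at its rotated Ewald
   position into the 3D intensity volume with trilinear weights (weighted
   mean; Friedel mates deposited symmetrically).

Seeding the first assignment with the Fourier volume of a predicted model
(PM-aided) instead of a random volume is what cuts the iteration count and
rescues low-signal data.  A final refinement pass re-searches a geodesic cap
of radius ``3 * delta_beta`` around each pattern's direction at the finer
``refine_delta_beta`` spacing.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.ndimage import gaussian_filter

from ._interp import bilinear, trilinear
from .geometry import (
    DetectorGeometry,
    OrientationGrid,
    euler_to_matrix,
    ewald_qmap,
    orientation_cap,
    polar_qmap,
    sample_orientation_grid,
)
from .scatter import FourierVolume
from .simulate import PatternStack, bin2x2_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "PolarSlice",
    "CMConfig",
    "CMState",
    "extract_slice",
    "cartesian_to_polar",
    "normalize_rings",
    "inplane_correlate",
    "best_orientation",
    "merge_volume",
    "random_reference_volume",
    "run_cm",
]


@dataclasses.dataclass
class PolarSlice:
    """Ring-resampled slice ``I(r, theta)``: rings 1 binned pixel apart,
    ``n_theta`` uniform azimuths over ``[0, 2 pi)``."""

    values: np.ndarray  # (n_rings, n_theta)
    valid: np.ndarray  # same shape, True where measured
    r_indices: np.ndarray  # ring radii in binned pixels

    @property
    def n_theta(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class CMConfig:
    """Tunables of the CM loop.

    ``r_min``/``r_max`` bound the rings entering the correlation (defaults:
    binned beam-stop radius + 2, and 85% of the Nyquist ring); ``n_theta``
    defaults to the next power of two >= the outer ring circumference.
    """

    delta_beta: float = 0.1
    refine_delta_beta: float | None = 0.02
    r_min: int | None = None
    r_max: int | None = None
    n_theta: int | None = None
    max_iters: int = 10
    tol: float = 1e-3
    cap_radius_factor: float = 3.0
    bin_factor: int = 2
    parabolic_gamma: bool = True

    def resolve(self, geom_b: DetectorGeometry, beam_stop_px: int = 0) -> "CMConfig":
        """Fill geometry-dependent defaults for a binned detector."""
        nyquist = geom_b.n_pixels // 2
        r_max = self.r_max if self.r_max is not None else max(3, int(0.85 * nyquist))
        if self.r_min is not None:
            r_min = self.r_min
        else:
            bs_binned = int(np.ceil(beam_stop_px / self.bin_factor / 2.0))
            r_min = bs_binned + 2
        if not 0 < r_min < r_max <= nyquist:
            raise ValueError(f"invalid ring bounds r_min={r_min}, r_max={r_max}")
        n_theta = self.n_theta
        if n_theta is None:
            n_theta = int(2 ** np.ceil(np.log2(max(64, 2 * np.pi * r_max))))
        return dataclasses.replace(self, r_min=r_min, r_max=r_max, n_theta=n_theta)


@dataclasses.dataclass
class CMState:
    """Result of a CM run: merged volume, per-pattern assignments and trace."""

    volume: FourierVolume
    assigned_eulers: np.ndarray  # (n, 3)
    cc_per_pattern: np.ndarray  # (n,)
    cc_mean_trace: list[float]
    n_iterations: int


# ---------------------------------------------------------------------------
# slice extraction and polar machinery


def extract_slice(
    volume: FourierVolume,
    euler: tuple[float, float, float],
    geom_b: DetectorGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Fourier slice of ``volume`` on the binned detector grid at ``euler``.

    Evaluates the volume (intensity, or |F|^2 of a complex reference) at the
    rotated Ewald coordinates ``R q_pixel`` by trilinear interpolation.
    Returns ``(slice, valid)``.
    """
    vals, vol_valid = volume.matching_values()
    q = ewald_qmap(geom_b)
    r = euler_to_matrix(euler)
    coords = volume.q_to_voxel(q @ r.T)
    return trilinear(vals, vol_valid, coords)


def cartesian_to_polar(
    slice_values: np.ndarray,
    valid: np.ndarray | None,
    r_indices: np.ndarray,
    n_theta: int,
    beam_center: tuple[float, float] | None = None,
) -> PolarSlice:
    """Resample a (stack of) Cartesian slice(s) onto concentric rings.

    Ring ``r`` azimuth ``theta`` maps to pixel ``(cy + r sin theta,
    cx + r cos theta)``; bilinear interpolation, invalid pixels propagate.
    """
    n = slice_values.shape[-1]
    if beam_center is None:
        beam_center = ((n - 1) / 2.0, (n - 1) / 2.0)
    r_indices = np.asarray(r_indices, dtype=float)
    if r_indices.max() > n / 2:
        raise ValueError("outermost ring lies beyond the slice grid")
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    rows = beam_center[0] + r_indices[:, None] * np.sin(theta)[None, :]
    cols = beam_center[1] + r_indices[:, None] * np.cos(theta)[None, :]
    vals, ok = bilinear(slice_values, valid, rows, cols)
    return PolarSlice(values=vals, valid=np.broadcast_to(ok, vals.shape).copy(),
                      r_indices=r_indices.astype(int))


def normalize_rings(
    values: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean / unit-variance normalization of each ring over its valid samples.

    Invalid samples are zero-filled after normalization (neutral under the
    zero-mean inner product).  Rings with fewer than 2 valid samples or zero
    variance are flagged unusable.  Works on ``(..., n_rings, n_theta)``.
    """
    v = np.where(valid, values, 0.0)
    n_valid = valid.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = v.sum(axis=-1) / n_valid
        var = ((v - mean[..., None]) ** 2 * valid).sum(axis=-1) / n_valid
    ring_ok = (n_valid >= 2) & (var > 0)
    sd = np.sqrt(np.where(var > 0, var, 1.0))
    out = (values - mean[..., None]) / sd[..., None]
    out = np.where(valid & ring_ok[..., None], out, 0.0)
    return out, ring_ok


def normalize_polar(polar: PolarSlice) -> PolarSlice:
    """:func:`normalize_rings` applied to a :class:`PolarSlice` (unusable rings
    become fully invalid)."""
    vals, ring_ok = normalize_rings(polar.values, polar.valid)
    return PolarSlice(values=vals, valid=polar.valid & ring_ok[..., None],
                      r_indices=polar.r_indices)


def inplane_correlate(
    pattern_polar: PolarSlice,
    ref_polar: PolarSlice,
    parabolic: bool = False,
) -> tuple[float, float, np.ndarray]:
    """Ring-averaged Pearson correlation for every in-plane angle at once.

    Both inputs must be ring-normalized.  ``C(gamma)`` is computed by the 1D
    FFT cross-correlation along theta summed over rings usable in both;
    returns ``(gamma_best, C_max, C_curve)``.
    """
    n_theta = pattern_polar.n_theta
    pat_ok = pattern_polar.valid.any(axis=-1)
    ref_ok = ref_polar.valid.any(axis=-1)
    ok = pat_ok & ref_ok
    if not ok.any():
        raise ValueError("no common valid rings")
    pf = np.fft.fft(pattern_polar.values[ok], axis=-1)
    rf = np.fft.fft(ref_polar.values[ok], axis=-1)
    curve = np.fft.ifft((np.conj(pf) * rf).sum(axis=0)).real / (n_theta * ok.sum())
    k = int(np.argmax(curve))
    gamma = _gamma_from_bin(curve, k, n_theta, parabolic)
    return gamma, float(curve[k]), curve


def _gamma_from_bin(curve: np.ndarray, k: int, n_theta: int, parabolic: bool) -> float:
    delta = 0.0
    if parabolic:
        cm, c0, cp = curve[(k - 1) % n_theta], curve[k], curve[(k + 1) % n_theta]
        denom = cm - 2 * c0 + cp
        if denom < 0:
            delta = float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))
    return ((k + delta) * 2.0 * np.pi / n_theta) % (2.0 * np.pi)


# ---------------------------------------------------------------------------
# batched engine used by the CM loop


def _polar_reference_stack(
    volume: FourierVolume,
    grid: OrientationGrid,
    polar_q: np.ndarray,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized polar slices of ``volume`` for every grid direction (gamma=0).

    ``polar_q`` is the ``(n_rings, n_theta, 3)`` Ewald polar q-map.  Returns
    ``(values (D, n_rings, n_theta), ring_ok (D, n_rings))``.
    """
    vals, vol_valid = volume.matching_values()
    if vol_valid.all():
        vol_valid = None
    n_dirs = len(grid)
    nr, nt, _ = polar_q.shape
    out = np.empty((n_dirs, nr, nt))
    ring_ok = np.empty((n_dirs, nr), dtype=bool)
    mats = np.stack([euler_to_matrix((a, b, 0.0))
                     for a, b in zip(grid.alphas, grid.betas)])
    for s in range(0, n_dirs, chunk):
        r = mats[s:s + chunk]
        coords = volume.q_to_voxel(np.einsum("dab,rtb->drta", r, polar_q))
        v, ok = trilinear(vals, vol_valid, coords)
        out[s:s + chunk], ring_ok[s:s + chunk] = normalize_rings(v, ok)
    return out, ring_ok


def _polar_patterns(
    patterns_b: np.ndarray,
    mask_b: np.ndarray,
    r_indices: np.ndarray,
    n_theta: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized polar form of all binned patterns; returns
    ``(values (n, n_rings, n_theta), ring_ok (n, n_rings))``."""
    polar = cartesian_to_polar(patterns_b, ~mask_b, r_indices, n_theta)
    return normalize_rings(polar.values, polar.valid)


def _assign_batch(
    pat_fft_conj: np.ndarray,
    pat_ring_ok: np.ndarray,
    ref_vals: np.ndarray,
    ref_ring_ok: np.ndarray,
    parabolic: bool,
    chunk: int = 16,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best (direction index, gamma, C) per pattern against a slice stack."""
    n_pat, nr, nt = pat_fft_conj.shape
    ref_fft = np.fft.fft(ref_vals, axis=-1)
    # batched matmul over theta-frequency: (f, p, r) @ (f, r, d) -> (f, p, d)
    rf = np.ascontiguousarray(ref_fft.transpose(2, 1, 0))
    best_dir = np.empty(n_pat, dtype=int)
    best_gamma = np.empty(n_pat)
    best_c = np.empty(n_pat)
    for s in range(0, n_pat, chunk):
        pf = np.ascontiguousarray(pat_fft_conj[s:s + chunk].transpose(2, 0, 1))
        num = np.matmul(pf, rf)  # (f, pc, d)
        curves = np.fft.ifft(num.transpose(1, 2, 0), axis=-1).real  # (pc, d, f)
        n_ok = pat_ring_ok[s:s + chunk].astype(float) @ ref_ring_ok.T.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            curves /= (nt * np.where(n_ok > 0, n_ok, 1.0))[:, :, None]
        curves[n_ok == 0] = -np.inf
        flat = curves.reshape(len(curves), -1)
        arg = np.argmax(flat, axis=1)
        d_idx, k_idx = np.divmod(arg, nt)
        for j, (d, k) in enumerate(zip(d_idx, k_idx)):
            best_dir[s + j] = d
            best_c[s + j] = curves[j, d, k]
            best_gamma[s + j] = _gamma_from_bin(curves[j, d], int(k), nt, parabolic)
    return best_dir, best_gamma, best_c


def best_orientation(
    pattern: PolarSlice,
    ref_volume: FourierVolume,
    grid: OrientationGrid,
    geom_b: DetectorGeometry,
    parabolic: bool = True,
) -> tuple[tuple[float, float, float], float]:
    """Exhaustive search over grid directions (FFT over gamma) for one pattern.

    ``pattern`` must already be ring-normalized.  Ties break at the first
    maximum in grid order.  Returns ``((alpha, beta, gamma), C)``.
    """
    polar_q = polar_qmap(geom_b, pattern.r_indices, pattern.n_theta)
    ref_vals, ref_ok = _polar_reference_stack(ref_volume, grid, polar_q)
    pat_ok = pattern.valid.any(axis=-1)
    if not (pat_ok[None, :] & ref_ok).any():
        raise ValueError("all reference slices invalid for this pattern")
    pf = np.conj(np.fft.fft(pattern.values, axis=-1))[None]
    d, g, c = _assign_batch(pf, pat_ok[None], ref_vals, ref_ok, parabolic)
    e = (float(grid.alphas[d[0]]), float(grid.betas[d[0]]), float(g[0]))
    return e, float(c[0])


# ---------------------------------------------------------------------------
# merging


def merge_volume(
    patterns_b: np.ndarray,
    mask_b: np.ndarray,
    eulers: np.ndarray,
    geom_b: DetectorGeometry,
    dimension: int,
    voxel_pitch_q: float | None = None,
    oversampling: int = 2,
    friedel: bool = True,
) -> FourierVolume:
    """Accumulate binned patterns into a 3D intensity volume.

    Each measured pixel deposits its value on the 8 voxels around its rotated
    Ewald position ``R q`` with trilinear weights; voxel intensity is the
    weighted mean.  With ``friedel`` each pixel is also deposited at ``-R q``
    (the diffracting density is real).  Zero-weight voxels form the missing
    mask.
    """
    if voxel_pitch_q is None:
        voxel_pitch_q = geom_b.center_q_pitch / oversampling
    patterns_b = np.asarray(patterns_b, dtype=float)
    if patterns_b.ndim == 2:
        patterns_b = patterns_b[None]
    eulers = np.atleast_2d(np.asarray(eulers, dtype=float))
    n_pat = len(patterns_b)
    if len(eulers) != n_pat:
        raise ValueError("one euler per pattern required")
    m = dimension
    q = ewald_qmap(geom_b)
    measured = ~mask_b
    qm = q[measured]  # (n_px, 3)
    vsum = np.zeros(m**3)
    wsum = np.zeros(m**3)
    mats = np.stack([euler_to_matrix(e) for e in eulers])
    chunk = max(1, 2_000_000 // max(1, len(qm)))
    for s in range(0, n_pat, chunk):
        qrot = np.einsum("pab,xb->pxa", mats[s:s + chunk], qm)
        vals = patterns_b[s:s + chunk][:, measured].reshape(-1)
        for sgn in ((1.0, -1.0) if friedel else (1.0,)):
            coords = (sgn / voxel_pitch_q) * qrot.reshape(-1, 3) + m // 2
            _deposit_trilinear(vsum, wsum, coords, vals, m)
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1.0), 0.0)
    return FourierVolume(
        dimension=m,
        voxel_pitch_q=voxel_pitch_q,
        intensity=intensity.reshape(m, m, m),
        weight=wsum.reshape(m, m, m),
        missing_mask=(wsum == 0).reshape(m, m, m),
    )


def _deposit_trilinear(vsum, wsum, coords, vals, m):
    i0 = np.floor(coords).astype(np.int64)
    inside = ((i0 >= 0) & (i0 <= m - 2)).all(axis=1)
    i0, f = i0[inside], coords[inside] - i0[inside]
    v = vals[inside]
    g = 1.0 - f
    base = (i0[:, 0] * m + i0[:, 1]) * m + i0[:, 2]
    for di in (0, 1):
        wi = f[:, 0] if di else g[:, 0]
        for dj in (0, 1):
            wij = wi * (f[:, 1] if dj else g[:, 1])
            for dk in (0, 1):
                w = wij * (f[:, 2] if dk else g[:, 2])
                flat = base + ((di * m + dj) * m + dk)
                vsum += np.bincount(flat, weights=w * v, minlength=m**3)
                wsum += np.bincount(flat, weights=w, minlength=m**3)


def random_reference_volume(
    dimension: int,
    voxel_pitch_q: float,
    rng: np.random.Generator,
    smooth_voxels: float = 3.0,
) -> FourierVolume:
    """Random starting volume for the classical (non-PM) method: positive
    uniform noise, Gaussian-smoothed and Friedel-symmetrized."""
    v = rng.uniform(0.0, 1.0, (dimension,) * 3)
    v = gaussian_filter(v, smooth_voxels)
    v = 0.5 * (v + v[::-1, ::-1, ::-1])
    v = np.roll(v, (1, 1, 1), axis=(0, 1, 2))  # keep q=0 at index m/2 after inversion
    return FourierVolume(dimension=dimension, voxel_pitch_q=voxel_pitch_q,
                         intensity=v, weight=np.ones_like(v),
                         missing_mask=np.zeros(v.shape, dtype=bool))


# ---------------------------------------------------------------------------
# the CM loop


def run_cm(
    stack: PatternStack,
    config: CMConfig,
    reference: FourierVolume | None = None,
    seed: int = 0,
    dimension: int | None = None,
    oversampling: int = 2,
) -> CMState:
    """Full CM orientation determination on a pattern stack.

    ``reference`` seeds the first assignment (PM-aided); ``None`` starts from
    a random volume.  Runs at most ``config.max_iters`` assignment+merge
    cycles, stopping early once the mean best correlation changes by less
    than ``config.tol``, then performs one cap-restricted refinement pass at
    ``config.refine_delta_beta`` and a final merge.
    """
    if stack.binned:
        geom_b, patterns_b, mask_b = stack.geom, stack.patterns, stack.mask
    else:
        geom_b = stack.geom.binned(config.bin_factor)
        patterns_b, mask_b = bin2x2_arrays(stack.patterns, stack.mask)
    beam_stop = stack.params.beam_stop_px if stack.params is not None else 0
    cfg = config.resolve(geom_b, beam_stop)
    r_indices = np.arange(cfg.r_min, cfg.r_max + 1)
    polar_q = polar_qmap(geom_b, r_indices, cfg.n_theta)

    pat_vals, pat_ok = _polar_patterns(patterns_b, mask_b, r_indices, cfg.n_theta)
    pat_fft_conj = np.conj(np.fft.fft(pat_vals, axis=-1))

    if reference is not None:
        volume = reference
        if dimension is None:
            dimension = reference.dimension
        dq = reference.voxel_pitch_q
    else:
        dq = geom_b.center_q_pitch / oversampling
        if dimension is None:
            dimension = oversampling * geom_b.n_pixels
        volume = random_reference_volume(dimension, dq, np.random.default_rng(seed))

    grid = sample_orientation_grid(cfg.delta_beta)
    trace: list[float] = []
    eulers = np.zeros((len(patterns_b), 3))
    cc = np.zeros(len(patterns_b))
    n_iters = 0
    for it in range(max(1, cfg.max_iters)):
        ref_vals, ref_ok = _polar_reference_stack(volume, grid, polar_q)
        d, g, cc = _assign_batch(pat_fft_conj, pat_ok, ref_vals, ref_ok,
                                 cfg.parabolic_gamma)
        eulers = np.stack([grid.alphas[d], grid.betas[d], g], axis=1)
        if np.isnan(cc).any():
            raise RuntimeError("CM diverged: NaN correlation")
        trace.append(float(cc.mean()))
        logger.info("CM iter %d: CC_mean = %.4f", it + 1, trace[-1])
        volume = merge_volume(patterns_b, mask_b, eulers, geom_b, dimension, dq)
        n_iters = it + 1
        if it >= 1 and abs(trace[-1] - trace[-2]) < cfg.tol:
            break
        if cfg.max_iters == 0:
            break

    if cfg.refine_delta_beta is not None:
        cap_radius = cfg.cap_radius_factor * cfg.delta_beta
        eulers, cc = _refine_pass(
            pat_fft_conj, pat_ok, volume, eulers, polar_q,
            cap_radius, cfg.refine_delta_beta, cfg.parabolic_gamma,
        )
        trace.append(float(cc.mean()))
        logger.info("CM refine: CC_mean = %.4f", trace[-1])
        volume = merge_volume(patterns_b, mask_b, eulers, geom_b, dimension, dq)

    return CMState(volume=volume, assigned_eulers=eulers, cc_per_pattern=cc,
                   cc_mean_trace=trace, n_iterations=n_iters)


def _refine_pass(
    pat_fft_conj: np.ndarray,
    pat_ok: np.ndarray,
    volume: FourierVolume,
    eulers: np.ndarray,
    polar_q: np.ndarray,
    cap_radius: float,
    delta: float,
    parabolic: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pattern local search on a geodesic cap around the current direction."""
    out_e = eulers.copy()
    out_c = np.empty(len(eulers))
    for p in range(len(eulers)):
        cap = orientation_cap(eulers[p, 0], eulers[p, 1], cap_radius, delta)
        ref_vals, ref_ok = _polar_reference_stack(volume, cap, polar_q, chunk=1024)
        d, g, c = _assign_batch(pat_fft_conj[p:p + 1], pat_ok[p:p + 1],
                                ref_vals, ref_ok, parabolic)
        out_e[p] = (cap.alphas[d[0]], cap.betas[d[0]], g[0])
        out_c[p] = c[0]
    return out_e, out_c
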