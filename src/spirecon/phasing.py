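"""Hybrid HIO-ER phase retrieval of merged 3D amplitudes.

The merged intensity volume gives 3D moduli ``A = sqrt(I)``; phases are
recovered by alternating a real-space constraint (a fixed cubic support plus
positivity inside it) with the Fourier-modulus projection.  On *measured*
voxels the modulus is replaced by ``A`` and the phase kept; on *missing*
voxels (beam stop, never-touched voxels) both modulus and phase float.  Two
real-space update rules are supported:

* **ER** (error reduction): the violating set — density outside the support,
  or negative inside — is zeroed.
* **HIO** (hybrid input-output): on the violating set the new input is
  ``x_prev - beta * rho``; elsewhere ``rho`` (Fienup feedback ``beta``,
  default 0.9).

Starting schedules follow the two study arms: random phases use 1000 HIO +
100 ER; phases taken from a predicted-model reference volume use 1100 ER
only (a good start must not be kicked away by HIO's exploratory feedback).
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np

from .scatter import DensityMap

__all__ = [
    "PhasingSchedule",
    "make_support",
    "beam_stop_cube_mask",
    "run_phasing",
    "upsample_density",
    "phasing_success",
    "align_to",
]


@dataclasses.dataclass(frozen=True)
class PhasingSchedule:
    """Ordered (algorithm, iteration-count) segments plus the HIO feedback."""

    segments: tuple[tuple[str, int], ...]
    hio_feedback: float = 0.9

    def __post_init__(self) -> None:
        for algo, n in self.segments:
            if algo not in ("HIO", "ER"):
                raise ValueError(f"unknown algorithm {algo!r}")
            if n < 0:
                raise ValueError("iteration counts must be >= 0")
        if not 0 < self.hio_feedback <= 1:
            raise ValueError("hio_feedback must lie in (0, 1]")

    @classmethod
    def random_default(cls, scale: float = 1.0) -> "PhasingSchedule":
        """1000 HIO + 100 ER (optionally scaled down for desk-size problems)."""
        return cls(segments=(("HIO", int(1000 * scale)), ("ER", int(100 * scale))))

    @classmethod
    def prior_default(cls, scale: float = 1.0) -> "PhasingSchedule":
        """1100 ER — exploratory HIO would kick a good start away."""
        return cls(segments=(("ER", int(1100 * scale)),))


def make_support(
    model_extent_A: float,
    voxel_pitch_x: float,
    dimension: int,
    margin_factor: float = 1.2,
) -> np.ndarray:
    """Centered cubic support of side ``ceil(margin * extent / pitch)`` voxels."""
    if model_extent_A <= 0:
        raise ValueError("extent must be positive")
    side = int(math.ceil(margin_factor * model_extent_A / voxel_pitch_x))
    if side > dimension:
        raise ValueError("support exceeds the grid")
    lo = (dimension - side) // 2
    support = np.zeros((dimension,) * 3, dtype=bool)
    support[lo:lo + side, lo:lo + side, lo:lo + side] = True
    return support


def beam_stop_cube_mask(dimension: int, size_voxels: int) -> np.ndarray:
    """Central ``size^3`` cube of missing low-resolution voxels (beam stop)."""
    mask = np.zeros((dimension,) * 3, dtype=bool)
    if size_voxels > 0:
        c = dimension // 2
        lo, hi = c - size_voxels // 2, c - size_voxels // 2 + size_voxels
        mask[lo:hi, lo:hi, lo:hi] = True
    return mask


def random_friedel_phases(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Random phase array (standard FFT layout) with phi(-q) = -phi(q)."""
    return np.angle(np.fft.fftn(rng.standard_normal(shape)))


def run_phasing(
    amplitudes: np.ndarray,
    missing_mask: np.ndarray,
    support: np.ndarray,
    schedule: PhasingSchedule,
    seed: int | None = None,
    init_phases: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative phase retrieval; returns ``(density, final complex volume)``.

    All arrays are in the centered layout (q = 0 at index ``m // 2``);
    ``amplitudes`` must be >= 0 and ``missing_mask`` True where the modulus
    is unknown (those voxels float freely).  ``init_phases`` (centered
    layout, radians) seeds the run; otherwise Friedel-consistent random
    phases are drawn from ``seed``.
    """
    a = np.asarray(amplitudes, dtype=float)
    if (a < 0).any():
        raise ValueError("amplitudes must be non-negative")
    measured = ~np.asarray(missing_mask, dtype=bool)
    if not measured.any():
        raise ValueError("empty measured set")
    # to standard FFT layout
    a_std = np.fft.ifftshift(a)
    meas_std = np.fft.ifftshift(measured)
    sup_std = np.fft.ifftshift(np.asarray(support, dtype=bool))
    if init_phases is not None:
        phases = np.fft.ifftshift(np.asarray(init_phases, dtype=float))
    else:
        rng = np.random.default_rng(0 if seed is None else seed)
        phases = random_friedel_phases(a.shape, rng)
    g = np.where(meas_std, a_std, 0.0) * np.exp(1j * phases)
    x_prev = np.fft.ifftn(g).real
    beta = schedule.hio_feedback
    for algo, n_iter in schedule.segments:
        for _ in range(n_iter):
            rho = np.fft.ifftn(g).real
            violating = ~sup_std | (sup_std & (rho < 0))
            if algo == "ER":
                x = np.where(violating, 0.0, rho)
            else:
                x = np.where(violating, x_prev - beta * rho, rho)
            x_prev = x
            gf = np.fft.fftn(x)
            if np.isnan(gf).any():
                raise RuntimeError("phase retrieval diverged (NaN)")
            mag = np.abs(gf)
            phase = np.where(mag > 0, gf / np.where(mag > 0, mag, 1.0), 1.0)
            g = np.where(meas_std, a_std * phase, gf)
    density = np.fft.ifftn(g).real
    return np.fft.fftshift(density), np.fft.fftshift(g)


def upsample_density(
    density: np.ndarray,
    voxel_pitch_x: float,
    target_pitch: float = 1.0,
) -> DensityMap:
    """Fourier zero-padding interpolation of a real-space map to a finer pitch.

    The map is transformed, zero-padded to the dimension implied by the
    target pitch, and inverse transformed; the scaling preserves density
    *values* (and hence total density) for band-limited maps.  The achieved
    pitch ``old_pitch * n_old / n_new`` is stored on the result.
    """
    if target_pitch >= voxel_pitch_x:
        raise ValueError("target spacing must be finer than the current spacing")
    n_old = density.shape[0]
    n_new = int(round(n_old * voxel_pitch_x / target_pitch))
    f = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(density)))
    pad = np.zeros((n_new,) * 3, dtype=complex)
    lo = n_new // 2 - n_old // 2
    pad[lo:lo + n_old, lo:lo + n_old, lo:lo + n_old] = f
    fine = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(pad))).real
    fine *= (n_new / n_old) ** 3
    return DensityMap(values=fine, voxel_pitch=voxel_pitch_x * n_old / n_new)


def _symmetry_ops() -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """The 48 axis permutation x axis flip operations of a cubic grid."""
    return [(perm, signs) for perm in itertools.permutations((0, 1, 2))
            for signs in itertools.product((1, -1), repeat=3)]


def _apply_op(vol: np.ndarray, perm, signs) -> np.ndarray:
    out = np.transpose(vol, perm)
    for ax, s in enumerate(signs):
        if s < 0:
            # flip about the centre voxel m/2 of an even grid
            out = np.roll(np.flip(out, axis=ax), 1, axis=ax)
    return out


def align_to(
    reference: np.ndarray, moving: np.ndarray
) -> tuple[np.ndarray, float]:
    """Best overlay of ``moving`` onto ``reference`` over the trivial ambiguities.

    Searches the 48 cubic axis permutation/flip operations (which include the
    point inversion inherent to phase retrieval) combined with the best
    integer translation found by FFT cross-correlation.  Returns the aligned
    copy of ``moving`` and the overall Pearson correlation.
    """
    ref = reference - reference.mean()
    nref = np.linalg.norm(ref)
    fref = np.conj(np.fft.fftn(ref))
    best = (-np.inf, None, None)
    for perm, signs in _symmetry_ops():
        cand = _apply_op(moving, perm, signs)
        c = cand - cand.mean()
        xc = np.fft.ifftn(np.fft.fftn(c) * fref).real
        k = np.unravel_index(np.argmax(xc), xc.shape)
        cc = xc[k] / (nref * np.linalg.norm(c) + 1e-300)
        if cc > best[0]:
            best = (cc, (perm, signs), k)
    cc, (perm, signs), k = best
    aligned = np.roll(_apply_op(moving, perm, signs), [-s for s in k],
                      axis=(0, 1, 2))
    return aligned, float(cc)


def phasing_success(
    recovered: np.ndarray, truth: np.ndarray, threshold: float = 0.5
) -> tuple[float, bool]:
    """Overall real-space correlation after trivial-ambiguity alignment.

    Success is declared above ``threshold`` (default 0.5), matching the
    overall-CC criterion used for the success-rate tables.
    """
    _, cc = align_to(truth, recovered)
    return cc, bool(cc > threshold)
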