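"""Diffraction geometry, Ewald mapping, rotation conventions and orientation sampling.

Conventions used throughout the package
---------------------------------------

* The incident beam travels along +z; the flat square detector sits
  perpendicular to it at ``distance`` metres downstream.
* Pixel indices are 0-based with pixel centres at integer indices; the beam
  centre defaults to the geometric detector centre ``(n - 1) / 2``.
* Scattering vectors use the crystallographic convention ``|q| = 2 sin(theta)
  / lambda`` (no ``2 pi``), so resolution is simply ``d = 1 / |q|``.
* Orientations are intrinsic z-x'-z'' Euler triplets ``(alpha, beta, gamma)``
  with matrix ``R = Rz(alpha) @ Rx(beta) @ Rz(gamma)``.  A snapshot at
  orientation ``R`` samples the molecular transform at ``R q_pixel``
  (the Ewald sphere is rotated, not the molecule); ``gamma`` is then a pure
  in-plane rotation of the pattern, which is what allows the FFT-based
  in-plane search in :mod:`spirecon.orient`.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple

import numpy as np

__all__ = [
    "DetectorGeometry",
    "EulerTriplet",
    "OrientationGrid",
    "ewald_qmap",
    "polar_qmap",
    "resolution_at_radius",
    "euler_to_matrix",
    "matrix_to_euler",
    "rotation_angle_between",
    "sample_orientation_grid",
    "orientation_cap",
    "random_eulers",
    "direction_to_alpha_beta",
]


class EulerTriplet(NamedTuple):
    """Intrinsic z-x'-z'' Euler angles, ``alpha, gamma in [0, 2pi)``, ``beta in [0, pi]``."""

    alpha: float
    beta: float
    gamma: float


@dataclasses.dataclass(frozen=True)
class DetectorGeometry:
    """Square flat detector downstream of the interaction point.

    Parameters
    ----------
    wavelength:
        XFEL wavelength in Angstrom.
    n_pixels:
        Pixels per detector side (even).
    pixel_size:
        Pixel pitch in micrometres.
    distance:
        Sample-to-detector distance in metres.
    beam_center:
        Fractional pixel coordinates of the direct beam; defaults to the
        detector centre ``(n - 1) / 2`` on both axes.
    """

    wavelength: float
    n_pixels: int
    pixel_size: float
    distance: float
    beam_center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.pixel_size <= 0 or self.distance <= 0:
            raise ValueError("wavelength, pixel_size and distance must be positive")
        if self.n_pixels <= 0 or self.n_pixels % 2:
            raise ValueError("n_pixels must be a positive even integer")
        if self.beam_center is None:
            c = (self.n_pixels - 1) / 2.0
            object.__setattr__(self, "beam_center", (c, c))

    @property
    def pixel_m(self) -> float:
        return self.pixel_size * 1e-6

    @property
    def center_q_pitch(self) -> float:
        """Reciprocal-space pitch (1/A) of one pixel at the detector centre."""
        return self.pixel_m / (self.distance * self.wavelength)

    def binned(self, factor: int = 2) -> "DetectorGeometry":
        """Geometry of the pattern after ``factor x factor`` pixel binning."""
        if self.n_pixels % factor:
            raise ValueError("n_pixels not divisible by binning factor")
        return DetectorGeometry(
            wavelength=self.wavelength,
            n_pixels=self.n_pixels // factor,
            pixel_size=self.pixel_size * factor,
            distance=self.distance,
        )


def ewald_qmap(geom: DetectorGeometry) -> np.ndarray:
    """Per-pixel scattering vectors on the Ewald sphere.

    Returns an ``(n, n, 3)`` array in 1/A: ``q = (s_hat - z_hat) / lambda``
    with ``s_hat`` the unit vector from the sample to the pixel centre.
    Axis 0 of the detector array maps to y, axis 1 to x.
    """
    n = geom.n_pixels
    cy, cx = geom.beam_center[0], geom.beam_center[1]
    idx = np.arange(n, dtype=float)
    y = (idx - cy)[:, None] * geom.pixel_m
    x = (idx - cx)[None, :] * geom.pixel_m
    return _xy_to_q(x, y, geom)


def _xy_to_q(x: np.ndarray, y: np.ndarray, geom: DetectorGeometry) -> np.ndarray:
    """Detector-plane offsets (metres, broadcastable) -> scattering vectors (1/A)."""
    d = geom.distance
    r = np.sqrt(x * x + y * y + d * d)
    q = np.empty(np.broadcast(x, y).shape + (3,), dtype=float)
    q[..., 0] = x / (r * geom.wavelength)
    q[..., 1] = y / (r * geom.wavelength)
    q[..., 2] = (d / r - 1.0) / geom.wavelength
    return q


def polar_qmap(geom: DetectorGeometry, radii_px: np.ndarray, n_theta: int) -> np.ndarray:
    """Scattering vectors for a polar grid on the detector.

    ``radii_px`` are ring radii in pixels from the beam centre; ``n_theta``
    azimuth samples cover ``[0, 2 pi)``.  Returns ``(n_rings, n_theta, 3)``.
    """
    radii = np.asarray(radii_px, dtype=float)
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    rho = radii[:, None] * geom.pixel_m
    x = rho * np.cos(theta)[None, :]
    y = rho * np.sin(theta)[None, :]
    return _xy_to_q(x, y, geom)


def resolution_at_radius(geom: DetectorGeometry, radius_px: float) -> float:
    """Resolution ``d = 1/|q|`` (A) at a given radius (pixels) from the beam centre."""
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    if radius_px == 0:
        return math.inf
    rho = radius_px * geom.pixel_m
    two_theta = math.atan2(rho, geom.distance)
    return geom.wavelength / (2.0 * math.sin(two_theta / 2.0))


def _rz(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rx(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def euler_to_matrix(e: EulerTriplet | tuple[float, float, float]) -> np.ndarray:
    """Rotation matrix ``R = Rz(alpha) @ Rx(beta) @ Rz(gamma)`` (intrinsic z-x'-z'')."""
    a, b, g = e
    return _rz(a) @ _rx(b) @ _rz(g)


def matrix_to_euler(r: np.ndarray) -> EulerTriplet:
    """Inverse of :func:`euler_to_matrix`; at the beta in {0, pi} degeneracy the
    whole in-plane angle is reported in alpha (gamma = 0)."""
    b = math.acos(min(1.0, max(-1.0, float(r[2, 2]))))
    if math.sin(b) > 1e-9:
        a = math.atan2(r[0, 2], -r[1, 2])
        g = math.atan2(r[2, 0], r[2, 1])
    else:
        # gimbal degenerate: R = Rz(alpha + gamma) (beta=0) or Rz(alpha - gamma) Rx(pi)
        a = math.atan2(r[1, 0], r[0, 0])
        g = 0.0
    return EulerTriplet(a % (2 * math.pi), b, g % (2 * math.pi))


def rotation_angle_between(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic angle in degrees between two rotation matrices."""
    tr = float(np.trace(r1 @ r2.T))
    return math.degrees(math.acos(min(1.0, max(-1.0, (tr - 1.0) / 2.0))))


@dataclasses.dataclass(frozen=True)
class OrientationGrid:
    """Quasi-uniform grid of slice-normal directions (alpha, beta).

    Per ring at polar angle beta the azimuthal step obeys
    ``delta_alpha * sin(beta) ~= delta_beta`` so the solid-angle density is
    uniform; gamma is never gridded (it is searched by FFT).
    """

    delta_beta: float
    alphas: np.ndarray
    betas: np.ndarray

    def __len__(self) -> int:
        return len(self.alphas)

    @property
    def directions(self) -> np.ndarray:
        """Unit normal vectors ``Rz(a) Rx(b) z_hat``; shape ``(n, 3)``."""
        sa, ca = np.sin(self.alphas), np.cos(self.alphas)
        sb, cb = np.sin(self.betas), np.cos(self.betas)
        return np.stack([sa * sb, -ca * sb, cb], axis=1)


def sample_orientation_grid(delta_beta: float) -> OrientationGrid:
    """Uniform direction sampling: beta rings at multiples of ``delta_beta``,
    ``max(1, round(2 pi sin(beta) / delta_beta))`` alpha samples per ring, and a
    single direction at each pole."""
    if not 0 < delta_beta <= math.pi / 2:
        raise ValueError("delta_beta must lie in (0, pi/2]")
    alphas: list[np.ndarray] = []
    betas: list[np.ndarray] = []
    n_rings = int(math.floor(math.pi / delta_beta + 1e-9))
    for k in range(n_rings + 1):
        b = k * delta_beta
        n_a = max(1, int(round(2.0 * math.pi * math.sin(b) / delta_beta)))
        alphas.append(np.arange(n_a) * (2.0 * math.pi / n_a))
        betas.append(np.full(n_a, b))
    return OrientationGrid(
        delta_beta=delta_beta,
        alphas=np.concatenate(alphas),
        betas=np.concatenate(betas),
    )


def direction_to_alpha_beta(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit direction(s) -> (alpha, beta) with ``n = (sin a sin b, -cos a sin b, cos b)``."""
    n = np.asarray(n, dtype=float)
    beta = np.arccos(np.clip(n[..., 2], -1.0, 1.0))
    alpha = np.arctan2(n[..., 0], -n[..., 1]) % (2 * math.pi)
    return alpha, beta


def orientation_cap(
    center_alpha: float, center_beta: float, radius: float, delta: float
) -> OrientationGrid:
    """Local direction grid inside a geodesic cap, used by the refinement pass.

    Rings of polar offset ``psi = 0, delta, ..., <= radius`` around the centre
    direction, each carrying ``max(1, round(2 pi sin(psi) / delta))`` samples.
    """
    if radius <= 0 or delta <= 0:
        raise ValueError("radius and delta must be positive")
    locals_: list[np.ndarray] = []
    n_rings = int(math.floor(radius / delta + 1e-9))
    for k in range(n_rings + 1):
        psi = k * delta
        n_a = max(1, int(round(2.0 * math.pi * math.sin(psi) / delta)))
        phi = np.arange(n_a) * (2.0 * math.pi / n_a)
        locals_.append(
            np.stack(
                [
                    np.sin(psi) * np.cos(phi),
                    np.sin(psi) * np.sin(phi),
                    np.full(n_a, math.cos(psi)),
                ],
                axis=1,
            )
        )
    local = np.concatenate(locals_)
    r0 = _rz(center_alpha) @ _rx(center_beta)
    alpha, beta = direction_to_alpha_beta(local @ r0.T)
    return OrientationGrid(delta_beta=delta, alphas=alpha, betas=beta)


def random_eulers(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` orientations uniform on SO(3): alpha, gamma uniform on [0, 2pi),
    ``beta = arccos(1 - 2u)``.  Returns an ``(n, 3)`` array."""
    a = rng.uniform(0.0, 2 * math.pi, n)
    b = np.arccos(1.0 - 2.0 * rng.uniform(0.0, 1.0, n))
    g = rng.uniform(0.0, 2 * math.pi, n)
    return np.stack([a, b, g], axis=1)
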