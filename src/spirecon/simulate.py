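"""Snapshot diffraction-pattern simulation with Poisson noise, beam stop and binning.

Per-pixel noiseless intensity follows the far-field single-particle formula

    I(pixel) = J * r_e^2 * Omega * |F(R q_pixel)|^2

where ``J`` is the photon fluence (photons/A^2, uniform disc focus), ``r_e``
the classical electron radius, ``Omega = A cos^3(2 theta) / D^2`` the solid
angle of the flat-detector pixel, and ``R = Rz(a) Rx(b) Rz(g)`` the rotation
of the Ewald sphere for that snapshot.  Poisson sampling uses a per-pattern
RNG stream spawned from (master seed, pattern index) so any subset of a
dataset is reproducible.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np

from .geometry import DetectorGeometry, euler_to_matrix, ewald_qmap, random_eulers
from .scatter import R_E_A, AtomicModel, structure_factor

__all__ = [
    "SimulationParams",
    "DiffractionPattern",
    "PatternStack",
    "simulate_pattern",
    "solid_angle_map",
    "apply_beam_stop",
    "bin2x2",
    "bin2x2_arrays",
    "make_dataset",
]


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Beam and noise parameters for pattern simulation.

    ``photons_per_pulse`` and the uniform-disc ``beam_focus_um`` (micrometre
    diameter) set the fluence; ``beam_stop_px`` is the side of the masked
    central square on the unbinned detector; ``atom_sigma_A`` is the Gaussian
    atomic width of the scatterer model.
    """

    photons_per_pulse: float
    beam_focus_um: float = 0.1
    seed: int = 0
    poisson: bool = True
    beam_stop_px: int = 0
    atom_sigma_A: float = 1.0

    def __post_init__(self) -> None:
        if self.photons_per_pulse < 0 or self.beam_focus_um <= 0:
            raise ValueError("photons_per_pulse must be >= 0 and focus > 0")
        if self.beam_stop_px < 0 or self.beam_stop_px % 2:
            raise ValueError("beam_stop_px must be an even non-negative integer")

    @property
    def fluence(self) -> float:
        """Photons per square Angstrom at the focus."""
        radius_A = self.beam_focus_um * 1e4 / 2.0
        return self.photons_per_pulse / (np.pi * radius_A**2)


@dataclasses.dataclass
class DiffractionPattern:
    """One snapshot: photon counts, unmeasured-pixel mask and optional truth."""

    counts: np.ndarray
    mask: np.ndarray
    true_euler: tuple[float, float, float] | None = None
    binned: bool = False

    @property
    def n_photons(self) -> float:
        """Total counts over measured pixels."""
        return float(self.counts[~self.mask].sum())


def solid_angle_map(geom: DetectorGeometry) -> np.ndarray:
    """Per-pixel solid angle of a flat detector: ``A cos^3(2 theta) / D^2``."""
    n = geom.n_pixels
    cy, cx = geom.beam_center
    idx = np.arange(n, dtype=float)
    y = (idx - cy)[:, None] * geom.pixel_m
    x = (idx - cx)[None, :] * geom.pixel_m
    d = geom.distance
    cos2t = d / np.sqrt(x * x + y * y + d * d)
    return (geom.pixel_m**2 / d**2) * cos2t**3


def simulate_pattern(
    model: AtomicModel,
    geom: DetectorGeometry,
    params: SimulationParams,
    euler: tuple[float, float, float],
    rng: np.random.Generator | None = None,
) -> DiffractionPattern:
    """Simulate one snapshot at the given Euler orientation.

    With ``params.poisson`` the counts are Poisson-sampled from the noiseless
    intensity (``rng`` required unless noiseless); the beam stop is applied
    last.
    """
    q = ewald_qmap(geom)
    r = euler_to_matrix(euler)
    f = structure_factor(model.centered(), q @ r.T, sigma=params.atom_sigma_A)
    intensity = params.fluence * R_E_A**2 * solid_angle_map(geom) * np.abs(f) ** 2
    if params.poisson:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        counts = rng.poisson(intensity).astype(float)
    else:
        counts = intensity
    pat = DiffractionPattern(counts=counts, mask=np.zeros(counts.shape, dtype=bool),
                             true_euler=tuple(euler))
    return apply_beam_stop(pat, params.beam_stop_px)


def apply_beam_stop(pattern: DiffractionPattern, size_px: int) -> DiffractionPattern:
    """Mask the central ``size_px x size_px`` square (counts zeroed under the mask)."""
    n = pattern.counts.shape[0]
    if size_px % 2 or size_px < 0:
        raise ValueError("size_px must be even and >= 0")
    if size_px > n:
        raise ValueError("beam stop larger than detector")
    if size_px == 0:
        return pattern
    lo, hi = n // 2 - size_px // 2, n // 2 + size_px // 2
    mask = pattern.mask.copy()
    mask[lo:hi, lo:hi] = True
    counts = pattern.counts.copy()
    counts[mask] = 0.0
    return DiffractionPattern(counts=counts, mask=mask,
                              true_euler=pattern.true_euler, binned=pattern.binned)


def bin2x2(pattern: DiffractionPattern) -> DiffractionPattern:
    """Sum 2x2 pixel blocks; a binned pixel is masked if any contributor is masked."""
    counts, mask = bin2x2_arrays(pattern.counts, pattern.mask)
    return DiffractionPattern(counts=counts, mask=mask,
                              true_euler=pattern.true_euler, binned=True)


def bin2x2_arrays(counts: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Block-sum the trailing two axes; mask may omit leading stack axes."""
    n = counts.shape[-1]
    if n % 2 or counts.shape[-2] % 2:
        raise ValueError("binning requires even dimensions")
    shape = counts.shape[:-2] + (counts.shape[-2] // 2, 2, n // 2, 2)
    binned = counts.reshape(shape).sum(axis=(-3, -1))
    bmask = mask.reshape(mask.shape[:-2] + (mask.shape[-2] // 2, 2, n // 2, 2)).any(axis=(-3, -1))
    out = binned * ~bmask  # zero under the mask (mask is authoritative downstream)
    return out, bmask


@dataclasses.dataclass
class PatternStack:
    """A dataset of snapshots sharing one geometry, mask and simulation setup."""

    patterns: np.ndarray  # (n, s, s)
    mask: np.ndarray  # (s, s), True = unmeasured
    eulers: np.ndarray | None  # (n, 3) ground truth (simulation only)
    geom: DetectorGeometry
    params: SimulationParams | None = None
    binned: bool = False

    def __len__(self) -> int:
        return len(self.patterns)

    def subset(self, indices: np.ndarray) -> "PatternStack":
        return PatternStack(self.patterns[indices], self.mask,
                            None if self.eulers is None else self.eulers[indices],
                            self.geom, self.params, self.binned)

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            # track_times=False keeps identical-seed files byte-identical
            f.create_dataset("patterns", data=self.patterns.astype(np.float32),
                             track_times=False)
            f.create_dataset("mask", data=self.mask, track_times=False)
            if self.eulers is not None:
                f.create_dataset("euler_true", data=self.eulers, track_times=False)
            g = f.create_group("geometry")
            g.attrs.update(
                wavelength_A=self.geom.wavelength, n_pixels=self.geom.n_pixels,
                pixel_um=self.geom.pixel_size, distance_m=self.geom.distance,
            )
            p = f.create_group("params")
            if self.params is not None:
                p.attrs.update(
                    photons_per_pulse=self.params.photons_per_pulse,
                    beam_focus_um=self.params.beam_focus_um, seed=self.params.seed,
                    poisson=self.params.poisson, beam_stop_px=self.params.beam_stop_px,
                    atom_sigma_A=self.params.atom_sigma_A,
                )
            f.attrs["binned"] = self.binned

    @classmethod
    def load(cls, path: str) -> "PatternStack":
        with h5py.File(path, "r") as f:
            g = f["geometry"].attrs
            geom = DetectorGeometry(float(g["wavelength_A"]), int(g["n_pixels"]),
                                    float(g["pixel_um"]), float(g["distance_m"]))
            p = f["params"].attrs
            params = None
            if "photons_per_pulse" in p:
                params = SimulationParams(
                    photons_per_pulse=float(p["photons_per_pulse"]),
                    beam_focus_um=float(p["beam_focus_um"]), seed=int(p["seed"]),
                    poisson=bool(p["poisson"]), beam_stop_px=int(p["beam_stop_px"]),
                    atom_sigma_A=float(p.get("atom_sigma_A", 1.0)),
                )
            eulers = f["euler_true"][()] if "euler_true" in f else None
            return cls(f["patterns"][()].astype(float), f["mask"][()].astype(bool),
                       eulers, geom, params, bool(f.attrs["binned"]))


def make_dataset(
    model: AtomicModel,
    geom: DetectorGeometry,
    params: SimulationParams,
    n_patterns: int,
    seed: int | None = None,
    path: str | None = None,
) -> PatternStack:
    """Simulate ``n_patterns`` snapshots at orientations uniform on SO(3).

    The orientation stream and every per-pattern Poisson stream are spawned
    from the master seed, so identical seeds give bit-identical stacks and
    pattern ``i`` is reproducible in isolation.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    seed = params.seed if seed is None else seed
    master = np.random.SeedSequence(seed)
    orient_rng = np.random.default_rng(master.spawn(1)[0])
    eulers = random_eulers(n_patterns, orient_rng)
    pattern_seeds = master.spawn(n_patterns)
    stack = None
    for i in range(n_patterns):
        rng = np.random.default_rng(pattern_seeds[i])
        pat = simulate_pattern(model, geom, params, eulers[i], rng=rng)
        if stack is None:
            stack = np.empty((n_patterns,) + pat.counts.shape)
            mask = pat.mask
        stack[i] = pat.counts
    result = PatternStack(patterns=stack, mask=mask, eulers=eulers,
                          geom=geom, params=params, binned=False)
    if path is not None:
        result.save(path)
    return result
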