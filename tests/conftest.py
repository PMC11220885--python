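"""Shared fixtures: geometries, phantom molecules, and desk-scale datasets.

Heavy artefacts (the 500-pattern noise-free dataset, the CM convergence
runs, the 32^3 phasing panel) are session-scoped so the orientation,
convergence-ordering and metric tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from spirecon.geometry import DetectorGeometry
from spirecon.orient import CMConfig, run_cm
from spirecon.phantom import PhantomSpec, desk_dataset, perturb_model, phantom_model
from spirecon.phasing import make_support
from spirecon.scatter import AtomicModel, build_reference_volume, model_to_density
from spirecon.simulate import SimulationParams


@pytest.fixture(scope="session")
def geom64() -> DetectorGeometry:
    """64^2 desk detector: 1 A beam, 300 um pixels, 0.1 m camera."""
    return DetectorGeometry(wavelength=1.0, n_pixels=64, pixel_size=300.0, distance=0.1)


@pytest.fixture(scope="session")
def blob_model() -> AtomicModel:
    """150 carbon-like atoms, Rg 12 A — the small-dataset phantom."""
    return phantom_model(PhantomSpec(n_atoms=150, radius_of_gyration_target=12.0, seed=1))


@pytest.fixture(scope="session")
def ref_volume(blob_model, geom64):
    return build_reference_volume(blob_model, geom64)


@pytest.fixture(scope="session")
def noiseless_params() -> SimulationParams:
    return SimulationParams(photons_per_pulse=2e15, poisson=False)


@pytest.fixture(scope="session")
def tiny_ds():
    """50 noiseless snapshots of the tiny phantom (32^2 detector)."""
    return desk_dataset("tiny")


@pytest.fixture(scope="session")
def small_nf():
    """Noise-free variant of the small dataset: 500 snapshots, 64^2 detector."""
    return desk_dataset("small", noise=False)


@pytest.fixture(scope="session")
def cm_small_accuracy(small_nf):
    """PM-aided CM run on the noise-free small dataset with the true-model
    reference at delta_beta 0.1 + 0.02 refinement (orientation-recovery arm)."""
    cfg = CMConfig(delta_beta=0.1, refine_delta_beta=0.02, max_iters=2)
    return run_cm(small_nf.stack, cfg, reference=small_nf.truth_volume)


@pytest.fixture(scope="session")
def cm_convergence_pair(small_nf):
    """PM-aided vs random-init CM traces on the same dataset (delta_beta 0.2)."""
    cfg = CMConfig(delta_beta=0.2, refine_delta_beta=None, max_iters=12, tol=5e-4)
    pm = run_cm(small_nf.stack, cfg, reference=small_nf.reference_volume, seed=2)
    rand = run_cm(small_nf.stack, cfg, reference=None, seed=2)
    return pm, rand


class PhasingPanel:
    """32^3 band-limited phantom with analytic amplitudes and prior phases."""

    def __init__(self) -> None:
        self.model = phantom_model(PhantomSpec(60, 9.0, seed=4))
        self.predicted = perturb_model(self.model, 1.5, seed=5)
        self.dimension = 32
        self.pitch = 2.0
        self.support = make_support(self.model.extent, self.pitch, self.dimension, 1.2)
        # clip the faint Gaussian tails so the ground-truth object is exactly
        # supported (consistent data for the fixed-point checks)
        truth = model_to_density(self.model, spacing=self.pitch, sigma=2.0,
                                 dimension=self.dimension).values
        self.truth = truth * self.support
        f = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(self.truth)))
        self.amplitudes = np.abs(f)
        self.true_phases = np.angle(f)
        pd = model_to_density(self.predicted, spacing=self.pitch, sigma=2.0,
                              dimension=self.dimension).values
        self.prior_phases = np.angle(np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(pd))))


@pytest.fixture(scope="session")
def phasing_panel() -> PhasingPanel:
    return PhasingPanel()


def centered_ifft(volume: np.ndarray) -> np.ndarray:
    """Real part of the inverse FFT of a centered-layout complex volume."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(volume))).real
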