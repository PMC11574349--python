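import warnings

import numpy as np
import pytest

from optoquant import simulate as sim

warnings.filterwarnings("ignore", message="Bad rank filter performance")


@pytest.fixture(scope="session")
def clean_nuclei_movie():
    """Small noiseless population movie with a DV gradient."""
    cfg = sim.default_nuclei_config(seed=2, n_frames=6,
                                    noise=sim.NoiseSpec(gaussian_sd=0.0))
    stack, truth = sim.simulate_nuclei_movie(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def flat_field_movie():
    """Uniformly bright nuclei, low jitter: resolvable-field fixture."""
    cfg = sim.default_nuclei_config(
        seed=5, n_frames=2, noise=sim.NoiseSpec(gaussian_sd=0.0),
        baseline_from_gradient=False, lattice_jitter_frac=0.05)
    stack, truth = sim.simulate_nuclei_movie(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def export_movie():
    """Noiseless export-mode movie (nuclear drop + cytoplasmic rise)."""
    cfg = sim.default_nuclei_config(mode="export", seed=3, n_frames=50,
                                    noise=sim.NoiseSpec(gaussian_sd=0.0))
    stack, truth = sim.simulate_nuclei_movie(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def sna_movie():
    """Default transcription-reporter movie (SNR 10, seed 0), short."""
    cfg = sim.default_foci_config(seed=0, n_frames=12)
    stack, truth = sim.simulate_foci_movie(cfg)
    return cfg, stack, truth


def match_points(detected: np.ndarray, truth: np.ndarray, tol: float):
    """Greedy nearest matching; returns (n_matched, n_det, n_truth)."""
    if len(detected) == 0 or len(truth) == 0:
        return 0, len(detected), len(truth)
    d = np.hypot(detected[:, 0, None] - truth[None, :, 0],
                 detected[:, 1, None] - truth[None, :, 1])
    n_match = int(((d.min(axis=1) <= tol)).sum())
    return n_match, len(detected), len(truth)
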