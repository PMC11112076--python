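import warnings

import numpy as np
import pytest

from tmsclean import artifact_sim, ground_truth, headmodel

warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-scale generator config used by most integration tests."""
    return ground_truth.GroundTruthConfig(n_trials=24, fs=1000.0, seed=1)


@pytest.fixture(scope="session")
def small_gt(small_cfg):
    return ground_truth.generate_ground_truth(small_cfg)


@pytest.fixture(scope="session")
def bank():
    return artifact_sim.ArtifactTopographyBank()


@pytest.fixture(scope="session")
def montage60():
    return headmodel.build_montage_1020(60)


@pytest.fixture(scope="session")
def sir_leadfield(montage60):
    return headmodel.compute_leadfield(
        ground_truth.neuronal_head_model(),
        headmodel.shell_source_space(),
        montage60,
    )


@pytest.fixture(scope="session")
def corrupted_small(small_gt, bank):
    """alpha=0, contrast 1/200, 250 μV corruption of the small dataset."""
    cond = artifact_sim.ArtifactCondition(
        alpha=0.0, contrast=1.0 / 200.0, amplitude_uv=250.0, seed=5
    )
    real = artifact_sim.simulate_realization(
        cond, small_gt.times, small_gt.fs, small_gt.n_trials,
        bank=bank, rng=np.random.default_rng(42),
    )
    return artifact_sim.superpose(small_gt, real), real
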