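import numpy as np
import pytest

from lesionft.io import AnnotatedCase
from lesionft.nn.model import ModelConfig, build_model
from lesionft.synthetic import SyntheticCohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """A miniature but structurally complete network configuration."""
    return ModelConfig(channels_per_pathway=(2, 1), kernels_per_conv=4,
                       head_channels=(8, 2))


@pytest.fixture(scope="session")
def tiny_net(tiny_model_cfg):
    return build_model(tiny_model_cfg, np.random.default_rng(0))


@pytest.fixture(scope="session")
def small_cohort():
    """Four quickly generated baseline/follow-up pairs."""
    cfg = SyntheticCohortConfig(n_train_patients=2, n_test_patients=2,
                                volume_shape=(8, 64, 64),
                                lesion_radius_range_vox=(1.5, 3.0), seed=11)
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def synthetic_case():
    """One annotated baseline case on a small grid."""
    cfg = SyntheticCohortConfig(n_train_patients=0, n_test_patients=1,
                                volume_shape=(8, 64, 64),
                                lesion_radius_range_vox=(1.5, 3.0), seed=5)
    return simulate_cohort(cfg)[0][0]


@pytest.fixture(scope="session")
def mini_trained():
    """A quickly trained base model plus held-out test patients.

    Sizes and learning rate are chosen for a roughly one-minute build that
    still reaches a clearly non-trivial segmentation quality."""
    from lesionft.training import TrainConfig, train_base
    cfg = SyntheticCohortConfig(n_train_patients=4, n_test_patients=5,
                                volume_shape=(8, 56, 56),
                                lesion_radius_range_vox=(1.5, 3.0), seed=41)
    cohort = simulate_cohort(cfg)
    train_cases = [b for b, _ in cohort[:4]]
    test_pairs = cohort[4:]
    model_cfg = ModelConfig.scaled(8, channels_per_pathway=(2, 1))
    train_cfg = TrainConfig(iterations=600, patch_size=48,
                            patches_per_slice=10, checkpoint_every=300,
                            learning_rate=5e-4, seed=41)
    net, _ = train_base(train_cases, model_cfg, train_cfg)
    return net, model_cfg, test_pairs


def make_case(shape=(4, 16, 16), channels=(2, 1), organ=None, lesion=None,
              spacing=(1.0, 1.0, 1.0), patient_id="t0",
              timepoint="baseline", seed=0):
    """Hand-assembled AnnotatedCase for geometry-level tests."""
    rng = np.random.default_rng(seed)
    if organ is None:
        organ = np.ones(shape, np.uint8)
    sequences = [rng.random(shape + (c,)).astype(np.float32)
                 for c in channels]
    return AnnotatedCase(patient_id=patient_id, timepoint=timepoint,
                         sequences=sequences, organ_mask=organ,
                         lesion_mask=lesion, spacing_mm=spacing)
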