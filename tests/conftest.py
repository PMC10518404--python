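import numpy as np
import pytest

from qcdseg import PhantomConfig, generate_cohort, partition_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Independent per-pixel Dice: explicit loops, no vectorisation shared
    with the implementation."""
    inter = size_a = size_b = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            av, bv = bool(a[i, j]), bool(b[i, j])
            inter += av and bv
            size_a += av
            size_b += bv
    if size_a + size_b == 0:
        return 1.0
    return 2.0 * inter / (size_a + size_b)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small dual-mode cohort shared by training-dependent tests."""
    return generate_cohort(PhantomConfig(seed=7), n_patients=8,
                           slices_per_patient=2)


@pytest.fixture(scope="session")
def tiny_split(tiny_cohort):
    return partition_cohort(tiny_cohort, fractions=(0.6, 0.2, 0.2), seed=7)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_split):
    """Quickly trained 2-member ensemble (depths 1-2) for interface tests."""
    from qcdseg import NetworkSpec, TrainingConfig, train_ensemble

    train, val, _ = tiny_split
    specs = [NetworkSpec(depth=d, base_filters=4, input_size=64)
             for d in (1, 2)]
    cfg = TrainingConfig(learning_rate=1e-3, max_epochs=2,
                         early_stop_patience=2, batch_size=8, seed=7)
    return train_ensemble(train, val, specs, cfg)
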