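from __future__ import annotations

import numpy as np
import pytest

import mldstnet as m


@pytest.fixture(scope="session")
def phantoms30():
    """Balanced 30-image phantom dataset (10 per class, 64 px)."""
    return m.generate_phantom_dataset(10, m.PhantomSpec(image_size=64), seed=5)


@pytest.fixture(scope="session")
def tiny_cnn_config():
    """Smallest config that still exercises all four blocks."""
    return m.CNNConfig(
        input_size=16, kernel_sizes=(3, 3, 3, 3), filters=(4, 4, 4, 8),
        fc_units=16, epochs=3, learning_rate=0.02, batch_size=4, seed=0,
    )


@pytest.fixture(scope="session")
def separable_features():
    """Linearly separable 2-feature, 3-class point clouds (n=150)."""
    rng = np.random.default_rng(0)
    X = np.vstack(
        [
            rng.normal([0, 0], 0.5, (50, 2)),
            rng.normal([4, 0], 0.5, (50, 2)),
            rng.normal([0, 4], 0.5, (50, 2)),
        ]
    )
    labels = ["benign"] * 50 + ["malignant"] * 50 + ["ignorant"] * 50
    return X, labels


def _random_mass(rng: np.random.Generator) -> m.MassFunction:
    v = rng.dirichlet(np.ones(3))
    return m.MassFunction.from_array(v)


@pytest.fixture
def random_mass_factory():
    return _random_mass


@pytest.fixture(scope="session")
def e2e_run():
    """The reference end-to-end experiment: 150 phantoms (50/class, 128 px),
    5-fold CV, desk-scale CNN — run twice under the same master seed.

    Session-scoped because the two runs dominate the suite's runtime.
    """
    import tempfile

    from mldstnet.pipeline import PipelineConfig, SyntheticOptions, run_pipeline

    reports = []
    for _ in range(2):
        cfg = PipelineConfig(
            out_dir=tempfile.mkdtemp(prefix="mldst_e2e_"),
            synthetic=SyntheticOptions(n_per_class=50, image_size=128),
            seed=11,
            log_level="WARNING",
        )
        report, artifacts = run_pipeline(cfg)
        reports.append((report, artifacts))
    return reports
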