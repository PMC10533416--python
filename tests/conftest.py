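import numpy as np
import pytest

import crowdseg as cs


def binary_cm(diag: float) -> np.ndarray:
    """Symmetric 2x2 column-stochastic CM with the given diagonal."""
    return np.array([[diag, 1.0 - diag], [1.0 - diag, diag]])


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained coupled model for contract tests."""
    cfg = cs.ModelConfig(n_classes=2, n_annotators=3, encoder_channels=(4, 8))
    return cs.CoupledModel(cfg, seed=0)


@pytest.fixture(scope="session")
def cm_dataset():
    """Dense dataset with three exact-CM annotators (diagonals .9/.8/.7)."""
    personas = [
        cs.AnnotatorPersona(kind="cm_corruptor", annotator_id=i, cm=binary_cm(d))
        for i, d in enumerate((0.9, 0.8, 0.7))
    ]
    gts = cs.generate_shapes(24, 32, 32, 2, seed=5)
    return cs.build_dataset(gts, personas, label_density="dense", seed=5)


@pytest.fixture(scope="session")
def mixed_personas():
    """Five annotators spanning the simulated corruption types."""
    return [
        cs.AnnotatorPersona(kind="over_segmenter", annotator_id=0, strength=2),
        cs.AnnotatorPersona(kind="under_segmenter", annotator_id=1, strength=2),
        cs.AnnotatorPersona(kind="class_confuser", annotator_id=2, strength=0.3),
        cs.AnnotatorPersona(kind="cm_corruptor", annotator_id=3, cm=binary_cm(0.925)),
        cs.AnnotatorPersona(kind="cm_corruptor", annotator_id=4, cm=binary_cm(0.825)),
    ]
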