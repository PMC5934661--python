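import numpy as np
import pytest

import iwscoring as iw
from iwscoring.synthetic import identity_system_specs


@pytest.fixture(scope="session")
def small_model():
    """A model trained on a small synthetic training set (identity transforms)."""
    cfg = iw.SimulationConfig(n_variants=4000, seed=3)
    matrix, labels, _ = iw.generate_two_class_scores(cfg)
    model = iw.train(matrix, "K11", seed=7, reference_size=1500,
                     system_specs=identity_system_specs(matrix.systems))
    return model, matrix, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_matrix(values, systems=None, chrom="chr1"):
    """Build a ScoreMatrix from a plain array with synthetic variant keys."""
    values = np.asarray(values, dtype=float)
    systems = systems or [f"s{i}" for i in range(values.shape[1])]
    keys = [iw.VariantKey(chrom, i + 1, "A", "T") for i in range(values.shape[0])]
    return iw.ScoreMatrix(keys, list(systems), values)
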