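import numpy as np
import pytest

import methcorr as mc


@pytest.fixture
def tiny_meth():
    """3 probes x 2 samples, one missing β."""
    beta = np.array([[0.1, 0.9], [0.5, np.nan], [0.0, 1.0]])
    return mc.MethylationMatrix(["cg01", "cg02", "cg03"], ["A", "B"], beta)


#: samples used for training; the rest of the cohort is held out
N_TRAIN = 150


@pytest.fixture(scope="session")
def small_cohort():
    """Matched synthetic cohort small enough for per-test training.

    The first N_TRAIN samples are the training cohort; the remaining
    samples share the same ground truth and serve as an external held-out
    cohort for inference tests.
    """
    spec = mc.SyntheticSpec(
        n_samples=200, n_signal_genes=20, n_null_genes=20,
        probes_per_gene_pos=6, probes_per_gene_neg=6,
        signal_fraction=0.6, seed=42,
    )
    meth, expr, truth = mc.generate(spec)
    return spec, meth, expr, truth


@pytest.fixture(scope="session")
def trained(small_cohort):
    """A model store trained once on the small cohort, shared across tests."""
    _, meth, expr, _ = small_cohort
    train_ids = meth.sample_ids[:N_TRAIN]
    config = mc.MethcorrConfig(seed=7)
    store = mc.train(
        meth.subset_samples(train_ids), expr.subset_samples(train_ids),
        config, cancer_type="synthetic", platform="450K")
    return config, store
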