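import numpy as np
import pandas as pd
import pytest

from pathsampler import ExpressionDataset, SyntheticSpec, generate_two_class_dataset


def make_dataset(matrix, probe_ids, sample_ids, labels, case_label="case",
                 control_label="control"):
    """Hand-built ExpressionDataset from a samples-last (probes x samples) array."""
    values = pd.DataFrame(np.asarray(matrix, dtype=float),
                          index=probe_ids, columns=sample_ids)
    return ExpressionDataset(
        values=values,
        labels=pd.Series(list(labels), index=sample_ids),
        case_label=case_label,
        control_label=control_label,
    )


@pytest.fixture
def tiny_dataset():
    """3 probes x 4 samples, 2 per class."""
    return make_dataset(
        [[1.0, 2.0, 7.5, 8.0],
         [5.0, 5.5, 5.2, 5.1],
         [3.0, 3.25, 1.0, 0.5]],
        probe_ids=["PA", "PB", "PC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        labels=["case", "case", "control", "control"],
    )


@pytest.fixture
def separable_dataset():
    """One perfectly separating planted probe among 50 background probes."""
    spec = SyntheticSpec(n_samples_per_class=(10, 10), n_probes=50,
                         n_informative=1, effect_size=8.0, noise_sd=1.0, seed=11)
    return generate_two_class_dataset(spec)


def random_two_class(rng, n_per_class=(4, 4), n_probes=3):
    """Unstructured random dataset for oracle-equivalence sweeps."""
    n = sum(n_per_class)
    values = rng.normal(size=(n_probes, n))
    probe_ids = [f"g{i}" for i in range(n_probes)]
    sample_ids = [f"s{i}" for i in range(n)]
    labels = ["case"] * n_per_class[0] + ["control"] * n_per_class[1]
    return make_dataset(values, probe_ids, sample_ids, labels)
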