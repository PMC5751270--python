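import numpy as np
import pandas as pd
import pytest

from stressprofiler.io_core import (CountMatrix, SampleDescriptor, STRESSES,
                                    TISSUES, TIME_LABELS)


def make_samples() -> list[SampleDescriptor]:
    """The full 24-sample two-stress, three-tissue design."""
    out = []
    for stress in STRESSES:
        for tissue in TISSUES:
            for t in range(4):
                out.append(SampleDescriptor(
                    sample_id=f"{stress[0]}.{tissue}."
                              f"{TIME_LABELS[stress][t]}",
                    stress=stress, tissue=tissue, time_index=t,
                    role="control" if t == 0 else "treatment",
                ))
    return out


def make_counts(array, gene_ids=None, samples=None) -> CountMatrix:
    arr = np.asarray(array, dtype=np.int64)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(arr.shape[0])]
    if samples is None:
        samples = [
            SampleDescriptor(f"s{j}", "cold", "FL", j % 4,
                             "control" if j % 4 == 0 else "treatment")
            for j in range(arr.shape[1])
        ]
    df = pd.DataFrame(arr, index=pd.Index(gene_ids, name="gene_id"),
                      columns=[s.sample_id for s in samples])
    return CountMatrix(counts=df, samples=samples)


@pytest.fixture
def full_design_samples():
    return make_samples()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
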