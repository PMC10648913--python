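import numpy as np
import pytest

from refstab.io import CtMatrix, SampleMeta


def make_matrix(ct, genes=None, treatment="SA", times=None) -> CtMatrix:
    """CtMatrix from a 2-D array with minimal valid metadata."""
    ct = np.asarray(ct, dtype=float)
    n_genes, n_samples = ct.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    times = times if times is not None else [2.0] * n_samples
    meta = {
        s: SampleMeta(s, treatment, times[j], j + 1)
        for j, s in enumerate(samples)
    }
    return CtMatrix(genes=list(genes), samples=samples, ct=ct, meta=meta)


@pytest.fixture
def abc_matrix() -> CtMatrix:
    """Three-gene worked example: A and B perfectly co-vary, C is flat."""
    return make_matrix(
        [[20.0, 21.0, 22.0, 23.0],
         [30.0, 31.0, 32.0, 33.0],
         [25.0, 25.0, 25.0, 25.0]],
        genes=["A", "B", "C"],
    )
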