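import numpy as np
import pandas as pd
import pytest

from hspnet.io import ExpressionMatrix
from hspnet.simulate import default_spec, generate_cohort, hallmark_sets


@pytest.fixture(scope="session")
def reference_cohort():
    """The package's reference synthetic cohort (fixed seed)."""
    spec = default_spec(seed=1)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def reference_sets(reference_cohort):
    return {s.name: s for s in hallmark_sets(reference_cohort.truth.spec)}


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for pipeline smoke tests."""
    spec = default_spec(seed=3, n_tumor=80, n_normal=100, n_background=60,
                        n_signature=20)
    return spec, generate_cohort(spec)


@pytest.fixture()
def expr_matrix():
    """Tiny deterministic expression matrix helper."""
    def make(values, genes=None, samples=None, condition="tumor", cohort="T"):
        arr = np.asarray(values, dtype=float)
        genes = genes or [f"G{i}" for i in range(arr.shape[0])]
        samples = samples or [f"S{i}" for i in range(arr.shape[1])]
        return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples),
                                condition=condition, cohort=cohort)
    return make
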