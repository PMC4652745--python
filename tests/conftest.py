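import numpy as np
import pytest

from ruvmeth.core import ControlSet, DesignSpec, MethylationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, prefix_s="s", prefix_f="f"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return MethylationMatrix(
        values,
        tuple(f"{prefix_s}{i}" for i in range(n)),
        tuple(f"{prefix_f}{j}" for j in range(m)),
    )


def simple_design(n, x=None):
    if x is None:
        x = np.zeros(n)
        x[n // 2 :] = 1.0
    return DesignSpec(X=np.asarray(x, dtype=float)[:, None], Z=np.ones((n, 1)))


@pytest.fixture
def small_design():
    return simple_design(6)


def all_controls(mat) -> ControlSet:
    return ControlSet(mat.feature_ids, origin="user")
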