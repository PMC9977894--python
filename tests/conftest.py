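import numpy as np
import pytest

from groupcapsnet.capsule_core import (CapsuleField, GroupPartition,
                                       WeightBank)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bank(in_types, out_types, in_dim, out_dim, g, kernel=(3, 3),
              kernel_shared=False, seed=0, dtype=np.float64):
    """Randomly initialised weight bank (float64 for tight comparisons)."""
    return WeightBank(in_types, out_types, in_dim, out_dim, kernel,
                      GroupPartition(g, in_types), kernel_shared,
                      rng=np.random.default_rng(seed), dtype=dtype,
                      name=f"test[{in_types}->{out_types},g={g}]")


def make_field(batch, h, w, t, d, seed=0, dtype=np.float64):
    vals = np.random.default_rng(seed).normal(0, 0.5, (batch, h, w, t, d))
    return CapsuleField(vals.astype(dtype))
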