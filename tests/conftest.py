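import numpy as np
import pytest
from hypothesis import settings

from caiso.reduction import BlockType, IsotopeCycleBlock

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def make_block(
    block_id: str,
    block_type: BlockType,
    run_index: int,
    i42,
    i43,
    i435,
    i44,
    label: str = "",
) -> IsotopeCycleBlock:
    """Build a block from scalars (constant cycles) or arrays."""
    def arr(x, n):
        x = np.asarray(x, float)
        return np.full(n, float(x)) if x.ndim == 0 else x

    n = max(np.asarray(x).size for x in (i42, i43, i435, i44))
    n = max(n, 2)
    return IsotopeCycleBlock(
        block_id=block_id,
        block_type=block_type,
        run_index=run_index,
        intensity_42=arr(i42, n),
        intensity_43=arr(i43, n),
        intensity_43p5=arr(i435, n),
        intensity_44=arr(i44, n),
        label=label,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
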