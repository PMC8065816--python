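import numpy as np
import pytest

from sweepconv.pipeline import demo


@pytest.fixture(scope="session")
def demo_run():
    """One full end-to-end demo run (simulation + all stages), shared across
    tests because the nSL scan over 24k SNPs x 200 haplotypes dominates the
    suite's runtime."""
    return demo(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
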