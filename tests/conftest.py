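import numpy as np
import pytest

from genomesurvey.depthmodel import DepthWindow


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_depth_windows(depths, scaffold="s1", width=500, gc=0.4):
    """Windows with both raw and corrected depth set to the given values."""
    return [
        DepthWindow(
            scaffold,
            i * width,
            (i + 1) * width,
            gc_fraction=gc,
            n_fraction=0.0,
            raw_depth=float(d),
            corrected_depth=float(d),
        )
        for i, d in enumerate(depths)
    ]


@pytest.fixture
def depth_windows_factory():
    return make_depth_windows
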