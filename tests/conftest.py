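import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes dp_oracle importable

from thdpnum import build_profile  # noqa: E402
from thdpnum.synthetic import make_family  # noqa: E402


@pytest.fixture(scope="session")
def small_family():
    """A compact homolog family with indels and known ground truth."""
    return make_family(seed=11, n=8, length=120, identity=0.7,
                       indel_rate=0.03, mean_indel_len=2.0)


@pytest.fixture(scope="session")
def small_profile(small_family):
    profile, refmap = build_profile(small_family.alignment, "ref")
    return profile, refmap
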