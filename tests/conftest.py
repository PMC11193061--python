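import random

import pytest

from tagmux import build_index, demo_config


@pytest.fixture(scope="session")
def demo_cfg():
    return demo_config()


@pytest.fixture(scope="session")
def demo_index(demo_cfg):
    return build_index(demo_cfg.tags)


def clean_filler(index, length, rng=None, forbidden_prefix=""):
    """Random padding whose every window (in context of an optional prefix)
    misses the tag index, so planted content is the only signal."""
    rng = rng or random.Random(0)
    for _ in range(500):
        filler = "".join(rng.choice("ACGT") for _ in range(length))
        joined = forbidden_prefix + filler
        if all(
            joined[i : i + L] not in index.table
            for L in index.lengths
            for i in range(len(joined) - L + 1)
        ):
            return filler
    raise AssertionError("could not build index-clean filler")
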