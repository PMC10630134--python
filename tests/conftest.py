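import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from chainani.params import SketchParams


@pytest.fixture(scope="session")
def params() -> SketchParams:
    """Default parameters (k=15, c=125, markers 21 @ 1/1000)."""
    return SketchParams()


@pytest.fixture(scope="session")
def tiny_params() -> SketchParams:
    """Dense, short-k parameters for small hand-checkable genomes:
    every 7-mer is a seed, every other 9-mer a marker."""
    return SketchParams(k=7, marker_k=9, c=1, marker_c=2, chunk_size=200)
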