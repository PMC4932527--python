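import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from otscreen.core_io import GenomeAssembly
from otscreen.synthetic_data import generate_genome, make_fixture
from otscreen.target_search import Guide


@pytest.fixture(scope="session")
def guide() -> Guide:
    return Guide(name="g1", protospacer="ACGTACGGTTCAGCTAAGCT")


@pytest.fixture(scope="session")
def small_genome() -> GenomeAssembly:
    return generate_genome({"chr1": 10_000, "chr2": 5_000}, seed=7)


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The default synthetic fixture (seed 42), generated once per session."""
    outdir = tmp_path_factory.mktemp("fixture") / "fx42"
    return make_fixture(outdir, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
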