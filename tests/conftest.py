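from __future__ import annotations

import numpy as np
import pytest

from tickpi import default_config, generate_scenario
from tickpi.records import CANONICAL_AA

_AA = np.array(list(CANONICAL_AA))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def scenario():
    """One mini repertoire scenario (3 species, 6 families, planted truth)."""
    return generate_scenario(default_config(1))


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory):
    """The same scenario written to disk as the pipeline input contract."""
    out = tmp_path_factory.mktemp("scenario")
    generate_scenario(default_config(1), out_dir=out)
    return out
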