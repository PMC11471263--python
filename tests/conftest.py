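import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from fabkit.fixtures import (FixtureSpec, build_reference_set,
                             make_reference_fixture, make_structure_fixture)


@pytest.fixture(scope="session")
def spec7() -> FixtureSpec:
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def refset(spec7):
    return build_reference_set(spec7)


@pytest.fixture(scope="session")
def ref_workspace(spec7, tmp_path_factory):
    """Reference fixture written to disk: (fasta, sidecar, refset)."""
    out = tmp_path_factory.mktemp("refs")
    return make_reference_fixture(spec7, out)


@pytest.fixture(scope="session")
def fab_structure(spec7, tmp_path_factory):
    """Default Fab-layout structure fixture: (cif_path, truth_path)."""
    out = tmp_path_factory.mktemp("struct")
    return make_structure_fixture(spec7, {"entry_id": "FX0001"}, out)
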