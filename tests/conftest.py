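import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracle.py

from natrigem.sodium import build_halophile_core
from natrigem.synthetic import make_toy6


@pytest.fixture
def toy6():
    return make_toy6()


@pytest.fixture(scope="session")
def halophile_core():
    return build_halophile_core()


@pytest.fixture(scope="session")
def halophile_core_no_counter():
    return build_halophile_core(counter_proton=False)


@pytest.fixture
def toy6_sbml_path(tmp_path):
    from natrigem.sbml import write_sbml

    path = tmp_path / "toy6.xml"
    write_sbml(make_toy6(), str(path))
    return path
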