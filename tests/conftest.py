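import pytest

from eugene.fixtures import (
    build_csd_fixture,
    build_pt_fixture,
    build_registry_fixture,
    build_repressilator_fixture,
    run_fixture,
)
from eugene.model import Device, PartInstance


def make_part(name: str, part_type: str, **props) -> PartInstance:
    """Bare part instance for unit tests (values given as PrimitiveValue)."""
    return PartInstance(name, part_type, props)


@pytest.fixture(scope="session")
def csd_program():
    return build_csd_fixture()


@pytest.fixture(scope="session")
def csd_results(csd_program, tmp_path_factory):
    """Interpreter results for every stage of the cell-surface-display ladder."""
    base = tmp_path_factory.mktemp("csd")
    return {
        stage: run_fixture(csd_program, stage, workdir=base)
        for stage in csd_program.stages()
    }


@pytest.fixture(scope="session")
def pt_program():
    return build_pt_fixture()


@pytest.fixture(scope="session")
def pt_results(pt_program, tmp_path_factory):
    base = tmp_path_factory.mktemp("pt")
    return {
        stage: run_fixture(pt_program, stage, workdir=base)
        for stage in pt_program.stages()
    }


@pytest.fixture(scope="session")
def registry_result(tmp_path_factory):
    return run_fixture(build_registry_fixture(), workdir=tmp_path_factory.mktemp("reg"))


@pytest.fixture(scope="session")
def repressilator_result(tmp_path_factory):
    return run_fixture(
        build_repressilator_fixture(), workdir=tmp_path_factory.mktemp("rep")
    )


@pytest.fixture
def simple_device():
    """The two-part promoter/CDS device used throughout the language docs."""
    p1 = make_part("P1", "Promoter")
    gfp = make_part("GFP", "CDS")
    return Device("BBa_1", (p1, gfp))
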