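import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ankylotherm.structures import Atom, Residue, ResidueSequence, StructureModel
from ankylotherm.synthetic import (
    RepeatGeometrySpec,
    make_charge_fixture,
    make_repeat_structure,
    notch_ternary_complex,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ideal_domain() -> StructureModel:
    """Three-repeat idealized ankyrin structure, Notch-style numbering."""
    return make_repeat_structure(RepeatGeometrySpec(n_repeats=3, start_number=1872))


@pytest.fixture(scope="session")
def ternary_complex() -> StructureModel:
    return notch_ternary_complex()


@pytest.fixture(scope="session")
def two_cluster_fixture():
    return make_charge_fixture([((0.0, 0.0, 0.0), 4, -1), ((80.0, 0.0, 0.0), 3, -1)])


@pytest.fixture()
def single_residue_model() -> StructureModel:
    res = Residue("A", 1, "GLY", [Atom("CA", "C", np.zeros(3))])
    return StructureModel("fixture", {"A": [res]})


def make_seq(letters: str, start: int = 1, sid: str = "seq") -> ResidueSequence:
    return ResidueSequence(sid, letters, list(range(start, start + len(letters))))
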