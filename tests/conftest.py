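import pytest

from lateralis import ontology as onto
from lateralis import synthdata as synth

TOY_OBO = """format-version: 1.2

[Term]
id: T:root
name: root

[Term]
id: T:A
name: branch A
is_a: T:root

[Term]
id: T:B
name: leaf B
is_a: T:A

[Term]
id: T:C
name: leaf C
is_a: T:A

[Term]
id: T:D
name: branch D
is_a: T:root

[Term]
id: T:E
name: leaf E
is_a: T:D

[Term]
id: T:F
name: leaf F
is_a: T:D
"""


@pytest.fixture(scope="session")
def toy_obo_path(tmp_path_factory):
    p = tmp_path_factory.mktemp("obo") / "toy.obo"
    p.write_text(TOY_OBO)
    return p


@pytest.fixture(scope="session")
def toy_graph(toy_obo_path):
    return onto.load_obo(toy_obo_path)


@pytest.fixture(scope="session")
def toy_cohort(toy_graph):
    """Four probands, one leaf each: {B}, {C}, {E}, {F} (closed)."""
    raw = {"p1": {"T:B"}, "p2": {"T:C"}, "p3": {"T:E"}, "p4": {"T:F"}}
    return {p: onto.annotation_closure(t, toy_graph) for p, t in raw.items()}


@pytest.fixture(scope="session")
def toy_ic(toy_cohort, toy_graph):
    return onto.compute_ic(toy_cohort, toy_graph)


@pytest.fixture(scope="session")
def mini_obo_path(tmp_path_factory):
    p = tmp_path_factory.mktemp("mini") / "mini.obo"
    synth.gen_mini_ontology(p)
    return p


@pytest.fixture(scope="session")
def mini_graph(mini_obo_path):
    return onto.load_obo(mini_obo_path)
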