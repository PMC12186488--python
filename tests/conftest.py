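"""Shared fixtures: tiny hand-built ontologies and a synthetic study."""

import logging

import pytest

from gocollapse.ontology import OntologyGraph, parse_obo
from gocollapse.synthetic import make_two_species_fixture


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    """Keep expected data-cleaning warnings out of the test output."""
    logging.getLogger("gocollapse").setLevel(logging.ERROR)
    yield


DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: left
namespace: molecular_function
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: right
namespace: molecular_function
is_a: GO:0000001 ! root

[Term]
id: GO:0000004
name: bottom
namespace: molecular_function
is_a: GO:0000002 ! left
is_a: GO:0000003 ! right
"""


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    """D is_a B, D is_a C, B is_a A, C is_a A."""
    return parse_obo(DIAMOND_OBO)


@pytest.fixture(scope="session")
def study():
    """A default two-species synthetic study, generated once per session."""
    return make_two_species_fixture(seed=20250922 % (2**31))


def pipeline_inputs(fixture):
    """Parse a fixture bundle into (graph, {label: (ann, de_table)})."""
    from io import StringIO

    from gocollapse.de import read_de_table
    from gocollapse.ontology import propagate, read_annotations

    graph = parse_obo(fixture.obo_text)
    species = {}
    for label in fixture.labels:
        de = read_de_table(StringIO(fixture.de_text[label]), label)
        pairs = read_annotations(fixture.annotation_text[label])
        ann = propagate(graph, pairs, de.genes, "molecular_function", label)
        species[label] = (ann, de)
    return graph, species
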