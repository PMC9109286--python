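import pytest

from icd11kit import (
    EntityRecord,
    Foundation,
    SynthParams,
    assign_codes,
    default_config,
    derive_linearization,
    generate_foundation,
    generate_sanctioning_rules,
    insert_residuals,
    paper_fixture,
)


def make_entity(uri, title=None, parents=(), **kwargs):
    """Minimal content-model-complete record for graph-shape tests."""
    title = title or uri.rsplit(":", 1)[-1]
    return EntityRecord(
        uri=uri,
        concept_title={"en": title},
        fully_specified_name={"en": f"{title} (fsn)"},
        brief_definition=f"{title}.",
        parent_uris=tuple(parents),
        **kwargs,
    )


def small_foundation(edges, root="urn:t:root"):
    """Foundation from a {child: [parents]} edge dict; parents may reference
    the root as 'root'."""
    f = Foundation(root, "Test root")
    resolve = lambda u: root if u == "root" else u
    for child, parents in edges.items():
        f.add_entity(make_entity(child, parents=[resolve(p) for p in parents]))
    return f


def pipeline(foundation, config):
    """Derive + residuals + codes in one step."""
    lin = insert_residuals(derive_linearization(foundation, config), foundation)
    return lin, assign_codes(lin)


@pytest.fixture(scope="session")
def fixture_triple():
    return paper_fixture()


@pytest.fixture(scope="session")
def seed7_foundation():
    return generate_foundation(SynthParams(seed=7, n_entities=50, n_chapters=3))


@pytest.fixture(scope="session")
def seed7_pipeline(seed7_foundation):
    config = default_config(seed7_foundation)
    lin, assignment = pipeline(seed7_foundation, config)
    return seed7_foundation, config, lin, assignment


@pytest.fixture(scope="session")
def seed4_foundation():
    return generate_foundation(SynthParams(seed=4, n_entities=60, n_chapters=3))


@pytest.fixture(scope="session")
def seed9_ruleset():
    params = SynthParams(seed=9, n_entities=120, n_chapters=4, n_equivalences=10)
    foundation = generate_foundation(params)
    rules = generate_sanctioning_rules(foundation, params)
    return foundation, rules
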