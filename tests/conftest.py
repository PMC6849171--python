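import pytest

from kneetext.features import default_schemas, load_default_resources


@pytest.fixture(scope="session")
def resources():
    return load_default_resources()


@pytest.fixture(scope="session")
def minilex(resources):
    return resources.minilexicon


@pytest.fixture(scope="session")
def schemas():
    return default_schemas()


@pytest.fixture()
def tiny_lexicon(tmp_path):
    """Three-synonym concept plus a couple of distractors, written to TSV."""
    p = tmp_path / "lex.tsv"
    p.write_text(
        "concept_id\tname\tsemantic_type\n"
        "C1\tswelling\tsosy\n"
        "C1\tedema\tsosy\n"
        "C1\toedema\tsosy\n"
        "C2\tknee\tanat\n"
        "C3\tphysiotherapy\tproc\n"
        "C3\tphysio\tproc\n"
    )
    return p
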