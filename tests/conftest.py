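import pytest

from eventpost import GeneratorConfig, generate

FIG_TEXT = "IL-2 acts by enhancing binding activity of NF-κB to p55 ."

FIG_A1 = (
    "T1\tProtein 0 4\tIL-2\n"
    "T2\tProtein 43 48\tNF-κB\n"
    "T3\tProtein 52 55\tp55\n"
)

FIG_A2 = (
    "T4\tPositive_regulation 13 22\tenhancing\n"
    "T5\tBinding 23 30\tbinding\n"
    "E1\tBinding:T5 Theme:T2 Theme:T3\n"
    "E2\tPositive_regulation:T4 Cause:T1 Theme:E1\n"
)


@pytest.fixture
def fig_doc():
    """A nested positive-regulation-over-binding document."""
    from eventpost import read_standoff

    return read_standoff(FIG_A1, FIG_A2, FIG_TEXT, doc_id="fig")


@pytest.fixture(scope="session")
def small_corpus():
    """A 40-document synthetic corpus with ground truth (seed fixed)."""
    return generate(GeneratorConfig(n_documents=40, seed=11))
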