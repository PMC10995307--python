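import pytest

from herbmine import corpus_synth as cs
from herbmine import extraction as ex


@pytest.fixture(scope="session")
def small_synth():
    """A 300-entry synthetic corpus with the default planted pairs."""
    spec = cs.default_spec(n_entries=300, seed=11)
    texts, gt = cs.generate_corpus(spec)
    return spec, texts, gt


@pytest.fixture(scope="session")
def small_transactions(small_synth):
    spec, texts, gt = small_synth
    entries = [(t.entry_id, text) for t, text in zip(gt.transactions, texts)]
    phyla = {t.entry_id: t.phylum for t in gt.transactions}
    annotated = ex.annotate_corpus(entries, spec.lexicon, phyla)
    return ex.build_transactions(annotated)
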