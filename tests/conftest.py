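import pytest

from qsconsensus.fixtures import CorpusSpec, make_corpus
from qsconsensus.textmining import SentenceRecord, train_classifier


def corpus_records(spec: CorpusSpec, seed: int) -> list[SentenceRecord]:
    tsv = make_corpus(spec, seed=seed)
    records = []
    for line in tsv.strip().split("\n"):
        label, sentence = line.split("\t", 1)
        records.append(SentenceRecord(text=sentence, label=label))
    return records


@pytest.fixture(scope="session")
def separable_corpus():
    """200+200 sentences with disjoint class filler vocabularies."""
    return corpus_records(CorpusSpec(n_pos=200, n_neg=200, vocab_overlap=0.0), seed=11)


@pytest.fixture(scope="session")
def trained_svm(separable_corpus):
    """SVM sentence classifier trained once on the separable corpus."""
    model, metrics = train_classifier(separable_corpus, seed=0)
    return model, metrics
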