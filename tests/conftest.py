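import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hostsieve import extract_matrix
from hostsieve.partition import PHAGE, label_viruses
from hostsieve.synthetic import CorpusSpec, generate_corpus, transition_matrix

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def separated_corpus():
    """Two-class synthetic corpus with strongly separated composition."""
    return generate_corpus(CorpusSpec(seed=1))


@pytest.fixture(scope="session")
def corpus_Xy(separated_corpus):
    """Feature matrix and phage/eukaryote labels for the separated corpus."""
    labeled = label_viruses(separated_corpus)
    labels = {v.id: int(v.label == PHAGE) for v in labeled}
    X = extract_matrix(separated_corpus)
    y = np.array([labels[i] for i in X.index])
    return X.to_numpy(), y


@pytest.fixture(scope="session")
def null_corpus_Xy():
    """Null-control corpus: both classes share one composition model."""
    shared = transition_matrix(gc=0.5, persistence=0.2)
    spec = CorpusSpec(
        seed=3,
        phage_transitions=shared,
        eukaryote_transitions=shared,
        phage_dna_fraction=0.5,
        eukaryote_dna_fraction=0.5,
    )
    records = generate_corpus(spec)
    labeled = label_viruses(records)
    labels = {v.id: int(v.label == PHAGE) for v in labeled}
    X = extract_matrix(records)
    y = np.array([labels[i] for i in X.index])
    return X.to_numpy(), y
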