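import pytest

from songlearn.corpus import SyntheticCorpusSpec, generate_synthetic_corpus
from songlearn.learning import ExperimentConfig, run_learning


@pytest.fixture(scope="session")
def motif_corpus():
    """Planted-motif corpus at the standard study conditions."""
    spec = SyntheticCorpusSpec(seed=1)
    songs, motifs = generate_synthetic_corpus(spec)
    return spec, songs, motifs


@pytest.fixture(scope="session")
def trained_run(motif_corpus):
    """A full 15-trial learning run on the standard corpus (shared)."""
    _, songs, motifs = motif_corpus
    snapshots, metrics = run_learning(songs, ExperimentConfig(n_trials=15, seed=1))
    return snapshots, metrics, motifs
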