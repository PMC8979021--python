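import numpy as np
import pytest

from smireg.negative_sampling import sample_negatives
from smireg.pair_data import load_pairs
from smireg.synthetic_data import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    cfg = SyntheticConfig(
        n_families=4,
        molecules_per_family=6,
        n_mirnas=50,
        fingerprint_noise=0.05,
        label_noise=0.0,
        seed=3,
    )
    corpus = generate_corpus(cfg)
    out = tmp_path_factory.mktemp("corpus")
    corpus.write(out)
    return out


@pytest.fixture(scope="session")
def corpus(corpus_dir):
    # regenerate in memory (deterministic) so tests can reach ground truth
    return generate_corpus(
        SyntheticConfig(
            n_families=4,
            molecules_per_family=6,
            n_mirnas=50,
            fingerprint_noise=0.05,
            label_noise=0.0,
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def datasets(corpus_dir):
    return load_pairs(
        corpus_dir / "pairs.tsv",
        corpus_dir / "mirnas.fasta",
        fingerprints=corpus_dir / "fingerprints.tsv",
    )


@pytest.fixture(scope="session")
def up_balanced(datasets):
    """Up-direction dataset augmented to positive/negative balance."""
    other = {(p.sm_id, p.mirna_id) for p in datasets["down"].positives}
    return sample_negatives(datasets["up"], seed=5, other_direction_positives=other)


@pytest.fixture(scope="session")
def trained_bundle(up_balanced):
    from smireg.model_training import train_direction

    bundle, _report = train_direction(
        up_balanced, algorithms=["rf"], grids={"rf": [21]}, seed=9
    )
    return bundle


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
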