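import pytest

from rootsig import Bioset, CorpusSpec, generate_list_corpus


def make_bioset(bid, genes, experiment="E1", tissue="BLOOD"):
    return Bioset.from_symbols(bid, experiment, tissue, genes)


@pytest.fixture
def toy_corpus():
    """Three biosets with distinct, partially overlapping gene sets."""
    return [
        make_bioset("bs1", ["A", "B", "C"], "E1"),
        make_bioset("bs2", ["B", "C", "D"], "E1"),
        make_bioset("bs3", ["X", "Y"], "E2", "BRAIN"),
    ]


@pytest.fixture
def planted_spec():
    """27-bioset corpus with a 66-gene signature planted into 5 biosets
    spanning 3 of 9 experiments; batch structure dominates baseline."""
    return CorpusSpec(
        n_experiments=9,
        biosets_per_experiment=3,
        universe_size=2000,
        baseline_inclusion_prob=0.05,
        experiment_specific_genes=60,
        experiment_share_prob=0.7,
        signature_size=66,
        signature_biosets=("E1_B1", "E1_B2", "E2_B1", "E2_B2", "E3_B1"),
        signature_inclusion_prob=0.95,
        seed=1,
    )


@pytest.fixture
def planted_corpus(planted_spec):
    return generate_list_corpus(planted_spec)
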