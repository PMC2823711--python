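import numpy as np
import pytest

from alnbench.evolver import EvolutionParams
from alnbench.msa import MultipleAlignment
from alnbench.phylo import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_taxon_tree():
    return parse_newick("(A:0.1,B:0.2);")


@pytest.fixture
def four_taxon_tree():
    return parse_newick("((A:0.15,B:0.15):0.1,(C:0.15,D:0.15):0.1);")


@pytest.fixture
def small_params(two_taxon_tree):
    return EvolutionParams(tree=two_taxon_tree, root_length=400, seed=11)


def random_alignment_pair(rng, max_taxa=5, max_cols=20):
    """A random (predicted, truth) alignment pair over identical sequences.

    Builds a random gapped truth, then reshuffles the gap placement of each
    row independently to make a prediction with the same ungapped content.
    """
    n_taxa = int(rng.integers(2, max_taxa + 1))
    names = [f"s{i}" for i in range(n_taxa)]

    def random_rows(seq_lengths, n_cols):
        rows = []
        for length in seq_lengths:
            chars = rng.choice(list("ACGT"), size=length)
            positions = sorted(rng.choice(n_cols, size=length, replace=False))
            row = ["-"] * n_cols
            for pos, ch in zip(positions, chars):
                row[pos] = ch
            rows.append("".join(row))
        return rows

    while True:
        n_cols = int(rng.integers(3, max_cols + 1))
        seq_lengths = [int(rng.integers(1, n_cols + 1)) for _ in range(n_taxa)]
        truth_rows = random_rows(seq_lengths, n_cols)
        if all(any(r[j] != "-" for r in truth_rows) for j in range(n_cols)):
            break
    truth = MultipleAlignment.from_rows(names, truth_rows)

    # prediction: same residues, independently re-placed gaps
    while True:
        n_cols2 = int(rng.integers(max(seq_lengths), max_cols + 1))
        pred_rows = []
        for name, length in zip(names, seq_lengths):
            seq = truth.ungapped(name)
            positions = sorted(rng.choice(n_cols2, size=length, replace=False))
            row = ["-"] * n_cols2
            for pos, ch in zip(positions, seq):
                row[pos] = ch
            pred_rows.append("".join(row))
        if all(any(r[j] != "-" for r in pred_rows) for j in range(n_cols2)):
            break
    predicted = MultipleAlignment.from_rows(names, pred_rows)
    return predicted, truth
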