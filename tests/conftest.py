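import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")

# Worked-example strings printed in the methods description: the third
# prefix subsequence used for the descriptor walkthrough, and the full
# 57-symbol characteristic sequence used for the partition walkthrough.
EXAMPLE_SUBSEQ_28 = "1010011110011010101010110011"
EXAMPLE_SEQ_57 = "101001111001101010101011001101011010010110110101000100010"


@pytest.fixture(scope="session")
def example_subseq():
    return EXAMPLE_SUBSEQ_28


@pytest.fixture(scope="session")
def example_seq57():
    return EXAMPLE_SEQ_57


@pytest.fixture
def fasta_file(tmp_path):
    def write(records: dict[str, str], name="test.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{k}\n{v}\n" for k, v in records.items()))
        return path

    return write


@pytest.fixture
def pairs_file(tmp_path):
    def write(rows, name="pairs.tsv", delim="\t"):
        path = tmp_path / name
        path.write_text("".join(delim.join(map(str, r)) + "\n" for r in rows))
        return path

    return write


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset shared by classifier-level tests."""
    from sparseppi.simulate import GeneratorConfig, generate_pair_dataset

    cfg = GeneratorConfig(
        n_proteins=120, n_positive=30, n_negative=30,
        signal_strength=0.5, seed=7,
    )
    return generate_pair_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
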