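import numpy as np
import pytest

from flankfill import ScoringParams, SequenceRecord, SimConfig, simulate_dataset, write_fasta


@pytest.fixture
def loose_params():
    """Thresholds relaxed for hand-sized example sequences."""
    return ScoringParams(min_raw_score=1, min_identity=0.0, min_aln_len=1, max_hits=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing records (or raw text) to a temp FASTA, returning the path."""

    def _write(records, name="test.fasta", raw=None):
        path = tmp_path / name
        if raw is not None:
            path.write_text(raw)
        else:
            write_fasta(records, path)
        return path

    return _write


@pytest.fixture
def small_truth():
    """A deterministic two-scaffold, error-free fixture with ground truth."""
    return simulate_dataset(SimConfig(seed=7, n_scaffolds=2, n_gaps=2))


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


@pytest.fixture
def make_record():
    def _make(seq, rid="s1"):
        return SequenceRecord(id=rid, sequence=seq)

    return _make
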