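import numpy as np
import pytest

from minihal import fixtures


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture(scope="session")
def planted():
    """5 genomes, 20 clean single-copy families, 5 paralog-contaminated."""
    spec = fixtures.FixtureSpec(
        n_genomes=5,
        n_single_copy_families=20,
        n_paralog_families=5,
        ancestor_length=120,
        seed=42,
    )
    pset, truth = fixtures.generate_proteomes(spec)
    return spec, pset, truth


def write_fasta(path, entries):
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")
    return path


@pytest.fixture()
def fasta_writer(tmp_path):
    def _write(name, entries):
        return write_fasta(tmp_path / name, entries)

    return _write
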