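import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spiraldna import NucleotideSequence, RepresentationParams

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cacag():
    return NucleotideSequence(id="x", residues="CACAG")


@pytest.fixture
def default_params():
    """The benchmark settings: L = 86, epsilon = 0.0375, default variants."""
    return RepresentationParams(L=86)


def random_sequence(rng: np.random.Generator, length: int, label: str = "r") -> NucleotideSequence:
    residues = "".join(rng.choice(list("ACGT"), size=length))
    return NucleotideSequence(id=label, residues=residues)


@pytest.fixture
def beta_globin_fasta(tmp_path):
    """A synthetic stand-in FASTA for the 11-species benchmark: same labels
    and first-exon lengths, simulated residues (the true exon sequences are
    user-supplied)."""
    from spiraldna.benchmark import BETA_GLOBIN_EXON_LENGTHS
    from spiraldna import write_fasta

    rng = np.random.default_rng(2026)
    seqs = [
        random_sequence(rng, n, label=name)
        for name, n in BETA_GLOBIN_EXON_LENGTHS.items()
    ]
    path = tmp_path / "synthetic_beta_globin_stand_in.fasta"
    write_fasta(seqs, path)
    return path
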