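import numpy as np
import pytest

from crisprscan.io_cli import GenomeRecord, PipelineConfig

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ref_db() -> list[str]:
    from crisprscan.features import load_reference_repeats

    return load_reference_repeats()


def make_genome(seq: str, gid: str = "g") -> GenomeRecord:
    return GenomeRecord(id=gid, seq=seq)
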