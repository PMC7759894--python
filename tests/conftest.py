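import numpy as np
import pytest

from hydropep.io_tables import PeptideRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


def random_sequence(rng, length):
    return "".join(rng.choice(list(AA), size=length))


def random_sample(rng, n_peptides, sample="S1", max_len=20):
    records = []
    for _ in range(n_peptides):
        length = int(rng.integers(3, max_len + 1))
        records.append(
            PeptideRecord(
                random_sequence(rng, length), sample,
                float(rng.lognormal(14, 1.5)),
            )
        )
    return records


@pytest.fixture
def peptide_table(tmp_path):
    """Small two-sample MaxQuant-style peptide table on disk."""
    lines = [
        "Sequence\tIntensity MCF_Neut\tIntensity HCM_Neut",
        "GGG\t1000000\t2000000",
        "AAAA\t2000000\t0",
        "LLLLL\t3000000\t500000",
        "IIAPPERKYS\t4000000\t1000000",
    ]
    path = tmp_path / "peptides.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
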