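import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from aroscan import (
    BernoulliStickers,
    FixedStickers,
    ProteinRecord,
    SyntheticConfig,
    gen_cohort,
)

AA_NO_ARO = "ACDEGHIKLMNPQRSTV"


def random_sequence(rng: np.random.Generator, length: int, p_aro: float = 0.15) -> str:
    """Random sequence with aromatic residues sprinkled at rate p_aro."""
    chars = []
    for _ in range(length):
        if rng.random() < p_aro:
            chars.append("FYW"[rng.integers(3)])
        else:
            chars.append(AA_NO_ARO[rng.integers(len(AA_NO_ARO))])
    return "".join(chars)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed synthetic cohort: geometric-null, fixed-spacing and too-short."""
    configs = [
        SyntheticConfig(n_proteins=40, length=400,
                        model=BernoulliStickers(p=0.08), id_prefix="null"),
        SyntheticConfig(n_proteins=15, length=400,
                        model=FixedStickers(k=10, n_stickers=25), id_prefix="per"),
    ]
    return gen_cohort(configs, seed=11)


@pytest.fixture()
def record_factory():
    def make(seq: str, pid: str = "p1") -> ProteinRecord:
        return ProteinRecord(id=pid, sequence=seq)
    return make
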