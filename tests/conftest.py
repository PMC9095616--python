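import numpy as np
import pytest

from mimoprofile.repertoire import PeptideRepertoire, normalize_reads

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def make_rep(counts: dict[str, float], sample_id: str = "S",
             normalize: bool = True) -> PeptideRepertoire:
    rep = PeptideRepertoire(sample_id=sample_id, counts=dict(counts))
    return normalize_reads(rep) if normalize else rep


def random_peptides(rng: np.random.Generator, n: int, length: int = 12) -> list[str]:
    out = set()
    while len(out) < n:
        out.add("".join(rng.choice(list(RESIDUES), size=length)))
    return sorted(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
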