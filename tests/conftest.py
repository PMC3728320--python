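import numpy as np
import pytest

from plastid_delim.io_formats import Alignment, SpeciesMap, read_tree


@pytest.fixture
def toy_alignment() -> Alignment:
    """The 4-row hand example used throughout: one constant, one
    informative and one variable-but-uninformative column."""
    return Alignment([("s1", "AAT"), ("s2", "AAT"), ("s3", "AGT"), ("s4", "AGA")])


@pytest.fixture
def balanced_tree():
    return read_tree(None, data="((a:1,b:1):1,c:2);")


def random_alignment(rng: np.random.Generator, n: int, L: int,
                     missing_frac: float = 0.0) -> Alignment:
    """Low-diversity random alignment: mutations scattered over a common
    ancestral sequence, with optional missing characters."""
    anc = rng.choice(list("ACGT"), size=L)
    rows = []
    for i in range(n):
        seq = anc.copy()
        n_mut = rng.integers(0, max(2, L // 10))
        for pos in rng.integers(0, L, size=n_mut):
            seq[pos] = rng.choice(list("ACGT"))
        if missing_frac > 0:
            mask = rng.random(L) < missing_frac
            seq[mask] = rng.choice(list("N-"), size=int(mask.sum()))
        rows.append((f"s{i}", "".join(seq)))
    return Alignment(rows)


def random_species_map(rng: np.random.Generator, ids: list[str],
                       n_species: int) -> SpeciesMap:
    labels = [f"sp{k}" for k in range(n_species)]
    return SpeciesMap({i: labels[int(rng.integers(n_species))] for i in ids})
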