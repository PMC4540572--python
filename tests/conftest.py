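import itertools

import numpy as np
import pytest

from morpheus import MPWM, DependencyGroup, parse_mpwm
from morpheus.mpwm import ALPHABET, NT_INDEX, nt_tuples


@pytest.fixture
def onehot_frequency_doc():
    """3-position frequency matrix with one-hot rows A, C, T."""
    return (
        "name: onehot\n"
        "type: frequency\n"
        "matrix:\n"
        "1 0 0 0\n"
        "0 1 0 0\n"
        "0 0 0 1\n"
    )


@pytest.fixture
def onehot_model(onehot_frequency_doc):
    return parse_mpwm(onehot_frequency_doc)


def brute_force_score(model: MPWM, site: str) -> float:
    """Independent term-by-term rescoring oracle: walks the model's
    blocks explicitly, never calling the package's scoring path."""
    covered = {p for g in model.groups for p in g.positions}
    total = 0.0
    for p in range(1, model.length + 1):
        if p not in covered:
            total += model.matrix[p - 1][NT_INDEX[site[p - 1]]]
    for g in model.groups:
        total += g.values["".join(site[p - 1] for p in g.positions)]
    return total


def all_sites(L: int):
    for combo in itertools.product(ALPHABET, repeat=L):
        yield "".join(combo)


def random_group(rng: np.random.Generator, positions, kind="weight"):
    d = len(positions)
    vals = rng.normal(size=4 ** d)
    if kind == "weight":
        vals = vals - vals.max()
    return DependencyGroup(tuple(positions), dict(zip(nt_tuples(d), vals.tolist())))
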