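import numpy as np
import pytest

from pepfer import (
    BindingMode,
    CountTable,
    EnergyModel,
    LibraryDesign,
    RoundParams,
    x5yx5_design,
    x11_design,
)
from pepfer.library import ALPHABET

N_AA = len(ALPHABET)


@pytest.fixture
def design_x5yx5():
    return x5yx5_design()


@pytest.fixture
def design_x11():
    return x11_design()


@pytest.fixture
def tiny_design():
    """Short unconstrained design for cheap oracle comparisons."""
    return LibraryDesign(name="tiny", length=5, fixed_positions={})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mode(rng, width, n_bias=None, flank_depth=0, scale=0.5):
    return BindingMode(
        width=width,
        coeffs=rng.normal(0, scale, size=(width, N_AA)),
        position_bias=None if n_bias is None else rng.normal(0, scale, n_bias),
        flank_depth=flank_depth,
    )


def random_model(rng, design, n_rounds=1, ns_width=3, flank_depth=0, scale=0.5):
    specific = random_mode(rng, design.length, flank_depth=flank_depth, scale=scale)
    nonspecific = random_mode(
        rng, ns_width, n_bias=design.length - ns_width + 1, scale=scale
    )
    per_round = [
        RoundParams(
            rng.normal(0, 0.3), rng.normal(0, 0.3), rng.normal(0, 0.3)
        )
        for _ in range(n_rounds)
    ]
    return EnergyModel(
        design=design,
        specific=specific,
        nonspecific=nonspecific,
        per_round=per_round,
    )


def random_peptides(rng, design, n):
    idx = rng.integers(0, N_AA, size=(n, design.length))
    for pos, res in design.fixed_positions.items():
        idx[:, pos - 1] = ALPHABET.index(res)
    return ["".join(ALPHABET[i] for i in row) for row in idx]


def random_table(rng, design, n=20, round_id=1):
    seqs = list(dict.fromkeys(random_peptides(rng, design, n)))
    k_in = rng.integers(0, 30, size=len(seqs))
    k_bd = rng.integers(0, 30, size=len(seqs))
    zero = (k_in == 0) & (k_bd == 0)
    k_in[zero] = 1
    return CountTable(
        round_id=round_id,
        design=design,
        sequences=seqs,
        counts_input=k_in,
        counts_bound=k_bd,
    )
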