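import numpy as np
import pytest

from bladekit.consensus import PermutantSpec

# Toy tandem repeat used throughout the permutation tests: repeat
# "GabGcdDefGgh" (lowercase marks loop-vs-strand visually; sequences are
# case-normalised), strands at 2-3, 5-6, 8-9, 11-12, two repeats.
TOY_REPEAT = "GabGcdDefGgh"
TOY_STRANDS = ((2, 3), (5, 6), (8, 9), (11, 12))


@pytest.fixture
def toy_tandem() -> str:
    return (TOY_REPEAT * 2).upper()


def toy_spec(velcro: str, deletion_policy="prefer-glycine") -> PermutantSpec:
    return PermutantSpec(
        velcro=velcro,
        strand_ranges=TOY_STRANDS,
        n_repeats=2,
        deletion_policy=deletion_policy,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
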