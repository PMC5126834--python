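import numpy as np
import pytest

from xcal.calibration import calibrate_library
from xcal.library import SeedAlignment, build_domain_model, build_profile
from xcal.simulate import FixtureSpec, generate_mini_library


@pytest.fixture(scope="session")
def tiny_seed():
    return SeedAlignment(
        model_id="toy",
        rows=("ACDA", "AC-A", "ACDA"),
    )


@pytest.fixture(scope="session")
def small_library():
    """8 clean families, short models: the workhorse for calibration tests."""
    spec = FixtureSpec(
        n_models=8, length_range=(25, 40), alpha=5, conservation=0.95,
        n_queries=10, rng_seed=11,
    )
    library, _ = generate_mini_library(spec)
    return library


@pytest.fixture(scope="session")
def small_calibrations(small_library):
    return calibrate_library(small_library, rng_seed=11, n_null=120, keep_strata=True)


@pytest.fixture(scope="session")
def weakened_library():
    """10 families; two have their local build estimated from a heavily
    noised seed copy, degrading only that build's sensitivity."""
    spec = FixtureSpec(
        n_models=10, length_range=(30, 45), alpha=6, conservation=0.95,
        n_queries=10, rng_seed=23, weakened_local=frozenset({"fam002", "fam007"}),
    )
    library, _ = generate_mini_library(spec)
    return library


@pytest.fixture(scope="session")
def weakened_calibrations(weakened_library):
    return calibrate_library(weakened_library, rng_seed=23, n_null=120, keep_strata=True)


def random_profile(L, mode, rng):
    """A random but well-formed profile: built from a random seed alignment
    so transition estimates are realistic (gaps included)."""
    alphabet = np.array(list("ACDE"))
    rows = []
    for _ in range(4):
        row = rng.choice(alphabet, size=L)
        gaps = rng.random(L) < 0.25
        rows.append("".join("-" if g else c for c, g in zip(row, gaps)))
    if all(set(r) == {"-"} for r in rows):  # ensure at least one residue
        rows[0] = "A" * L
    seed = SeedAlignment(model_id=f"rand{L}", rows=tuple(rows))
    return build_profile(seed, mode, pseudocount=0.7)
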