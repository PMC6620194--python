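import numpy as np
import pytest

from mprachim.design import (
    DEFAULT_SPACER_83,
    LibraryDesign,
    PlasmidLibrary,
    Clone,
    random_library,
)


@pytest.fixture(scope="session")
def design71() -> LibraryDesign:
    return LibraryDesign()


@pytest.fixture(scope="session")
def design83() -> LibraryDesign:
    return LibraryDesign(spacer=DEFAULT_SPACER_83)


@pytest.fixture(scope="session")
def two_clone_library(design71) -> PlasmidLibrary:
    return PlasmidLibrary(
        design71,
        [
            Clone("A" * 18, "AAAAAAAA"),
            Clone("C" * 18, "CCCCCCCC"),
        ],
    )


@pytest.fixture(scope="session")
def small_library(design71) -> PlasmidLibrary:
    return random_library(50, design71, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
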