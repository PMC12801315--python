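import pytest

from chemquiz import (
    BenchmarkConfig,
    build_benchmark,
    druglike_library,
    small_molecule_library,
)


@pytest.fixture(scope="session")
def druglike():
    return list(druglike_library())


@pytest.fixture(scope="session")
def small_lib():
    return list(small_molecule_library())


@pytest.fixture(scope="session")
def default_benchmark():
    """The full default benchmark (816 questions), built once per session."""
    return build_benchmark(BenchmarkConfig(master_seed=1))


@pytest.fixture(scope="session")
def tiny_config():
    """A scaled-down config for fast pipeline tests."""
    return BenchmarkConfig(
        master_seed=3,
        counts={
            "carbon_count": 4,
            "ring_count": 4,
            "shortest_path": 6,
            "atom_map": 4,
            "iupac_zinc": 6,
            "iupac_fg": 3,
            "iupac_locant": 4,
            "free_wilson": 4,
            "reaction": 18,
            "nmr_1d": 4,
            "nmr_2d": 3,
        },
    )
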