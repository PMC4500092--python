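import pytest

from tfscape.simulate import (
    LandscapeParams,
    generate_landscape,
    pair_contrast_matrix,
    pathway_fixtures,
    preset_ancsr1,
)


@pytest.fixture(scope="session")
def ancsr1_re_params():
    """Noiseless landscape with only the printed RE determinants of the
    ancestral protein: G3 +1.0, T4 +0.5, G3xT4 +0.8 kcal/mol."""
    return LandscapeParams(
        grand_mean=10.0,
        re_site_effects={
            3: {"G": 1.0, "A": -1 / 3, "C": -1 / 3, "T": -1 / 3},
            4: {"T": 0.5, "A": -0.5 / 3, "C": -0.5 / 3, "G": -0.5 / 3},
        },
        re_pair_contrasts=pair_contrast_matrix("G", {"T": 0.8, "A": -0.6}),
        noise_sd=0.0,
        replicates=1,
        seed=0,
    )


@pytest.fixture(scope="session")
def ancsr1_re_table(ancsr1_re_params):
    table, _ = generate_landscape(ancsr1_re_params)
    return table


@pytest.fixture(scope="session")
def preset_noiseless_table():
    """Full AncSR1-style preset (all orders populated), zero noise."""
    table, landscape = generate_landscape(
        preset_ancsr1(noise_sd=0.0, replicates=1)
    )
    return table, landscape


@pytest.fixture(scope="session")
def fixtures():
    return pathway_fixtures()
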