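import pytest

from ricehg.synthetic_world import WorldConfig, calibrate_to_paper, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A 20-country world used across the suite; session-scoped for speed."""
    return generate_world(WorldConfig(n_countries=20, seed=42))


@pytest.fixture(scope="session")
def calibrated_world():
    """A 30-country world scaled to the 5.3 Mg global grain THg reference."""
    return calibrate_to_paper(generate_world(WorldConfig(n_countries=30, seed=7)))


@pytest.fixture()
def gt_concentrations(calibrated_world):
    """Ground-truth (THg, MeHg) pairs keyed by country."""
    gt = calibrated_world.ground_truth
    return {
        c: (gt["true_thg_ng_g"][c], gt["true_mehg_ng_g"][c])
        for c in calibrated_world.countries
    }
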