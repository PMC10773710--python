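import pytest

from canopyspad import CampaignConfig, generate_campaign


@pytest.fixture(scope="session")
def noiseless_campaign():
    """Full 7x10x1 campaign, four stages, zero noise: exact ground truth."""
    cfg = CampaignConfig(spad_noise_sd=0.0, reflectance_noise_sd=0.0, reps=1, seed=11)
    profiles, reflectance, truth = generate_campaign(cfg)
    return cfg, profiles, reflectance, truth


@pytest.fixture(scope="session")
def noisy_campaign():
    """Default-noise 70-plot campaign, four stages."""
    cfg = CampaignConfig(reps=1, seed=42)
    profiles, reflectance, truth = generate_campaign(cfg)
    return cfg, profiles, reflectance, truth
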