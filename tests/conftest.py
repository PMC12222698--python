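import pytest


@pytest.fixture(scope="session")
def default_campaign():
    """One seeded draw of the default synthetic campaign, with spectrum."""
    from indoair.synthetic_data import ConcentrationModel, generate_concentrations

    model = ConcentrationModel(n_steps=2000)
    return generate_concentrations(model, seed=42, with_spectrum=True)


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded synthetic worker cohort with ground truth."""
    from indoair.synthetic_data import generate_cohort

    return generate_cohort(seed=42)
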