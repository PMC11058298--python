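import pytest

from dairylca import packaged_fixtures, reference_model, run_all_scenarios


@pytest.fixture(scope="session")
def bundle():
    return packaged_fixtures()


@pytest.fixture(scope="session")
def models(bundle):
    return {region: reference_model(region, bundle)
            for region in ("oder_spree", "diepholz")}


@pytest.fixture(scope="session")
def forward_results(bundle, models):
    scenarios = bundle.scenarios()
    return {region: run_all_scenarios(model, scenarios)
            for region, model in models.items()}
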