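import pytest

from akb import build_worked_examples, build_seed_taxonomy


@pytest.fixture(scope="session")
def bundle():
    """The worked-example bundle (taxonomy, rules, thresholds, diseases)."""
    return build_worked_examples()


@pytest.fixture(scope="session")
def tax(bundle):
    return bundle.taxonomy


@pytest.fixture()
def seed_tax():
    # function-scoped: several tests extend it in place
    return build_seed_taxonomy()


@pytest.fixture(scope="session")
def ihd_family(bundle):
    """The four ischemic-heart-disease family definitions."""
    return [
        bundle.diseases[i]
        for i in ("ihd", "myocardial_infarction", "prinzmetal_angina",
                  "organic_angina_pectoris")
    ]
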