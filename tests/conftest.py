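from importlib.resources import files

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def data_path(name: str) -> str:
    return str(files("gpcrstars.data") / name)


@pytest.fixture(scope="session")
def anchors():
    from gpcrstars.numbering import gpr18_anchors

    return gpr18_anchors()


@pytest.fixture(scope="session")
def nmap(anchors):
    from gpcrstars.numbering import build_numbering

    return build_numbering(anchors)


@pytest.fixture(scope="session")
def quality_records():
    from gpcrstars.stars import load_quality_table

    return load_quality_table(data_path("gpr18_quality_table.csv"))


@pytest.fixture(scope="session")
def specs():
    from gpcrstars.stars import default_specs

    return default_specs()


@pytest.fixture(scope="session")
def secondary_scores():
    from gpcrstars.ranking import load_secondary_table

    return load_secondary_table(data_path("gpr18_secondary_table.csv"))


@pytest.fixture(scope="session")
def pocket_predictions():
    from gpcrstars.pocket import load_predictions

    return load_predictions(data_path("pocket_predictions.json"))


@pytest.fixture(scope="session")
def default_bundle():
    from gpcrstars.synthetic import BundleSpec, build_bundle

    return build_bundle(BundleSpec())
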