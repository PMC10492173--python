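import pytest

from forumlab.catalog import TestCatalog
from forumlab.synthetic import LabPanelSpec, generate_corpus
from forumlab.types import LabObservation


@pytest.fixture(scope="session")
def catalog() -> TestCatalog:
    return TestCatalog.default()


@pytest.fixture(scope="session")
def panel_spec(catalog) -> LabPanelSpec:
    return LabPanelSpec(catalog)


@pytest.fixture(scope="session")
def small_corpus(panel_spec):
    """500 posts with ground truth, shared by extraction/screening tests."""
    return generate_corpus(panel_spec, None, 500, seed=1)


def make_obs(test_id, value, uncertain=False, post_id="p0", account_id="u0",
             test_day="2020-01-01"):
    return LabObservation(
        test_id=test_id, value=float(value), uncertain=uncertain,
        post_id=post_id, account_id=account_id, test_day=test_day,
    )
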