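import pytest

from phasemet.annotate import default_fragments
from phasemet.parents import get_parent, load_reference_table
from phasemet.rules import dedup_candidates, default_ruleset, enumerate_candidates

PARENT_NAMES = ("5F-ADB-PINACA", "5F-ADBICA")


@pytest.fixture(scope="session", params=PARENT_NAMES)
def parent_name(request):
    return request.param


@pytest.fixture(scope="session")
def parent(parent_name):
    return get_parent(parent_name)


@pytest.fixture(scope="session")
def ruleset(parent):
    return default_ruleset(parent.scaffold)


@pytest.fixture(scope="session")
def reference(parent_name):
    return load_reference_table(parent_name)


@pytest.fixture(scope="session")
def candidate_groups(parent, ruleset):
    return dedup_candidates(
        enumerate_candidates(parent.composition, ruleset, parent_id=parent.id)
    )


@pytest.fixture(scope="session")
def fragment_tables(parent):
    return default_fragments(parent.scaffold)
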