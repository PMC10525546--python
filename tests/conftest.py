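from datetime import date

import pytest
from hypothesis import HealthCheck, settings

import drcohesion as dc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return dc.load_registry()


@pytest.fixture(scope="session")
def worked_week():
    return dc.Week(date(2021, 12, 31), date(2022, 1, 6))


@pytest.fixture(scope="session")
def worked_corpus(registry):
    return dc.replay_worked_example(registry)


@pytest.fixture(scope="session")
def worked_tabulation(worked_corpus, worked_week, registry):
    return dc.tabulate(worked_corpus, worked_week, registry)


def make_occurrence(
    id="occ-1",
    text="Aggiornamento sulla pandemia COVID-19 in regione.",
    source=dc.Source.FACEBOOK,
    author_role=dc.AuthorRole.CITIZEN,
    province="Padova",
    published_at=date(2021, 12, 31),
):
    return dc.Occurrence(
        id=id,
        text=text,
        source=source,
        author_role=author_role,
        province=province,
        published_at=published_at,
    )


@pytest.fixture
def occurrence_factory():
    return make_occurrence
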