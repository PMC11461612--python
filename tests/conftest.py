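import pytest

import waitcast as wc
from waitcast import evalselect as ev
from waitcast import preprocess as pp

# Nine-row dummy log: three patients, two physicians, one morning.
TABLE1_LOG = """Index,Patient ID,Assign physician,Sequence,Activity,Event Time
1,Patient A,Physician A,1,Registration,2020-08-03 10:15:21
2,Patient A,Physician A,2,Addition into queue,2020-08-03 10:15:22
3,Patient B,Physician A,1,Registration,2020-08-03 10:15:36
4,Patient B,Physician A,2,Addition into queue,2020-08-03 10:15:38
5,Patient C,Physician B,1,Registration,2020-08-03 10:33:20
6,Patient C,Physician B,2,Preliminary examination,2020-08-03 10:33:26
7,Patient A,Physician A,3,Call for a consultation,2020-08-03 10:33:28
8,Patient B,Physician A,3,Call for a consultation,2020-08-03 10:36:12
9,Patient C,Physician B,3,Addition into queue,2020-08-03 11:23:45
"""


@pytest.fixture
def table1_text() -> str:
    return TABLE1_LOG


@pytest.fixture
def table1_records(table1_text):
    return wc.read_event_log(table1_text)


@pytest.fixture
def table1_episodes(table1_records):
    return wc.reconstruct_episodes(table1_records)


# ---- simulated clinic shared across the suite (3 physicians, 20 days) ----

@pytest.fixture(scope="session")
def clinic_log():
    return wc.simulate(wc.ClinicConfig(seed=1))


@pytest.fixture(scope="session")
def clinic_episodes(clinic_log):
    episodes, _ = wc.reconstruct_episodes(clinic_log)
    return episodes


@pytest.fixture(scope="session")
def clinic_features(clinic_episodes):
    return wc.build_features(clinic_episodes)


@pytest.fixture(scope="session")
def clinic_splits(clinic_features):
    """(train, test, state, drops) from the fixed-order pipeline."""
    return pp.preprocess_pipeline(clinic_features, ratio=0.8, seed=0)


@pytest.fixture(scope="session")
def alpha_selection(clinic_splits):
    """Repeated-CV selection over the Quad-Quad alpha ladder, DAES(30)."""
    train = clinic_splits[0]
    plan = ev.CVPlan(
        k=5,
        n_repeats=5,
        candidates=[ev.Candidate("quad_quad", a) for a in (0.5, 0.6, 0.7, 0.8, 0.9)],
        score="daes",
        gamma=30.0,
    )
    return ev.cross_validate_select(train, plan)
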