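import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from breathvoc import (
    ENV_EXCESS_MASSES,
    VOCPanel,
    BreathSample,
    generate_published_like_run,
)
from breathvoc.pipeline import run_fit

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def small_panel():
    return VOCPanel(("ammonia", "M34", "M89"))


def _sample(panel, sid, stype="alveolar", group="control", sex="M", age=50.0,
            co2=4.0, o2=16.0, conc=(100.0, 20.0, 2.0)):
    return BreathSample(
        sample_id=f"{stype[0].upper()}-{sid}",
        subject_id=sid,
        sample_type=stype,
        group=None if stype == "environmental" else group,
        sex=None if stype == "environmental" else sex,
        age=None if stype == "environmental" else age,
        co2=co2,
        o2=o2,
        panel=panel,
        concentrations=np.array(conc),
    )


@pytest.fixture
def make_sample(small_panel):
    def factory(sid, **kw):
        kw.setdefault("conc", (100.0, 20.0, 2.0))
        return _sample(small_panel, sid, **kw)

    return factory


@pytest.fixture
def tiny_cohort(make_sample):
    """Four subjects (2 cases / 2 controls) with paired room-air samples."""
    samples = []
    for i, (group, conc) in enumerate(
        [
            ("control", (90.0, 19.0, 1.2)),
            ("control", (110.0, 21.0, 1.6)),
            ("case", (140.0, 12.0, 3.2)),
            ("case", (120.0, 13.0, 4.0)),
        ]
    ):
        sid = f"S{i:03d}"
        samples.append(make_sample(sid, group=group, conc=conc, age=50.0 + i))
        samples.append(
            make_sample(sid, stype="environmental", co2=0.05, conc=(25.0, 5.0, 0.4))
        )
    return samples


# session-scoped: the published-structure synthetic run is shared by several
# test modules (counting checks, end-to-end structure, acceptance).
@pytest.fixture(scope="session")
def published_pair():
    return generate_published_like_run(0)


@pytest.fixture(scope="session")
def published_fit(published_pair):
    training, _ = published_pair
    return run_fit(
        training,
        seed=0,
        gradient_mode="explicit_list",
        explicit_list=ENV_EXCESS_MASSES,
        n_folds=50,
        n_boot=50,
    )
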