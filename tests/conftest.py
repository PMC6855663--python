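import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from radgem.growth import Cohort, Measurement, MeasurementSeries


def make_series(animal_id, group, days, volumes, fate="followed-to-end",
                fate_day=None):
    """Series whose ellipsoid volumes equal ``volumes`` exactly (cubic l=w=h)."""
    from radgem.growth import ELLIPSOID_FACTOR

    ms = []
    for d, v in zip(days, volumes):
        if v is None:
            ms.append(Measurement(day=d))
        else:
            side = (v / ELLIPSOID_FACTOR) ** (1 / 3)
            ms.append(Measurement(day=d, length=side, width=side, height=side))
    if fate == "followed-to-end" and fate_day is None:
        fate_day = days[-1]
    return MeasurementSeries(animal_id=animal_id, group=group, measurements=ms,
                             fate=fate, fate_day=fate_day)


def make_rtv_series(animal_id, group, days, rtvs, **kw):
    """Series with baseline volume 100 so the RTV trace equals ``rtvs``."""
    return make_series(animal_id, group, days, [100 * r for r in rtvs], **kw)


@pytest.fixture
def two_arm_cohort():
    """Tiny two-arm cohort with hand-computable group summaries."""
    return Cohort(
        series=[
            make_rtv_series("c1", "control", [0, 3, 7], [1, 1.0, 2.0]),
            make_rtv_series("c2", "control", [0, 3, 7], [1, 3.0, 4.0]),
            make_rtv_series("t1", "treated", [0, 3, 7], [1, 0.8, 1.2]),
            make_rtv_series("t2", "treated", [0, 3, 7], [1, 1.2, 1.8]),
        ],
        control_group="control",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
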