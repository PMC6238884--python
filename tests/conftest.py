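from datetime import date, datetime, time

import pytest

from diakb import PatientProfile, Registration, ThresholdConfig, build_context, default_kb
from diakb.model import ActivityQuantity, DataType

D0 = date(2024, 3, 4)  # a Monday


@pytest.fixture(scope="session")
def kb():
    return default_kb()


@pytest.fixture
def config():
    return ThresholdConfig()


@pytest.fixture
def profile():
    return PatientProfile(carb_absorption_rate=30.0)


def reg(day: int, hh: int, mm: int, data_type: DataType, value: float = 0.0,
        manual: bool = True, source: str = "test", **kw) -> Registration:
    ts = datetime.combine(D0, time(hh, mm))
    ts = ts.replace(day=D0.day + day)
    return Registration(timestamp=ts, data_type=data_type, value=value,
                        manual=manual, source=source, **kw)


def bg(day: int, hh: int, mm: int, value: float, **kw) -> Registration:
    return reg(day, hh, mm, DataType.BLOOD_GLUCOSE, value, **kw)


def carb(day: int, hh: int, mm: int, grams: float, **kw) -> Registration:
    return reg(day, hh, mm, DataType.CARBOHYDRATES, grams, **kw)


def bolus(day: int, hh: int, mm: int, units: float, **kw) -> Registration:
    return reg(day, hh, mm, DataType.INSULIN_BOLUS, units, **kw)


def activity(day: int, hh: int, mm: int, kind: str, amount=None, tag=None):
    return reg(day, hh, mm, DataType.PHYSICAL_ACTIVITY,
               value=float(amount or 0.0), manual=False,
               activity_quantity=ActivityQuantity(kind=kind, amount=amount, tag=tag))


def ctx_of(registrations, profile=None, lab=None, config=None, **kw):
    return build_context(registrations, profile or PatientProfile(carb_absorption_rate=30.0),
                         lab, config, **kw)
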