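"""Context construction, windowing and validation behaviour."""
from datetime import datetime, time, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bg, carb, ctx_of
from diakb import PatientProfile, Registration, build_context, slice_window
from diakb.model import ContextError, DataType


class TestBuildContext:
    def test_sorts_and_sets_period(self):
        regs = [bg(0, 14, 0, 6.0), bg(0, 8, 0, 5.5), bg(0, 11, 0, 7.0)]
        ctx = ctx_of(regs)
        times = [r.timestamp for r in ctx.registrations]
        assert times == sorted(times)
        assert ctx.period_start == times[0]
        assert ctx.period_end == times[-1]

    def test_duplicates_collapse_with_warning(self, caplog):
        import logging
        a = bg(0, 8, 0, 6.0)
        b = bg(0, 8, 0, 6.2)  # same minute, type and source
        with caplog.at_level(logging.WARNING, logger="diakb.model"):
            ctx = ctx_of([a, b])
        assert len(ctx.registrations) == 1
        assert any("duplicate" in rec.message for rec in caplog.records)

    def test_nan_value_rejected_with_index(self):
        raw = [{"timestamp": "2024-03-04T08:00", "data_type": "blood_glucose",
                "value": float("nan"), "source": "x", "manual": True}]
        with pytest.raises(ContextError, match="index 0"):
            build_context(raw, PatientProfile())

    def test_unknown_data_type_rejected(self):
        raw = [{"timestamp": "2024-03-04T08:00", "data_type": "ketones",
                "value": 1.0, "source": "x", "manual": True}]
        with pytest.raises(ContextError):
            build_context(raw, PatientProfile())

    def test_empty_requires_flag(self):
        with pytest.raises(ContextError):
            build_context([], PatientProfile())
        ctx = build_context([], PatientProfile(), allow_empty=True)
        assert ctx.registrations == []

    def test_idempotent(self):
        regs = [bg(0, 14, 0, 6.0), bg(0, 8, 0, 5.5), carb(0, 12, 0, 40.0)]
        once = ctx_of(regs)
        twice = ctx_of(once.registrations)
        assert once == twice


class TestSliceWindow:
    def test_boundary_half_open(self):
        """A registration exactly the lookback before the end is excluded."""
        end = datetime(2024, 3, 4, 15, 0)
        inside = carb(0, 11, 30, 40.0)
        boundary = carb(0, 11, 0, 40.0)
        outside = carb(0, 10, 59, 40.0)
        ctx = ctx_of([inside, boundary, outside, bg(0, 15, 0, 6.0)])
        got = slice_window(ctx, DataType.CARBOHYDRATES, end, timedelta(hours=4))
        assert [r.timestamp for r in got] == [inside.timestamp]

    def test_empty_context(self):
        ctx = build_context([], PatientProfile(), allow_empty=True)
        assert slice_window(ctx, DataType.CARBOHYDRATES,
                            datetime(2024, 3, 4, 15, 0), timedelta(hours=4)) == []

    @given(st.lists(st.integers(0, 60 * 48), min_size=1, max_size=30),
           st.integers(1, 60 * 48), st.integers(1, 60 * 24))
    @settings(max_examples=60, deadline=None)
    def test_disjoint_windows_partition_the_series(self, minutes, end_min, width_min):
        base = datetime(2024, 3, 4)
        regs = [Registration(timestamp=base + timedelta(minutes=m),
                             data_type=DataType.BLOOD_GLUCOSE, value=6.0,
                             source=f"s{i}")
                for i, m in enumerate(sorted(set(minutes)))]
        ctx = ctx_of(regs)
        end = base + timedelta(minutes=end_min)
        width = timedelta(minutes=width_min)
        everything = slice_window(ctx, DataType.BLOOD_GLUCOSE, end,
                                  timedelta(days=365))
        pieces = []
        for k in range(0, 4):
            pieces += slice_window(ctx, DataType.BLOOD_GLUCOSE, end - k * width, width)
        tail = [r for r in everything if r.timestamp <= end - 4 * width]
        assert sorted(r.timestamp for r in pieces + tail) == \
            sorted(r.timestamp for r in everything)


class TestProfileValidation:
    def test_overlapping_mealtimes_rejected(self):
        with pytest.raises(ValueError):
            PatientProfile(mealtime_windows={
                "lunch": (time(11), time(14)), "tea": (time(13), time(15))})

    def test_activity_fields_only_for_activity(self):
        from diakb.model import ActivityQuantity
        with pytest.raises(ValueError):
            Registration(timestamp=datetime(2024, 3, 4, 8), value=6.0,
                         data_type=DataType.BLOOD_GLUCOSE,
                         activity_quantity=ActivityQuantity(kind="steps", amount=100))

    def test_factor_tag_only_for_external(self):
        with pytest.raises(ValueError):
            Registration(timestamp=datetime(2024, 3, 4, 8), value=6.0,
                         data_type=DataType.BLOOD_GLUCOSE, factor_tag="sickness")
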