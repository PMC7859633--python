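"""Footfall parsing, the good-run rule, parameter extraction, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from strokequant import (
    HOOVES,
    GaitParameters,
    aggregate_parameters,
    footfall_frame,
    gait_changes,
    is_good_run,
    parse_footfalls,
    percent_change,
    run_parameters,
    runs_from_frame,
    write_footfalls,
)


def _params(velocity=205.0, cycle=0.45, swing=55.0, stride=89.9, pressure=2.8):
    return GaitParameters(
        velocity=velocity,
        cadence=60.0 / cycle,
        cycle_time={h: cycle for h in HOOVES},
        swing_percent={h: swing for h in HOOVES},
        stride_length={h: stride for h in HOOVES},
        mean_pressure={h: pressure for h in HOOVES},
    )


class TestParsing:
    def test_roundtrip_preserves_fields(self, tmp_path):
        frame = footfall_frame(_params(), "r1")
        path = tmp_path / "runs.csv"
        frame.to_csv(path, index=False)
        runs = parse_footfalls(path)
        assert len(runs) == 1 and len(runs[0].events) == 16
        write_footfalls(runs, tmp_path / "back.csv")
        again = parse_footfalls(tmp_path / "back.csv")
        for e1, e2 in zip(runs[0].events, again[0].events):
            assert e1 == e2

    def test_lift_before_contact_reported_with_row_number(self, tmp_path):
        frame = footfall_frame(_params(), "r1")
        frame.loc[4, "lift_time_s"] = frame.loc[4, "contact_time_s"] - 0.1
        with pytest.raises(ValueError, match="row 5"):
            runs_from_frame(frame)

    def test_unknown_hoof_code_rejected(self):
        frame = footfall_frame(_params(), "r1")
        frame.loc[0, "hoof"] = "XX"
        with pytest.raises(ValueError, match="XX"):
            runs_from_frame(frame)

    def test_missing_column_rejected(self, tmp_path):
        frame = footfall_frame(_params(), "r1").drop(columns=["pressure_au"])
        with pytest.raises(ValueError, match="pressure_au"):
            runs_from_frame(frame)


class TestGoodRun:
    def test_eleven_footfalls_rejected(self):
        frame = footfall_frame(_params(), "r1").iloc[:11]
        run = runs_from_frame(frame)[0]
        ok, reason = is_good_run(run)
        assert not ok and "12 consecutive footfalls" in reason

    def test_sixteen_footfalls_three_cycles_accepted(self):
        run = runs_from_frame(footfall_frame(_params(), "r1"))[0]
        ok, reason = is_good_run(run)
        assert ok and reason == "accepted"

    def test_missing_limb_rejected(self):
        frame = footfall_frame(_params(), "r1")
        frame = frame[frame.hoof != "RF"].reset_index(drop=True)
        # still >= 12 footfalls but RF has no cycles
        assert len(frame) == 12
        ok, reason = is_good_run(runs_from_frame(frame)[0])
        assert not ok and "RF" in reason


class TestRunParameters:
    def test_two_contact_hand_example(self):
        rows = []
        for hoof in HOOVES:
            for k, (t, x) in enumerate([(0.0, 0.0), (0.45, 80.0)]):
                rows.append(
                    dict(run_id="r", hoof=hoof, contact_time_s=t + 0.01 * HOOVES.index(hoof),
                         lift_time_s=t + 0.2 + 0.01 * HOOVES.index(hoof),
                         x_cm=x, y_cm=0.0, pressure_au=2.8)
                )
        params = run_parameters(runs_from_frame(pd.DataFrame(rows))[0])
        assert params.cycle_time["RF"] == pytest.approx(0.45)
        assert params.stride_length["RF"] == pytest.approx(80.0)
        # stance 0.2 s within a 0.45 s cycle -> swing 55.6%
        assert params.swing_percent["RF"] == pytest.approx(100 * 0.25 / 0.45, abs=1e-9)

    def test_velocity_and_cadence_from_construction(self):
        params = run_parameters(
            runs_from_frame(footfall_frame(_params(velocity=89.9 / 0.438, cycle=0.438), "r"))[0]
        )
        assert params.velocity == pytest.approx(205.3, abs=0.1)
        assert params.cadence == pytest.approx(137.0, abs=0.1)

    def test_swing_plus_stance_is_exactly_100(self):
        params = run_parameters(runs_from_frame(footfall_frame(_params(swing=52.3), "r"))[0])
        for h in HOOVES:
            stance_pct = 100.0 - params.swing_percent[h]
            assert params.swing_percent[h] + stance_pct == 100.0
            assert params.swing_percent[h] == pytest.approx(52.3, abs=1e-9)

    def test_velocity_equals_stride_over_cycle_noise_free(self):
        p = _params(velocity=89.9 / 0.45, cycle=0.45, stride=89.9)
        got = run_parameters(runs_from_frame(footfall_frame(p, "r"))[0])
        for h in HOOVES:
            assert got.velocity == pytest.approx(
                got.stride_length[h] / got.cycle_time[h], rel=1e-6
            )

    def test_reverse_direction_normalized(self):
        frame = footfall_frame(_params(), "r")
        frame["x_cm"] = -frame["x_cm"]
        params = run_parameters(runs_from_frame(frame)[0])
        assert params.velocity > 0
        assert all(params.stride_length[h] > 0 for h in HOOVES)

    def test_single_contact_limb_rejected(self):
        frame = footfall_frame(_params(), "r")
        frame = frame.drop(frame[frame.hoof == "LH"].index[1:]).reset_index(drop=True)
        with pytest.raises(ValueError, match="LH"):
            run_parameters(runs_from_frame(frame)[0])


class TestAggregation:
    def test_constant_input_is_idempotent(self):
        p = _params()
        agg = aggregate_parameters([(1, p), (1, p), (2, p), (3, p)], "pre")
        assert agg.as_flat() == pytest.approx(p.as_flat())

    def test_day_mean_weighting(self):
        runs = [
            (1, _params(velocity=100.0)),
            (1, _params(velocity=100.0)),
            (2, _params(velocity=130.0)),
            (3, _params(velocity=160.0)),
        ]
        agg = aggregate_parameters(runs, "pre")
        assert agg.velocity == pytest.approx(130.0)  # not the pooled 122.5

    def test_pre_needs_three_days(self):
        with pytest.raises(ValueError, match="3 distinct days"):
            aggregate_parameters([(1, _params()), (2, _params())], "pre")

    def test_post_needs_exactly_five_runs(self):
        runs = [("post", _params())] * 4
        with pytest.raises(ValueError, match="exactly 5"):
            aggregate_parameters(runs, "post")

    def test_aggregate_bounded_by_inputs(self):
        runs = [("post", _params(velocity=v)) for v in (60, 70, 80, 90, 100)]
        agg = aggregate_parameters(runs, "post")
        assert 60 <= agg.velocity <= 100


class TestPercentChange:
    @pytest.mark.parametrize(
        "post,pre,expected",
        [
            (89.9, 89.9, 0.0),
            (68.5, 205.2, -66.6),  # YC velocity change
            (57.3, 89.9, -36.3),  # YC LF stride change
        ],
    )
    def test_hand_values(self, post, pre, expected):
        assert percent_change(post, pre) == pytest.approx(expected, abs=0.05)

    @given(
        post=st.floats(min_value=0.1, max_value=1000),
        pre=st.floats(min_value=0.1, max_value=1000),
        c=st.floats(min_value=0.01, max_value=100),
    )
    def test_scale_invariance(self, post, pre, c):
        assert percent_change(c * post, c * pre) == pytest.approx(
            percent_change(post, pre), rel=1e-9, abs=1e-9
        )

    def test_zero_pre_rejected(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)

    def test_gait_changes_zero_for_identical_phases(self):
        p = _params()
        assert all(v == 0.0 for v in gait_changes(p, p).values())
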