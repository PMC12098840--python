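"""Closed-loop gating: soundness, breach latency, logging, determinism."""

import itertools

import numpy as np
import pandas as pd
import pytest

from magstim.controller import (
    ControllerConfig,
    GateSnapshot,
    SensorThresholds,
    ThresholdSpec,
    evaluate_gates,
    read_log,
    run_closed_loop,
    write_log,
    LOG_COLUMNS,
)
from magstim.errors import ConfigurationError, MagstimError, StreamTruncationError
from magstim.protocol import ProtocolPhase, StimulationProtocol
from magstim.synthetic import AnomalySpec, simulate_sensor_traces

THRESHOLDS = SensorThresholds(
    limits={
        "temperature": ThresholdSpec(upper=30.0),
        "sound": ThresholdSpec(upper=70.0),
        "vibration": ThresholdSpec(upper=1.0),
        "magnetic": ThresholdSpec(upper=60.0, lower=-60.0),
    }
)


def _positions(duration, poll_rate=20.0, in_target=True):
    t = np.arange(int(duration * poll_rate)) / poll_rate
    return pd.DataFrame(
        {"time_s": t, "chamber": "dark", "in_target": [in_target] * len(t)}
    )


@pytest.mark.parametrize(
    "protocol_on,sensors_ok,in_target",
    list(itertools.product([False, True], repeat=3)),
)
def test_gate_conjunction(protocol_on, sensors_ok, in_target):
    """Stimulation requires all three gates simultaneously."""
    snap = GateSnapshot(
        time=0.0, protocol_on=protocol_on, sensors_ok=sensors_ok, in_target=in_target
    )
    assert evaluate_gates(snap) == (protocol_on and sensors_ok and in_target)


def test_all_gates_pass_gives_full_protocol_on_time(short_protocol):
    duration = float(short_protocol.duration)
    sensors = simulate_sensor_traces(duration, 20.0, seed=0)
    log = run_closed_loop(short_protocol, sensors, _positions(duration), THRESHOLDS)
    on_time = (log["stim_state"] == "on").sum() / 20.0
    assert on_time == 10.0  # two 5 s windows
    # gate soundness: every ON row is inside an ON window and in target
    on_rows = log[log["stim_state"] == "on"]
    assert on_rows["in_target"].all()
    for t in on_rows["time_s"]:
        assert (0 <= t < 5) or (10 <= t < 15)


def test_breach_turns_stim_off_within_one_poll(short_protocol):
    """Temperature anomaly at t=2.00 s: off at or before t=2.05 s."""
    duration = float(short_protocol.duration)
    sensors = simulate_sensor_traces(
        duration,
        20.0,
        anomalies=[AnomalySpec("temperature", onset=2.0, duration=1.0, magnitude=10.0)],
        seed=0,
    )
    log = run_closed_loop(short_protocol, sensors, _positions(duration), THRESHOLDS)
    on = log[log["stim_state"] == "on"]["time_s"].to_numpy()
    assert np.any((on >= 0) & (on < 2.0))  # stimulating before the breach
    assert not np.any((on >= 2.05) & (on < 3.0))  # off within one poll
    assert np.any((on >= 3.1) & (on < 5.0))  # pause, not abort: resumes


def test_abort_latches_stimulation_off(short_protocol):
    duration = float(short_protocol.duration)
    sensors = simulate_sensor_traces(
        duration,
        20.0,
        anomalies=[AnomalySpec("sound", onset=2.0, duration=0.5, magnitude=40.0)],
        seed=0,
    )
    log = run_closed_loop(
        short_protocol,
        sensors,
        _positions(duration),
        THRESHOLDS,
        ControllerConfig(breach_action="abort"),
    )
    on = log[log["stim_state"] == "on"]["time_s"].to_numpy()
    assert on.max() < 2.05
    assert not np.any(on >= 2.05)


def test_out_of_target_window_blocks_stimulation(short_protocol):
    """Subject out of target during [2, 4) s of an ON window."""
    duration = float(short_protocol.duration)
    pos = _positions(duration)
    out = (pos["time_s"] >= 2.0) & (pos["time_s"] < 4.0)
    pos.loc[out, "in_target"] = False
    sensors = simulate_sensor_traces(duration, 20.0, seed=0)
    log = run_closed_loop(short_protocol, sensors, pos, THRESHOLDS)
    on = log[log["stim_state"] == "on"]["time_s"].to_numpy()
    assert not np.any((on >= 2.0) & (on < 4.0))
    assert np.any((on >= 4.0) & (on < 5.0))


def test_stale_sensor_fails_safe(short_protocol):
    """A sensor that stops reporting blocks stimulation two polls later."""
    duration = float(short_protocol.duration)
    sensors = simulate_sensor_traces(duration, 20.0, seed=0)
    sensors = sensors[
        ~((sensors["kind"] == "temperature") & (sensors["time_s"] >= 1.0))
    ]
    log = run_closed_loop(short_protocol, sensors, _positions(duration), THRESHOLDS)
    on = log[log["stim_state"] == "on"]["time_s"].to_numpy()
    assert not np.any(on >= 1.2)
    assert np.any(on < 1.0)


def test_threshold_tie_counts_as_breach(short_protocol):
    duration = float(short_protocol.duration)
    sensors = simulate_sensor_traces(
        duration, 20.0, baselines={"temperature": 30.0}, seed=0
    )
    log = run_closed_loop(short_protocol, sensors, _positions(duration), THRESHOLDS)
    assert (log["stim_state"] == "off").all()


def test_truncated_stream_raises_naming_stream(short_protocol):
    duration = float(short_protocol.duration)
    sensors = simulate_sensor_traces(duration / 4, 20.0, seed=0)
    with pytest.raises(StreamTruncationError, match="sensor stream"):
        run_closed_loop(short_protocol, sensors, _positions(duration), THRESHOLDS)


def test_thresholds_must_lie_in_detection_range():
    with pytest.raises(ConfigurationError, match="detection range"):
        SensorThresholds(limits={"temperature": ThresholdSpec(upper=200.0)})


def test_determinism_byte_for_byte(tmp_path, short_protocol):
    duration = float(short_protocol.duration)
    paths = []
    for name in ("a.csv", "b.csv"):
        sensors = simulate_sensor_traces(duration, 20.0, noise_sd=0.3, seed=9)
        log = run_closed_loop(short_protocol, sensors, _positions(duration), THRESHOLDS)
        path = tmp_path / name
        write_log(log, path)
        paths.append(path)
    assert paths[0].read_bytes() == paths[1].read_bytes()


class TestLogIO:
    def test_empty_log_is_header_only(self, tmp_path):
        path = tmp_path / "log.csv"
        write_log(pd.DataFrame(columns=LOG_COLUMNS), path)
        assert path.read_text().strip() == ",".join(LOG_COLUMNS)

    def test_round_trip_identity(self, tmp_path, short_protocol):
        duration = float(short_protocol.duration)
        sensors = simulate_sensor_traces(duration, 20.0, noise_sd=0.2, seed=3)
        log = run_closed_loop(short_protocol, sensors, _positions(duration), THRESHOLDS)
        path = tmp_path / "log.csv"
        write_log(log, path)
        back = read_log(path)
        pd.testing.assert_frame_equal(back, log)

    def test_five_minute_log_parses_with_monotone_check(self, tmp_path):
        n = 6000  # 5 min at 20 Hz
        t = np.arange(n) / 20.0
        log = pd.DataFrame(
            {
                "time_s": t,
                "mf_mT": 0.0,
                "temp_C": 24.0,
                "sound_dB": 45.0,
                "accel_g": 0.02,
                "stim_state": "off",
                "chamber": "dark",
                "in_target": True,
            }
        )
        path = tmp_path / "log.csv"
        write_log(log, path)
        assert len(read_log(path)) == 6000

    def test_non_monotone_time_rejected_with_row_number(self, tmp_path):
        log = pd.DataFrame(
            {
                "time_s": [0.0, 0.05, 0.05],
                "mf_mT": 0.0,
                "temp_C": 24.0,
                "sound_dB": 45.0,
                "accel_g": 0.0,
                "stim_state": "off",
                "chamber": "dark",
                "in_target": True,
            }
        )
        path = tmp_path / "log.csv"
        write_log(log, path)
        with pytest.raises(MagstimError, match="row 4"):
            read_log(path)
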