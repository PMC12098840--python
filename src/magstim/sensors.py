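"""Sensor models, raw-to-physical conversions, and agreement statistics.

The monitored quantities and their detection ranges:

==========  ==============  ==================
kind        example part    detection range
==========  ==============  ==================
magnetic    SS495A Hall     -67 .. 67 mT
temperature TMP36GT9Z       -40 .. 125 deg C
sound       SEN0232         30 .. 130 dB
vibration   ADXL345         -16 .. 16 g
==========  ==============  ==================

Transfer functions are replaceable calibration constants modeled on
standard part behavior: the Hall sensor is ratiometric (null at mid-supply,
31.25 mV/mT at a 5 V supply), the temperature sensor reads 10 mV/degC with
a 0.5 V offset, the sound level scales 50 dB/V.  The vibration part is
digital and already reports g directly.  Converted values outside a
sensor's detection range are clipped and flagged.

Agreement between a sensor and a reference instrument is summarized the
standard way: Pearson's correlation plus Bland-Altman bias and 1.96-SD
limits of agreement.  ``sus_score`` implements the System Usability Scale:
odd items contribute (score - 1), even items (5 - score), the sum times 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as _sps

from .errors import ConfigurationError, UndefinedStatisticError

__all__ = [
    "SENSOR_KINDS",
    "SensorSpec",
    "SENSOR_TABLE",
    "SensorReading",
    "Converted",
    "convert_hall",
    "convert_temperature",
    "convert_sound",
    "AgreementResult",
    "pearson_r",
    "bland_altman",
    "sus_score",
]

SENSOR_KINDS = ("magnetic", "temperature", "sound", "vibration")


@dataclass(frozen=True)
class SensorSpec:
    kind: str
    part: str
    supply_v: tuple
    supply_ma: float
    detection_range: tuple  # (min, max) in native units
    units: str


#: the platform's four monitoring sensors
SENSOR_TABLE = {
    "magnetic": SensorSpec("magnetic", "SS495A", (4.5, 10.5), 7.0, (-67.0, 67.0), "mT"),
    "temperature": SensorSpec(
        "temperature", "TMP36GT9Z", (2.7, 5.0), 0.05, (-40.0, 125.0), "degC"
    ),
    "sound": SensorSpec("sound", "SEN0232", (3.3, 5.0), 14.0, (30.0, 130.0), "dB"),
    "vibration": SensorSpec("vibration", "ADXL345", (2.0, 3.6), 0.14, (-16.0, 16.0), "g"),
}


@dataclass(frozen=True)
class SensorReading:
    """One typed sample in physical units; ``clipped`` marks range overflow."""

    time: float
    kind: str
    value: float
    clipped: bool = False


class Converted(NamedTuple):
    value: float
    clipped: bool


def _clip(kind: str, value: float) -> Converted:
    lo, hi = SENSOR_TABLE[kind].detection_range
    if value < lo:
        return Converted(lo, True)
    if value > hi:
        return Converted(hi, True)
    return Converted(value, False)


#: Hall sensitivity at a 5 V supply, volts per millitesla (3.125 mV/G)
HALL_V_PER_MT_AT_5V = 0.03125
TEMP_V_PER_DEGC = 0.010
TEMP_OFFSET_V = 0.5
SOUND_DB_PER_V = 50.0


def convert_hall(voltage: float, supply: float = 5.0) -> Converted:
    """Ratiometric Hall conversion: mid-supply null, sensitivity scaled by supply."""
    if supply <= 0:
        raise ConfigurationError("supply voltage must be > 0")
    if not 0 <= voltage <= supply:
        raise ConfigurationError(
            f"Hall output {voltage} V outside the 0..{supply} V supply rails"
        )
    sens = HALL_V_PER_MT_AT_5V * supply / 5.0
    return _clip("magnetic", (voltage - supply / 2.0) / sens)


def convert_temperature(voltage: float) -> Converted:
    """10 mV/degC with a 0.5 V offset (0.5 V reads 0 degC)."""
    if voltage < 0:
        raise ConfigurationError("sensor voltage must be >= 0")
    return _clip("temperature", (voltage - TEMP_OFFSET_V) / TEMP_V_PER_DEGC)


def convert_sound(voltage: float) -> Converted:
    """Linear 50 dB per volt."""
    if voltage < 0:
        raise ConfigurationError("sensor voltage must be >= 0")
    return _clip("sound", SOUND_DB_PER_V * voltage)


@dataclass(frozen=True)
class AgreementResult:
    """Pearson r plus Bland-Altman bias and limits of agreement."""

    pearson_r: float
    bias: float
    loa_lower: float
    loa_upper: float
    n: int


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Sample Pearson correlation of two equal-length series (n >= 3)."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("series must have equal length")
    if x.size < 3:
        raise ConfigurationError("Pearson correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a zero-variance series")
    return float(_sps.pearsonr(x, y).statistic)


def bland_altman(xs: Sequence[float], ys: Sequence[float]) -> AgreementResult:
    """Bland-Altman agreement of paired measurements.

    bias = mean(x - y); limits of agreement = bias +/- 1.96 * sample SD
    (ddof=1) of the differences.  Pearson r is included when defined, NaN
    for degenerate (zero-variance) input.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("series must have equal length")
    if x.size < 3:
        raise ConfigurationError("Bland-Altman analysis needs at least 3 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    try:
        r = pearson_r(x, y)
    except UndefinedStatisticError:
        r = float("nan")
    return AgreementResult(
        pearson_r=r,
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=int(x.size),
    )


def sus_score(response: Sequence[int]) -> float:
    """System Usability Scale score (0-100) of one 10-item response."""
    items = list(response)
    if len(items) != 10:
        raise ConfigurationError("a SUS response has exactly 10 items")
    if any((not float(i).is_integer()) or not 1 <= i <= 5 for i in items):
        raise ConfigurationError("SUS items must be integers in 1..5")
    total = sum(
        (item - 1) if idx % 2 == 0 else (5 - item)  # idx 0 is question 1 (odd)
        for idx, item in enumerate(items)
    )
    return total * 2.5
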