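"""Rule-based normal/abnormal screening of vital-sign samples.

The rules are fixed clinical thresholds:

* heart rate: normal band 60–100 bpm inclusive; below → bradycardia, above
  → tachycardia; an irregular rhythm → arrhythmia; PR interval > 0.2 s →
  atrioventricular (AV) block,
* body temperature: > 100.4 °F → fever,
* blood pressure: normal < 120/80; elevated when systolic 120–129 with
  diastolic < 80; stage-1 hypertension when systolic 130–139 or diastolic
  80–89 (readings above both bands are also flagged stage-1 or higher),
* SpO2: < 95 % → hypoxemia.

A sample is abnormal iff any flag fires; findings are returned as a
canonical sorted list so verdicts are order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "VitalSample",
    "ScreenVerdict",
    "FLAGS",
    "screen_heart",
    "screen_temperature",
    "screen_bp",
    "screen_spo2",
    "screen",
]

FLAGS = (
    "arrhythmia",
    "av_block",
    "bradycardia",
    "elevated_bp",
    "fever",
    "hypoxemia",
    "stage1_hypertension",
    "tachycardia",
)


def _check_range(name: str, value: Optional[float], lo: float, hi: float,
                 lo_open: bool = False, hi_open: bool = False) -> None:
    if value is None:
        return
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")
    below = value <= lo if lo_open else value < lo
    above = value >= hi if hi_open else value > hi
    if below or above:
        raise ValueError(f"{name}={value} outside physiologic range ({lo}, {hi})")


@dataclass(frozen=True)
class VitalSample:
    """One time-point of sensor readings; any subset of signals may be
    present, but at least one is required for screening."""

    heart_rate: Optional[float] = None        # bpm
    systolic: Optional[float] = None          # mmHg
    diastolic: Optional[float] = None         # mmHg
    temperature: Optional[float] = None       # deg F
    spo2: Optional[float] = None              # percent
    pr_interval: Optional[float] = None       # seconds
    rhythm_regular: Optional[bool] = None

    def __post_init__(self) -> None:
        _check_range("heart_rate", self.heart_rate, 0, 300, lo_open=True, hi_open=True)
        _check_range("spo2", self.spo2, 0, 100)
        _check_range("temperature", self.temperature, 80, 115, lo_open=True, hi_open=True)
        _check_range("systolic", self.systolic, 0, 300, lo_open=True, hi_open=True)
        _check_range("diastolic", self.diastolic, 0, 300, lo_open=True, hi_open=True)
        _check_range("pr_interval", self.pr_interval, 0, 2)

    def is_empty(self) -> bool:
        return all(
            v is None
            for v in (
                self.heart_rate,
                self.systolic,
                self.diastolic,
                self.temperature,
                self.spo2,
                self.pr_interval,
                self.rhythm_regular,
            )
        )


@dataclass(frozen=True)
class ScreenVerdict:
    overall: str                  # "normal" or "abnormal"
    findings: tuple[str, ...]     # canonical sorted flags


def screen_heart(
    hr: float,
    pr_interval: Optional[float] = None,
    rhythm_regular: Optional[bool] = None,
) -> list[str]:
    """Rate, rhythm and conduction flags. The 60–100 bpm band is inclusive
    at both ends; the PR threshold is strict (> 0.2 s)."""
    flags = []
    if hr < 60:
        flags.append("bradycardia")
    elif hr > 100:
        flags.append("tachycardia")
    if rhythm_regular is False:
        flags.append("arrhythmia")
    if pr_interval is not None and pr_interval > 0.2:
        flags.append("av_block")
    return flags


def screen_temperature(temperature: float) -> list[str]:
    """Fever iff strictly above 100.4 °F."""
    return ["fever"] if temperature > 100.4 else []


def screen_bp(systolic: float, diastolic: float) -> list[str]:
    """Blood-pressure banding: normal < 120/80, elevated 120–129 with
    diastolic < 80, stage-1 hypertension at 130–139 systolic or 80–89
    diastolic; readings beyond both bands carry the stage-1 flag too."""
    if systolic < 120 and diastolic < 80:
        return []
    if 120 <= systolic < 130 and diastolic < 80:
        return ["elevated_bp"]
    # stage-1 band, and anything higher
    return ["stage1_hypertension"]


def screen_spo2(spo2: float) -> list[str]:
    """Hypoxemia iff SpO2 below 95 %; 95 exactly is normal."""
    return ["hypoxemia"] if spo2 < 95 else []


def screen(sample: VitalSample) -> ScreenVerdict:
    """Union of all per-signal flags; abnormal iff any flag fires."""
    if sample.is_empty():
        raise ValueError("cannot screen an empty vital sample")
    flags: set[str] = set()
    if sample.heart_rate is not None:
        flags.update(screen_heart(sample.heart_rate, sample.pr_interval, sample.rhythm_regular))
    else:
        if sample.pr_interval is not None and sample.pr_interval > 0.2:
            flags.add("av_block")
        if sample.rhythm_regular is False:
            flags.add("arrhythmia")
    if sample.temperature is not None:
        flags.update(screen_temperature(sample.temperature))
    if sample.systolic is not None and sample.diastolic is not None:
        flags.update(screen_bp(sample.systolic, sample.diastolic))
    if sample.spo2 is not None:
        flags.update(screen_spo2(sample.spo2))
    findings = tuple(sorted(flags))
    return ScreenVerdict(
        overall="abnormal" if findings else "normal",
        findings=findings,
    )
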