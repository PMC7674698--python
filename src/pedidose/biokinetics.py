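"""Renogram biokinetics: per-minute source redistribution kidneys -> bladder.

A glomerularly filtered tracer (⁹⁹ᵐTc-DTPA) is taken up by the two kidneys at
injection and excreted to the bladder.  The model is deliberately minimal,
mirroring the dynamic-renography picture the dose analysis is built on:

* at t = 0 the administered activity is split equally between the kidneys;
* a kidney with relative function ``f`` drains linearly at a constant rate of
  ``f/20`` of its initial content per minute, i.e. it empties at ``20/f`` min
  (the 20-min normal transit); a kidney with ``f = 0`` never drains;
* drained activity accumulates in the bladder content (no voiding);
* radioactive decay is NOT applied here -- it enters through the
  decay-weighted dose integral downstream.

Fractions are of administered activity; each frame's compartment fractions
sum to one exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

COMPARTMENTS = ("kidney_L", "kidney_R", "bladder_content")

#: kidneys-to-bladder transit time at normal function, minutes
NORMAL_TRANSIT_MIN = 20.0

#: dynamic-test window, minutes ("up to 60 min in abnormal cases")
TEST_WINDOW_MIN = 60.0


@dataclass(frozen=True)
class Scenario:
    """One kidney-function condition for the dose pipeline."""

    function_left: float = 1.0
    function_right: float = 1.0
    administered_activity_B0: float = 1.0  # mCi
    sex: str = "male"
    integration_time_T: float | None = None  # minutes; None = ICRP rule
    frame_length: float = 1.0  # minutes

    def __post_init__(self) -> None:
        for f in (self.function_left, self.function_right):
            if not 0.0 <= f <= 1.0:
                raise ValueError("kidney function must lie in [0, 1]")
        if self.administered_activity_B0 <= 0:
            raise ValueError("administered activity B0 must be positive")
        if self.integration_time_T is not None and self.integration_time_T <= 0:
            raise ValueError("integration time T must be positive")
        if self.frame_length <= 0:
            raise ValueError("frame length must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")

    @property
    def is_normal(self) -> bool:
        return self.function_left == 1.0 and self.function_right == 1.0

    def default_horizon(self) -> float:
        """ICRP comparison horizon: 100 min normal, 1000 min degraded."""
        return 100.0 if self.is_normal else 1000.0


@dataclass(frozen=True)
class TimeActivity:
    """Piecewise-constant compartment fractions over 1-min frames."""

    frames: tuple[dict[str, float], ...]
    frame_length: float = 1.0

    def __post_init__(self) -> None:
        for m, fr in enumerate(self.frames):
            total = sum(fr.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frame {m}: fractions sum to {total!r}, not 1")

    @property
    def duration_min(self) -> float:
        return len(self.frames) * self.frame_length

    def fraction(self, compartment: str) -> np.ndarray:
        return np.array([fr.get(compartment, 0.0) for fr in self.frames])


def gfr_stage(gfr: float) -> int:
    """Chronic-kidney-disease stage (1-5) from GFR in mL/min/1.73 m².

    NKF-K/DOQI bins, half-open: [90, inf) -> 1, [60, 90) -> 2, [30, 60) -> 3,
    [15, 30) -> 4, [0, 15) -> 5.  Negative GFR raises ``ValueError``.
    """
    if gfr < 0:
        raise ValueError("GFR cannot be negative")
    for stage, lo in ((1, 90.0), (2, 60.0), (3, 30.0), (4, 15.0)):
        if gfr >= lo:
            return stage
    return 5


def _kidney_fraction(uptake: float, f: float, t: float) -> float:
    """Content of one kidney at time t (min) under linear drainage."""
    if f <= 0.0:
        return uptake
    return uptake * max(0.0, 1.0 - f * t / NORMAL_TRANSIT_MIN)


def build_time_activity(scenario: Scenario,
                        n_frames: int | None = None) -> TimeActivity:
    """Simulate the dynamic test window (default 60 one-minute frames).

    The administered activity starts split equally between the kidneys; each
    kidney drains linearly into the bladder at ``f/20`` of its initial
    content per minute.  Frame ``m`` holds the distribution at time
    ``m * frame_length`` (piecewise-constant source positions).
    """
    dt = scenario.frame_length
    if n_frames is None:
        n_frames = int(round(TEST_WINDOW_MIN / dt))
    uptake = {"kidney_L": 0.5, "kidney_R": 0.5}
    frames = []
    for m in range(n_frames):
        t = m * dt
        k_l = _kidney_fraction(uptake["kidney_L"], scenario.function_left, t)
        k_r = _kidney_fraction(uptake["kidney_R"], scenario.function_right, t)
        frames.append({"kidney_L": k_l, "kidney_R": k_r,
                       "bladder_content": 1.0 - k_l - k_r})
    return TimeActivity(tuple(frames), dt)


def extend_to_horizon(ta: TimeActivity, T: float) -> TimeActivity:
    """Repeat the final frame out to T minutes (static residual tail).

    After the dynamic window the source positions are frozen: bladder-held
    activity stays in the bladder and a non-draining kidney keeps its
    content, out to the integration horizon (decay handles the rest).
    """
    if T < ta.duration_min:
        raise ValueError(
            f"horizon T={T} min is shorter than the simulated {ta.duration_min} min")
    n_total = int(np.ceil(T / ta.frame_length - 1e-12))
    if n_total <= len(ta.frames):
        return ta
    tail = (ta.frames[-1],) * (n_total - len(ta.frames))
    return replace(ta, frames=ta.frames + tail)
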