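"""Stance detection from force and acceleration, step matching, filtering.

Force-plate stances are the contiguous regions where the filtered vGRF
exceeds 50 N.  Acceleration stances are found from the gravity-subtracted
vertical channel: an initial contact (IC) candidate at each upward crossing
of +0.18 g, kept only if the signal rises to at least +0.5 g shortly after
and was at or below 0 g shortly before, with a refractory period between
ICs; toe-off (TO) is the last downward crossing of -0.25 g before the next
IC, with the threshold relaxed stepwise toward -0.05 g when no crossing
exists.  Because threshold crossings on a smooth force curve lag the true
touchdown, both events are refined to the nearby crossing of a contact-onset
level (default -0.8 g, close to the free-fall floor of -1 g), which pins
them to the actual stance boundaries.

Acceleration- and force-detected steps are then matched one-to-one by
nearest IC time, and steps with implausible stance durations (outside
0.167-0.4 s) or signs of corruption are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import EventConfig
from .signals import SampledSignal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StanceInterval:
    """One detected ground contact, as sample indices into its source signal."""

    ic_index: int
    to_index: int
    rate: float
    source: str   # {"grf", "accel"}

    def __post_init__(self) -> None:
        if self.to_index <= self.ic_index:
            raise ValueError("to_index must exceed ic_index")
        if self.source not in ("grf", "accel"):
            raise ValueError("source must be 'grf' or 'accel'")

    @property
    def duration(self) -> float:
        return (self.to_index - self.ic_index) / self.rate

    @property
    def ic_time(self) -> float:
        return self.ic_index / self.rate

    @property
    def to_time(self) -> float:
        return self.to_index / self.rate


@dataclass(frozen=True)
class MatchedStep:
    """A force-plate stance paired with its acceleration-detected stance."""

    grf_stance: StanceInterval
    accel_stance: StanceInterval
    step_period: float   # s, accel IC to next accel IC
    next_accel_ic: int   # sample index of the following accel IC

    def __post_init__(self) -> None:
        if self.step_period <= self.accel_stance.duration:
            raise ValueError("step_period must exceed stance duration")


def detect_steps_grf(
    vgrf: SampledSignal, threshold_n: float = 50.0
) -> list[StanceInterval]:
    """Stance intervals where the force exceeds the absolute threshold.

    One interval per contiguous region with F > threshold; IC is the first
    and TO the last sample of the region.  Regions touching the signal
    boundary are incomplete steps and are discarded.
    """
    if vgrf.units != "N":
        raise ValueError("detect_steps_grf expects a force signal in N")
    above = vgrf.values > threshold_n
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    out = []
    for s, e in zip(starts, ends):
        if s == 0 or e == len(vgrf.values) - 1:
            continue   # boundary stance
        if e > s:
            out.append(StanceInterval(int(s), int(e), vgrf.rate, "grf"))
    return out


def _upward_crossings(x: np.ndarray, level: float) -> np.ndarray:
    return np.flatnonzero((x[:-1] <= level) & (x[1:] > level)) + 1


def _downward_crossings(x: np.ndarray, level: float) -> np.ndarray:
    return np.flatnonzero((x[:-1] > level) & (x[1:] <= level)) + 1


def detect_ic_accel(
    accel_v: SampledSignal, config: EventConfig = EventConfig()
) -> list[int]:
    """Initial-contact sample indices from vertical acceleration.

    Candidates are upward crossings of the IC threshold (+0.18 g); each must
    be followed by a rise to at least +0.5 g within 0.10 s and preceded by a
    value at or below 0 g within 0.10 s, and retained ICs are at least the
    refractory period apart.  A retained candidate is refined backwards to
    the last upward crossing of the contact-onset level (default -0.8 g)
    inside the lookback window, which marks the actual touchdown.
    """
    x = accel_v.values
    rate = accel_v.rate
    rise_n = max(1, int(round(config.ic_rise_window_s * rate)))
    fall_n = max(1, int(round(config.ic_fall_window_s * rate)))
    refractory_n = int(round(config.ic_refractory_s * rate))

    ics: list[int] = []
    for i in _upward_crossings(x, config.ic_threshold_g):
        if np.max(x[i : i + rise_n + 1]) < config.ic_rise_g:
            continue   # no expected increase after initial contact
        lo = max(0, i - fall_n)
        if np.min(x[lo:i]) > 0.0:
            continue   # no decrease before initial contact
        if ics and i - ics[-1] < refractory_n:
            continue
        onset = _upward_crossings(x[lo : i + 1], config.onset_threshold_g)
        ic = int(lo + onset[-1]) if len(onset) else int(i)
        if ics and ic - ics[-1] < refractory_n:
            continue
        ics.append(ic)
    return ics


def detect_to_accel(
    accel_v: SampledSignal,
    ic_index: int,
    next_ic_index: int,
    config: EventConfig = EventConfig(),
) -> tuple[int, float] | None:
    """Toe-off between two consecutive acceleration ICs.

    Returns ``(to_index, threshold_used)`` or None when no downward crossing
    exists even after relaxing the threshold to the ceiling (-0.05 g); such
    steps are flagged unmatched and dropped downstream.
    """
    if ic_index >= next_ic_index:
        raise ValueError("ic_index must precede next_ic_index")
    x = accel_v.values
    rate = accel_v.rate
    window = x[ic_index : next_ic_index + 1]

    threshold = config.to_threshold_g
    while threshold <= config.to_relax_ceiling_g + 1e-12:
        crossings = _downward_crossings(window, threshold)
        crossings = crossings[(crossings > 0) & (crossings < len(window) - 1)]
        if len(crossings):
            to = int(ic_index + crossings[-1])
            # refine forward to the settle crossing of the onset level
            settle_n = int(round(config.ic_fall_window_s * rate))
            seg = x[to : min(to + settle_n + 1, next_ic_index + 1)]
            settle = _downward_crossings(seg, config.onset_threshold_g)
            if len(settle):
                to = int(to + settle[0])
            return to, float(threshold)
        threshold += config.to_relax_step_g
    return None


def detect_steps_accel(
    accel_v: SampledSignal, config: EventConfig = EventConfig()
) -> list[StanceInterval]:
    """Acceleration-detected stances: paired IC/TO between consecutive ICs.

    The final IC has no successor and is dropped (incomplete step).
    """
    ics = detect_ic_accel(accel_v, config)
    out = []
    for ic, nxt in zip(ics[:-1], ics[1:]):
        found = detect_to_accel(accel_v, ic, nxt, config)
        if found is None:
            logger.debug("no toe-off for accel IC at sample %d; step dropped", ic)
            continue
        to, _ = found
        if to > ic:
            out.append(StanceInterval(ic, to, accel_v.rate, "accel"))
    return out


def match_steps(
    accel_stances: list[StanceInterval],
    grf_stances: list[StanceInterval],
    tolerance_s: float = 0.05,
) -> list[MatchedStep]:
    """Greedy one-to-one pairing of acceleration and force stances by
    nearest IC time (|dt| <= tolerance); unmatched stances on either side
    are dropped.  Matching is symmetric and independent of input order.

    The step period of a matched step spans its acceleration IC to the next
    acceleration IC in the input list; the last acceleration stance has no
    successor and cannot form a complete step.
    """
    accel = sorted(accel_stances, key=lambda s: s.ic_index)
    grf = sorted(grf_stances, key=lambda s: s.ic_index)
    if not accel or not grf:
        return []
    pairs = []
    for ai, a in enumerate(accel):
        for gi, g in enumerate(grf):
            dt = abs(a.ic_time - g.ic_time)
            if dt <= tolerance_s:
                pairs.append((dt, ai, gi))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_a: set[int] = set()
    used_g: set[int] = set()
    chosen: dict[int, int] = {}
    for dt, ai, gi in pairs:
        if ai in used_a or gi in used_g:
            continue
        used_a.add(ai)
        used_g.add(gi)
        chosen[ai] = gi
    out = []
    for ai in sorted(chosen):
        if ai + 1 >= len(accel):
            continue   # no next IC -> no step period
        a = accel[ai]
        nxt = accel[ai + 1].ic_index
        period = (nxt - a.ic_index) / a.rate
        if period <= a.duration:
            continue
        out.append(MatchedStep(grf[chosen[ai]], a, period, nxt))
    return out


def filter_steps(
    steps: list[MatchedStep],
    vgrf_bw: SampledSignal,
    config: EventConfig = EventConfig(),
) -> list[MatchedStep]:
    """Remove implausible or corrupted steps.

    A step survives when its force-plate stance duration lies within
    [0.167, 0.4] s (bounds inclusive), the stance window contains no NaN,
    and the stance peak reaches at least 1.2 BW (guards against the signal
    falling away mid-stance).
    """
    if vgrf_bw.units != "BW":
        raise ValueError("filter_steps expects the body-weight-normalized vGRF")
    out = []
    for step in steps:
        g = step.grf_stance
        if not config.min_stance_s <= g.duration <= config.max_stance_s:
            continue
        window = vgrf_bw.values[g.ic_index : g.to_index + 1]
        if np.any(np.isnan(window)):
            continue
        if np.nanmax(window) < config.min_peak_bw:
            continue
        out.append(step)
    return out
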