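"""Sampled-signal containers, preprocessing, and trial I/O.

The pipeline works on two time-aligned channels per running trial: vertical
ground reaction force from an instrumented treadmill (Newtons, ~1200 Hz) and
3-D sacral acceleration (gravity-subtracted g units, ~240 Hz).  This module
provides the containers for these signals, the zero-phase Butterworth
low-pass filtering used before event detection, body-weight normalization,
rate conversion, and a plain-CSV trial format that preserves the native
sampling rate of each channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import GRAVITY

logger = logging.getLogger(__name__)

#: Units a SampledSignal may carry.
VALID_UNITS = ("N", "BW", "g")


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled channel.

    Parameters
    ----------
    values : ndarray
        Sample values.
    rate : float
        Sampling rate in Hz, strictly positive.
    units : {"N", "BW", "g"}
        Physical units of the values.
    label : str
        Channel name, e.g. ``"grf"`` or ``"accel_v"``.
    """

    values: np.ndarray
    rate: float
    units: str
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("values must be a 1-D array of length >= 2")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Span of the sample grid in seconds, (n-1)/rate."""
        return (len(self.values) - 1) / self.rate

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at t=0."""
        return np.arange(len(self.values)) / self.rate


@dataclass(frozen=True)
class SubjectInfo:
    """Anthropometrics of one participant."""

    subject_id: str
    mass: float          # kg
    leg_length: float    # m, hip-to-ground during standing
    preferred_speed: float = 3.0   # m/s

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.leg_length <= 0 or self.preferred_speed <= 0:
            raise ValueError(
                "mass, leg_length and preferred_speed must be strictly positive"
            )


@dataclass(frozen=True)
class TrialRecord:
    """One treadmill trial: force plus sacral acceleration, time-aligned at t=0."""

    subject: SubjectInfo
    speed: float         # m/s
    grf: SampledSignal                  # N
    accel_v: SampledSignal              # g, vertical (gravity-subtracted)
    accel_ap: SampledSignal             # g, anterior-posterior
    accel_ml: SampledSignal             # g, medio-lateral
    accel_neck_v: SampledSignal | None = None
    accel_l5_v: SampledSignal | None = None

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")


def butterworth_lowpass(sig: SampledSignal, order: int, cutoff: float) -> SampledSignal:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The filter is applied bidirectionally with odd-reflection padding of three
    times the filter order, so there is no group delay and event timing is
    preserved; the effective magnitude response is |H(f)|^2, i.e. the gain at
    the cutoff is 0.5 rather than 1/sqrt(2).

    Raises
    ------
    ValueError
        If ``cutoff`` is not inside (0, rate/2).
    """
    nyquist = sig.rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, {nyquist}) Hz")
    sos = sps.butter(order, cutoff, btype="low", fs=sig.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, sig.values, padtype="odd", padlen=3 * order)
    return replace(sig, values=filtered)


def normalize_to_bw(grf: SampledSignal, mass: float) -> SampledSignal:
    """Divide a force signal (N) by body weight m*g, yielding BW units."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if grf.units != "N":
        raise ValueError(f"normalize_to_bw expects units 'N', got {grf.units!r}")
    return replace(grf, values=grf.values / (mass * GRAVITY), units="BW")


def resample_to(sig: SampledSignal, target_rate: float) -> SampledSignal:
    """Linearly interpolate a signal onto a new uniform grid.

    The target grid spans the common support [0, duration]; endpoints are
    preserved.  Linear interpolation is exact for degree-1 signals and
    adequate for band-limited content well below either Nyquist rate.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == sig.rate:
        return sig
    t_old = sig.times()
    n_new = int(np.floor(sig.duration * target_rate)) + 1
    t_new = np.arange(n_new) / target_rate
    return replace(sig, values=np.interp(t_new, t_old, sig.values), rate=target_rate)


# ---------------------------------------------------------------------------
# Trial CSV I/O
#
# One file per trial.  GRF and acceleration keep their native rates by using
# separate time columns; the shorter channel block is NaN-padded at the tail.
# ---------------------------------------------------------------------------

_GRF_COLS = ["time_s", "grf_n"]
_ACCEL_COLS = ["accel_time_s", "accel_v_g", "accel_ap_g", "accel_ml_g"]
_OPT_COLS = ["accel_neck_v_g", "accel_l5_v_g"]


def write_trial(record: TrialRecord, path: str | Path) -> None:
    """Write a trial to CSV (columns: time_s, grf_n, accel_time_s, accel_*_g)."""
    n = max(len(record.grf), len(record.accel_v))

    def pad(x: np.ndarray) -> np.ndarray:
        return np.concatenate([x, np.full(n - len(x), np.nan)])

    data = {
        "time_s": pad(record.grf.times()),
        "grf_n": pad(record.grf.values),
        "accel_time_s": pad(record.accel_v.times()),
        "accel_v_g": pad(record.accel_v.values),
        "accel_ap_g": pad(record.accel_ap.values),
        "accel_ml_g": pad(record.accel_ml.values),
    }
    if record.accel_neck_v is not None:
        data["accel_neck_v_g"] = pad(record.accel_neck_v.values)
    if record.accel_l5_v is not None:
        data["accel_l5_v_g"] = pad(record.accel_l5_v.values)
    pd.DataFrame(data).to_csv(path, index=False)


def _rate_from_times(t: np.ndarray) -> float:
    return 1.0 / float(np.median(np.diff(t)))


def read_trial(
    path: str | Path,
    subject: SubjectInfo,
    speed: float,
) -> TrialRecord:
    """Read a trial CSV written by :func:`write_trial`.

    Raises
    ------
    ValueError
        If required columns are missing (the error lists them).  Unknown
        extra columns are ignored with a logged warning.
    """
    df = pd.read_csv(path)
    required = _GRF_COLS + _ACCEL_COLS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} is missing required columns: {missing}")
    extra = [c for c in df.columns if c not in required + _OPT_COLS]
    if extra:
        logger.warning("trial file %s: ignoring unknown columns %s", path, extra)

    grf_mask = df["time_s"].notna().to_numpy()
    acc_mask = df["accel_time_s"].notna().to_numpy()
    grf_rate = _rate_from_times(df.loc[grf_mask, "time_s"].to_numpy())
    acc_rate = _rate_from_times(df.loc[acc_mask, "accel_time_s"].to_numpy())

    def acc(col: str) -> SampledSignal:
        return SampledSignal(
            df.loc[acc_mask, col].to_numpy(), acc_rate, "g", col.removesuffix("_g")
        )

    return TrialRecord(
        subject=subject,
        speed=speed,
        grf=SampledSignal(df.loc[grf_mask, "grf_n"].to_numpy(), grf_rate, "N", "grf"),
        accel_v=acc("accel_v_g"),
        accel_ap=acc("accel_ap_g"),
        accel_ml=acc("accel_ml_g"),
        accel_neck_v=acc("accel_neck_v_g") if "accel_neck_v_g" in df.columns else None,
        accel_l5_v=acc("accel_l5_v_g") if "accel_l5_v_g" in df.columns else None,
    )


def write_cohort_metadata(rows: list[dict], path: str | Path) -> None:
    """Write the cohort metadata table (subject_id, mass_kg, leg_length_m,
    speed_ms, trial_path)."""
    pd.DataFrame(rows, columns=["subject_id", "mass_kg", "leg_length_m", "speed_ms", "trial_path"]).to_csv(path, index=False)


def read_cohort(meta_path: str | Path) -> list[TrialRecord]:
    """Read every trial listed in a cohort metadata CSV."""
    meta_path = Path(meta_path)
    meta = pd.read_csv(meta_path)
    records = []
    for _, row in meta.iterrows():
        subject = SubjectInfo(
            subject_id=str(row["subject_id"]),
            mass=float(row["mass_kg"]),
            leg_length=float(row["leg_length_m"]),
        )
        trial_path = Path(row["trial_path"])
        if not trial_path.is_absolute():
            trial_path = meta_path.parent / trial_path
        records.append(read_trial(trial_path, subject, float(row["speed_ms"])))
    return records
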