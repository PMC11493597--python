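"""Per-step feature tables from acceleration windows and subject metadata.

Three feature families feed the regression models:

* **subject** — body mass and leg length, constant across a subject's steps;
* **general** — a frozen, versioned catalogue of time-series descriptors
  computed per acceleration axis on the step window (moments, energy,
  crossings, autocorrelations, dominant DFT frequency, linear trend);
* **domain** — step frequency and the vertical-acceleration impulse over
  the stance and over the entire step.

Windows come in two kinds, ``stance`` (IC to TO) and ``entire_step`` (IC to
the next IC); the impulse models use entire-step windows by default, the
others stance windows.  Cleaning removes features with missing values or
zero variance and one-hot encodes categoricals; standardization is always
fit on training rows only and applied unchanged elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FeatureConfig
from .events import MatchedStep
from .signals import SampledSignal, SubjectInfo

logger = logging.getLogger(__name__)

#: Features of catalogue "v1", computed per axis.
CATALOGUE_V1 = (
    "mean",
    "std",
    "min",
    "max",
    "median",
    "skewness",
    "kurtosis",
    "rms",
    "abs_energy",
    "mean_crossings",
    "autocorr_lag1",
    "autocorr_lag5",
    "autocorr_lag10",
    "dominant_freq_hz",
    "dominant_freq_mag",
    "trend_slope",
)

#: Columns that identify a step rather than describe it.
KEY_COLUMNS = ("subject_id", "trial", "step_index", "speed")


def subject_features(subject: SubjectInfo) -> dict[str, float]:
    """Anthropometric features: mass (kg) and leg length (m)."""
    return {"mass_kg": subject.mass, "leg_length_m": subject.leg_length}


def domain_features(accel_v: SampledSignal, step: MatchedStep) -> dict[str, float]:
    """Step frequency and vertical-acceleration impulses (stance / step)."""
    a = step.accel_stance
    stance_win = accel_v.values[a.ic_index : a.to_index + 1]
    step_win = accel_v.values[a.ic_index : step.next_accel_ic + 1]
    dt = 1.0 / accel_v.rate
    return {
        "step_frequency_hz": 1.0 / step.step_period,
        "accel_impulse_stance": float(np.trapezoid(stance_win, dx=dt)),
        "accel_impulse_step": float(np.trapezoid(step_win, dx=dt)),
    }


def _autocorr(x: np.ndarray, lag: int) -> float:
    n = len(x)
    if lag >= n - 1:
        return 0.0
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return np.nan
    return float(xc[:-lag] @ xc[lag:]) / denom


def general_ts_features(
    window: np.ndarray, rate: float, prefix: str = ""
) -> dict[str, float]:
    """The frozen catalogue of time-series descriptors for one axis window.

    Deterministic: identical windows yield identical feature vectors.
    Moments use population conventions (skewness m3/m2^1.5, excess kurtosis
    m4/m2^2 - 3); the dominant frequency is the largest non-DC magnitude of
    the real DFT, reported in Hz so it is window-length invariant.
    """
    x = np.asarray(window, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("window must contain at least 4 samples")
    mean = float(x.mean())
    xc = x - mean
    m2 = float(np.mean(xc**2))
    sd = float(np.sqrt(m2))
    if m2 > 0:
        skew = float(np.mean(xc**3)) / m2**1.5
        kurt = float(np.mean(xc**4)) / m2**2 - 3.0
    else:
        skew, kurt = 0.0, 0.0
    crossings = int(np.count_nonzero(np.diff(np.signbit(xc))))
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    k = 1 + int(np.argmax(spectrum[1:]))
    slope = float(np.polyfit(np.arange(n) / rate, x, 1)[0])
    feats = {
        "mean": mean,
        "std": sd,
        "min": float(x.min()),
        "max": float(x.max()),
        "median": float(np.median(x)),
        "skewness": skew,
        "kurtosis": kurt,
        "rms": float(np.sqrt(np.mean(x**2))),
        "abs_energy": float(x @ x),
        "mean_crossings": float(crossings),
        "autocorr_lag1": _autocorr(x, 1),
        "autocorr_lag5": _autocorr(x, 5),
        "autocorr_lag10": _autocorr(x, 10),
        "dominant_freq_hz": float(freqs[k]),
        "dominant_freq_mag": float(spectrum[k]),
        "trend_slope": slope,
    }
    return {f"{prefix}{k_}": v for k_, v in feats.items()}


def step_feature_row(
    subject: SubjectInfo,
    speed: float,
    accel: dict[str, SampledSignal],
    step: MatchedStep,
    window_kind: str,
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Assemble one step's full feature mapping (no key columns).

    ``accel`` maps axis name ("v", "ap", "ml") to the filtered acceleration
    channel; ``window_kind`` selects stance (IC-TO) or entire-step (IC-next
    IC) windows for the general catalogue.
    """
    if window_kind not in ("stance", "entire_step"):
        raise ValueError("window_kind must be 'stance' or 'entire_step'")
    a = step.accel_stance
    lo = a.ic_index
    hi = a.to_index if window_kind == "stance" else step.next_accel_ic
    row: dict[str, float] = {}
    row.update(subject_features(subject))
    for axis in config.axes:
        sig = accel[axis]
        row.update(
            general_ts_features(sig.values[lo : hi + 1], sig.rate, prefix=f"{axis}_")
        )
    row["window_duration_s"] = (hi - lo) / accel["v"].rate
    row.update(domain_features(accel["v"], step))
    row["speed_ms"] = speed
    return row


def feature_category(name: str) -> str:
    """Provenance category of a feature column: subject/general/domain/speed."""
    if name in ("mass_kg", "leg_length_m"):
        return "subject"
    if name in ("step_frequency_hz", "accel_impulse_stance", "accel_impulse_step"):
        return "domain"
    if name == "speed_ms":
        return "speed"
    return "general"


@dataclass(frozen=True)
class FeatureTable:
    """Rectangular per-step feature table with key columns and categories."""

    frame: pd.DataFrame
    window_kind: str

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in KEY_COLUMNS]

    @property
    def categories(self) -> dict[str, str]:
        return {c: feature_category(c) for c in self.feature_columns}


def clean_features(table: FeatureTable) -> FeatureTable:
    """Drop feature columns with any missing value or zero variance, and
    one-hot encode categorical (non-numeric) columns.

    The dropped columns are logged.  One-hot indicator columns produced here
    are exempt from later standardization.
    """
    df = table.frame.copy()
    feat_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    cat_cols = [c for c in feat_cols if not pd.api.types.is_numeric_dtype(df[c])]
    if cat_cols:
        df = pd.get_dummies(df, columns=cat_cols, dtype=float)
    drop = []
    for c in [c for c in df.columns if c not in KEY_COLUMNS]:
        col = df[c]
        if col.isna().any() or col.nunique(dropna=False) <= 1:
            drop.append(c)
    if drop:
        logger.info("clean_features: dropping %d columns: %s", len(drop), drop)
        df = df.drop(columns=drop)
    return FeatureTable(df, table.window_kind)


@dataclass(frozen=True)
class Scaler:
    """Per-column z-score parameters fitted on training rows only."""

    means: pd.Series
    sds: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self.means.index:
            out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out


def is_onehot(col: pd.Series) -> bool:
    vals = set(col.dropna().unique().tolist())
    return vals <= {0.0, 1.0}


def standardize(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[list[pd.DataFrame], Scaler]:
    """Z-score numeric feature columns using train-set mean/SD (population
    SD, ddof=0); one-hot indicator columns are left untouched.  Columns with
    zero training SD are dropped from all tables with a warning.

    Returns the transformed [train, *others] and the fitted scaler.
    """
    feat_cols = [c for c in train.columns if c not in KEY_COLUMNS]
    numeric = [c for c in feat_cols if not is_onehot(train[c])]
    means = train[numeric].mean()
    sds = train[numeric].std(ddof=0)
    dead = [c for c in numeric if sds[c] == 0.0 or not np.isfinite(sds[c])]
    if dead:
        logger.warning("standardize: dropping zero-variance columns %s", dead)
        numeric = [c for c in numeric if c not in dead]
        means, sds = means[numeric], sds[numeric]
    scaler = Scaler(means, sds)
    out = []
    for df in (train, *others):
        df = df.drop(columns=[c for c in dead if c in df.columns])
        out.append(scaler.transform(df))
    return out, scaler
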