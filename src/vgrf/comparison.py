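"""Literature baselines the main method is compared against.

Two established single-IMU approaches are reimplemented:

* **Alcantara-style** (active peak, impulse, contact time, step frequency):
  the vGRF is approximated directly from whole-body dynamics as
  F_est(t) = m*g*(a(t)+1) (clipped at zero), the characteristics are read
  off this curve over the acceleration-detected stances, and a per-target
  ordinary least-squares model maps {matched estimate, mass, speed} to the
  force-plate target.

* **Veras-style single-segment** (impact peak): the trunk is treated as a
  single segment whose centre-of-mass acceleration is a linear
  interpolation between the neck-base and L5-base channels; the segment
  force curve S(t) = trunk_mass_fraction*m*g*(a_com(t)+1), expressed in
  body weights of the whole body, yields an estimated impact peak that an
  OLS model maps to the true impact peak.

Both baselines consume only acceleration-side inputs at prediction time and
are evaluated with the same subject splits and metrics as the main method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characteristics import active_peak, impact_peak, stance_impulse
from .config import CharacteristicsConfig
from .events import StanceInterval
from .signals import SampledSignal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnthropometricModel:
    """Trunk segment parameters (fractions of whole-body quantities).

    Defaults follow standard anthropometric tables: the trunk carries
    43.46% of body mass and its centre of mass sits 44.86% of the way down
    the neck-to-L5 segment from the cranial end.
    """

    trunk_mass_fraction: float = 0.4346
    trunk_com_fraction: float = 0.4486

    def __post_init__(self) -> None:
        if not 0 < self.trunk_mass_fraction < 1:
            raise ValueError("trunk_mass_fraction must lie in (0, 1)")
        if not 0 < self.trunk_com_fraction < 1:
            raise ValueError("trunk_com_fraction must lie in (0, 1)")


def estimated_vgrf_bw(accel_v: SampledSignal) -> SampledSignal:
    """Whole-body vGRF estimate in BW from gravity-subtracted acceleration:
    a+1, clipped at zero (forces are nonnegative)."""
    if accel_v.units != "g":
        raise ValueError("expected acceleration in g units")
    return SampledSignal(
        np.maximum(accel_v.values + 1.0, 0.0), accel_v.rate, "BW", "est_vgrf"
    )


def alcantara_characteristics(
    accel_v: SampledSignal,
    stances: list[StanceInterval],
    step_periods: list[float],
) -> pd.DataFrame:
    """Per-step characteristic estimates from the acceleration-derived vGRF.

    ``stances`` are acceleration-detected; ``step_periods`` give the
    IC-to-next-IC duration per stance.  Returns one row per step with
    est_active_peak (BW), est_contact_time (s), est_impulse (BW*s), and
    est_step_frequency (Hz).
    """
    if len(stances) != len(step_periods):
        raise ValueError("stances and step_periods must align")
    est = estimated_vgrf_bw(accel_v)
    rows = []
    for stance, period in zip(stances, step_periods):
        window = est.values[stance.ic_index : stance.to_index + 1]
        rows.append(
            {
                "est_active_peak": active_peak(window),
                "est_contact_time": stance.duration,
                "est_impulse": stance_impulse(window, est.rate),
                "est_step_frequency": 1.0 / period,
            }
        )
    return pd.DataFrame(rows)


#: estimated regressor matched to each prediction target
ALCANTARA_MATCH = {
    "active_peak": "est_active_peak",
    "impulse": "est_impulse",
    "contact_time": "est_contact_time",
}


@dataclass(frozen=True)
class OlsModel:
    """Plain least-squares regression used by both baselines."""

    intercept: float
    coefficients: dict[str, float]

    @classmethod
    def fit(cls, X: pd.DataFrame, y: np.ndarray) -> "OlsModel":
        Xm = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(Xm, np.asarray(y, dtype=float), rcond=None)
        return cls(float(beta[0]), dict(zip(X.columns, map(float, beta[1:]))))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        cols = list(self.coefficients)
        beta = np.array([self.coefficients[c] for c in cols])
        return self.intercept + X[cols].to_numpy(dtype=float) @ beta


def alcantara_regress(
    est: pd.DataFrame, target_name: str, y: np.ndarray
) -> tuple[OlsModel, np.ndarray]:
    """OLS of one target on its matched estimate plus body mass and speed.

    ``est`` must contain the matched ``est_*`` column and ``mass_kg`` and
    ``speed_ms`` columns.  Returns the fitted model and its in-sample
    predictions.
    """
    if target_name not in ALCANTARA_MATCH:
        raise ValueError(f"Alcantara baseline does not cover {target_name!r}")
    cols = [ALCANTARA_MATCH[target_name], "mass_kg", "speed_ms"]
    model = OlsModel.fit(est[cols], y)
    return model, model.predict(est[cols])


def trunk_com_acceleration(
    accel_neck_v: SampledSignal,
    accel_l5_v: SampledSignal,
    anthro: AnthropometricModel = AnthropometricModel(),
) -> SampledSignal:
    """Trunk centre-of-mass acceleration by linear interpolation between the
    neck-base and L5-base channels: (1-f)*a_neck + f*a_l5."""
    if len(accel_neck_v) != len(accel_l5_v) or accel_neck_v.rate != accel_l5_v.rate:
        raise ValueError("neck and L5 channels must be time-aligned")
    f = anthro.trunk_com_fraction
    values = (1.0 - f) * accel_neck_v.values + f * accel_l5_v.values
    return SampledSignal(values, accel_neck_v.rate, "g", "accel_trunk_com_v")


def veras_impact_peak(
    a_com: SampledSignal,
    stances: list[StanceInterval],
    anthro: AnthropometricModel = AnthropometricModel(),
    config: CharacteristicsConfig = CharacteristicsConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Estimated impact peak per stance from the single-segment trunk curve.

    The segment curve S(t) = trunk_mass_fraction*(a_com+1) is expressed in
    whole-body BW; its impact peak is extracted with the same operator used
    on the force plate.  Returns ``(estimates, found_mask)`` aligned with
    ``stances``; steps without a detectable segment impact peak are flagged
    False (and excluded by the caller).
    """
    curve = np.maximum(
        anthro.trunk_mass_fraction * (a_com.values + 1.0), 0.0
    )
    est = np.full(len(stances), np.nan)
    found = np.zeros(len(stances), dtype=bool)
    for i, stance in enumerate(stances):
        window = curve[stance.ic_index : stance.to_index + 1]
        peak = impact_peak(window, config)
        if peak is not None:
            est[i] = peak
            found[i] = True
    n_missing = int((~found).sum())
    if n_missing:
        logger.info("veras_impact_peak: no segment impact peak on %d steps", n_missing)
    return est, found
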