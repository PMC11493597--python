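"""The four vGRF characteristics of a stance: active peak, impact peak,
impulse, and contact time.

All operators act on the body-weight-normalized force over one stance
window.  The active peak is the global stance maximum (~2.4 BW near
mid-stance); the impact peak is the first local maximum within the first
10% of stance, when one exists (rearfoot strikes only); the impulse is the
trapezoidal time integral in BW*s; contact time is the stance duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .config import CharacteristicsConfig
from .events import StanceInterval
from .signals import SampledSignal


@dataclass(frozen=True)
class StepCharacteristics:
    active_peak: float           # BW
    impulse: float               # BW*s
    contact_time: float          # s
    impact_peak: float | None = None   # BW, None when absent

    def __post_init__(self) -> None:
        if self.active_peak <= 0:
            raise ValueError("active_peak must be positive")
        if self.impulse <= 0:
            raise ValueError("impulse must be positive")
        if self.contact_time <= 0:
            raise ValueError("contact_time must be positive")
        if self.impact_peak is not None and self.impact_peak >= self.active_peak:
            raise ValueError("impact_peak must be below active_peak")


def active_peak(stance_vgrf: np.ndarray) -> float:
    """Maximum of the stance window (BW)."""
    stance_vgrf = np.asarray(stance_vgrf, dtype=float)
    if stance_vgrf.size == 0:
        raise ValueError("empty stance window")
    return float(np.max(stance_vgrf))


def impact_peak(
    stance_vgrf: np.ndarray, config: CharacteristicsConfig = CharacteristicsConfig()
) -> float | None:
    """Value of the first local maximum in the first 10% of stance, or None.

    A local maximum is a strict sign change of the first difference with
    prominence of at least 0.05 BW; both the window fraction and the
    prominence floor are configurable.
    """
    stance_vgrf = np.asarray(stance_vgrf, dtype=float)
    if stance_vgrf.size == 0:
        raise ValueError("empty stance window")
    peaks, _ = find_peaks(stance_vgrf, prominence=config.impact_prominence_bw)
    limit = config.impact_window_frac * len(stance_vgrf)
    for idx in peaks:
        if idx < limit:
            return float(stance_vgrf[idx])
        break
    return None


def stance_impulse(stance_vgrf: np.ndarray, rate: float) -> float:
    """Trapezoidal time integral of the stance window, BW*s."""
    stance_vgrf = np.asarray(stance_vgrf, dtype=float)
    if rate <= 0:
        raise ValueError("rate must be positive")
    return float(np.trapezoid(stance_vgrf, dx=1.0 / rate))


def contact_time(stance: StanceInterval) -> float:
    """Stance duration in seconds."""
    return stance.duration


def extract_characteristics(
    vgrf_bw: SampledSignal,
    stance: StanceInterval,
    config: CharacteristicsConfig = CharacteristicsConfig(),
) -> StepCharacteristics:
    """All four characteristics of one force-plate stance."""
    if vgrf_bw.units != "BW":
        raise ValueError("expected body-weight-normalized force")
    window = vgrf_bw.values[stance.ic_index : stance.to_index + 1]
    return StepCharacteristics(
        active_peak=active_peak(window),
        impact_peak=impact_peak(window, config),
        impulse=stance_impulse(window, vgrf_bw.rate),
        contact_time=contact_time(stance),
    )
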