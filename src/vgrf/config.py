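"""Run-time configuration for the vGRF prediction pipeline.

All tunable constants of the pipeline live here as frozen dataclasses with
the defaults used throughout: filter settings, gait-event thresholds,
feature-catalogue options, the Lasso regularization grid, and the synthetic
cohort parameters.  A :class:`RunConfig` can be loaded from a YAML file with
:func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: Standard gravity used for all body-weight normalization, m/s^2.
GRAVITY = 9.81

#: Prediction targets, in report order.
TARGETS = ("active_peak", "impact_peak", "impulse", "contact_time")


@dataclass(frozen=True)
class FilterConfig:
    """Zero-phase Butterworth low-pass settings."""

    grf_cutoff_hz: float = 30.0
    accel_cutoff_hz: float = 60.0
    order: int = 5


@dataclass(frozen=True)
class EventConfig:
    """Thresholds for step detection from force and acceleration.

    The force threshold is absolute (Newtons, applied before body-weight
    normalization); acceleration thresholds are in gravity-subtracted g
    units (flight = -1 g).
    """

    grf_threshold_n: float = 50.0
    ic_threshold_g: float = 0.18
    ic_rise_g: float = 0.5            # required rise after the IC crossing
    ic_rise_window_s: float = 0.10
    ic_fall_window_s: float = 0.10    # lookback window: must have been <= 0 g
    ic_refractory_s: float = 0.20
    onset_threshold_g: float = -0.95  # contact-onset refinement level
    to_threshold_g: float = -0.25
    to_relax_step_g: float = 0.05
    to_relax_ceiling_g: float = -0.05
    match_tolerance_s: float = 0.05
    min_stance_s: float = 0.167
    max_stance_s: float = 0.4
    min_peak_bw: float = 1.2          # corruption heuristic: signal falling away


@dataclass(frozen=True)
class CharacteristicsConfig:
    """Operational definition of the impact peak."""

    impact_window_frac: float = 0.10
    impact_prominence_bw: float = 0.05


@dataclass(frozen=True)
class FeatureConfig:
    catalogue_version: str = "v1"
    axes: tuple[str, ...] = ("v", "ap", "ml")
    #: window kind per target; impulse uses the entire step, others the stance
    window_by_target: dict = field(
        default_factory=lambda: {
            "active_peak": "stance",
            "impact_peak": "stance",
            "impulse": "entire_step",
            "contact_time": "stance",
        }
    )


@dataclass(frozen=True)
class ModelConfig:
    """One Lasso prediction task."""

    target: str = "active_peak"
    use_speed: bool = False
    lambda_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.geomspace(5e-6, 0.05, 20))
    )
    window_kind: str = "stance"

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        grid = tuple(float(g) for g in self.lambda_grid)
        if not grid or list(grid) != sorted(grid):
            raise ValueError("lambda_grid must be nonempty and sorted")
        if grid[0] < 5e-6 - 1e-12 or grid[-1] > 0.05 + 1e-12:
            raise ValueError("lambda_grid must lie within [5e-6, 0.05]")
        object.__setattr__(self, "lambda_grid", grid)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic running cohort.

    Defaults emulate the study protocol: four fixed treadmill speeds per
    subject, force sampled at 1200 Hz, sacral acceleration at 240 Hz, and
    roughly 41% of steps carrying an impact peak.
    """

    n_subjects: int = 10
    speeds: tuple[float, ...] = (2.22, 2.50, 2.78, 3.33)
    trial_duration: float = 30.0
    grf_rate: float = 1200.0
    accel_rate: float = 240.0
    noise_sd_accel: float = 0.08      # g, per filtered channel
    noise_sd_grf: float = 5.0         # N
    impact_probability: float = 0.41
    seed: int = 0
    #: if False the vertical channel is emitted in raw (gravity-inclusive) g
    gravity_subtracted: bool = True

    def __post_init__(self) -> None:
        if self.grf_rate <= 0 or self.accel_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if not 0.0 <= self.impact_probability <= 1.0:
            raise ValueError("impact_probability must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(s <= 0 for s in self.speeds):
            raise ValueError("speeds must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    events: EventConfig = field(default_factory=EventConfig)
    characteristics: CharacteristicsConfig = field(default_factory=CharacteristicsConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    lambda_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.geomspace(5e-6, 0.05, 20))
    )
    test_fraction: float = 7.0 / 43.0
    speed_groups: tuple[float, ...] | None = None   # None -> unique test speeds
    seed: int = 0


def config_hash(config: RunConfig) -> str:
    """Stable sha256 of the canonical JSON form of a config."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if isinstance(val, list):
            val = tuple(val)
        kwargs[f.name] = val
    return cls(**kwargs)


_SECTIONS = {
    "cohort": CohortConfig,
    "filter": FilterConfig,
    "events": EventConfig,
    "characteristics": CharacteristicsConfig,
    "features": FeatureConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; missing keys take defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, val in data.items():
        if key in _SECTIONS:
            kwargs[key] = _build(_SECTIONS[key], val or {})
        elif key in {"lambda_grid", "speed_groups"}:
            kwargs[key] = tuple(val) if val is not None else None
        elif key in {"test_fraction", "seed"}:
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config key: {key!r}")
    return RunConfig(**kwargs)
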