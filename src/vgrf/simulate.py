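"""Synthetic running cohorts: paired vGRF + sacral-acceleration trials.

The study's dataset is private, so the pipeline is exercised on simulated
cohorts with exact per-step ground truth.  Each stance is modelled as a
half-sine active component plus an optional Gaussian impact bump:

    F(t) = m*g * [ A*sin(pi*t/T_c) + I*exp(-(t - f*T_c)^2 / (2*w^2)) ]

for t in [0, T_c] and zero outside (flight).  This is the simplest waveform
with the morphology of a rearfoot-strike force curve — an impact peak within
the first 10% of stance followed by a larger active peak near mid-stance —
and it has closed forms for the peak and the impulse, which the tests use
as oracles.

Vertical sacral acceleration follows from whole-body dynamics,
a(t) = F(t)/(m*g) - 1 in gravity-subtracted g units (flight = -1 g, quiet
standing = 0 g); AP/ML channels are sensor noise.  Per-step stance
parameters have linear speed trends (contact time decreasing, peaks and
impulse increasing with speed) with subject-level random intercepts, so
subject-wise data splitting is meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf

from .config import GRAVITY, CohortConfig
from .signals import SampledSignal, SubjectInfo, TrialRecord

# Population parameters of the simulated cohort, pinned at the reference
# speed.  Means target an active peak of 2.44 BW and a contact time of
# 0.26 s; the speed slopes encode the usual trends (shorter contact, higher
# peaks at faster speeds).
REF_SPEED = 2.71          # m/s, mean of the four protocol speeds
ACTIVE_MEAN = 2.44        # BW
ACTIVE_SPEED_SLOPE = 0.25  # BW per m/s
ACTIVE_SUBJECT_SD = 0.15
ACTIVE_STEP_SD = 0.08
CONTACT_MEAN = 0.26       # s
CONTACT_SPEED_SLOPE = -0.045
CONTACT_SUBJECT_SD = 0.018
CONTACT_STEP_SD = 0.008
PERIOD_MEAN = 0.36        # s, IC-to-next-IC
PERIOD_SPEED_SLOPE = -0.03
PERIOD_SUBJECT_SD = 0.012
PERIOD_STEP_SD = 0.006
IMPACT_APEX_MEAN = 1.65   # BW, total curve value at the impact peak
IMPACT_APEX_SD = 0.15

MASS_MEAN, MASS_SD = 74.0, 11.9         # kg
LEG_LENGTH_MEAN, LEG_LENGTH_SD = 0.92, 0.05   # m


@dataclass(frozen=True)
class StanceParams:
    """Parameters of one simulated stance (force in BW, times in s)."""

    active_peak: float                 # A, BW
    contact_time: float                # T_c, s
    step_period: float                 # IC-to-next-IC, s
    impact_peak: float | None = None   # I, bump amplitude in BW; None = absent
    impact_time_frac: float = 0.05     # f, fraction of stance, in (0, 0.10]
    impact_width: float = 0.006        # w, s

    @property
    def has_impact(self) -> bool:
        return self.impact_peak is not None

    @property
    def is_valid_step(self) -> bool:
        """Whether the stance duration lies in the pipeline's valid range."""
        return 0.167 <= self.contact_time <= 0.4

    def validate(self) -> None:
        """Raise ValueError naming the first violated invariant."""
        if self.active_peak <= 0:
            raise ValueError("active_peak must be strictly positive")
        if self.contact_time <= 0:
            raise ValueError("contact_time must be strictly positive")
        if self.step_period <= self.contact_time:
            raise ValueError("step_period must exceed contact_time")
        if self.has_impact:
            if self.impact_peak <= 0:
                raise ValueError("impact_peak must be strictly positive")
            if not 0 < self.impact_time_frac <= 0.10:
                raise ValueError("impact_time_frac must lie in (0, 0.10]")
            if self.impact_width <= 0:
                raise ValueError("impact_width must be strictly positive")
            if self.active_peak <= self.impact_peak:
                raise ValueError("active_peak must exceed impact_peak")


def stance_waveform(t: np.ndarray, params: StanceParams) -> np.ndarray:
    """Normalized stance curve in BW at times ``t`` (s from initial contact).

    Zero outside [0, T_c].
    """
    t = np.asarray(t, dtype=float)
    tc = params.contact_time
    out = params.active_peak * np.sin(np.pi * np.clip(t, 0, tc) / tc)
    if params.has_impact:
        mu = params.impact_time_frac * tc
        out = out + params.impact_peak * np.exp(
            -((t - mu) ** 2) / (2 * params.impact_width**2)
        )
    return np.where((t >= 0) & (t <= tc), out, 0.0)


def stance_impulse_closed_form(params: StanceParams) -> float:
    """Closed-form time integral of the normalized stance curve, BW*s.

    Half-sine part integrates to 2*A*T_c/pi; the Gaussian bump contributes
    I*w*sqrt(2*pi) times the boundary-truncation factor from integrating
    over [0, T_c] only.
    """
    tc = params.contact_time
    total = 2.0 * params.active_peak * tc / math.pi
    if params.has_impact:
        mu = params.impact_time_frac * tc
        w = params.impact_width
        trunc = 0.5 * (
            erf((tc - mu) / (w * math.sqrt(2))) + erf(mu / (w * math.sqrt(2)))
        )
        total += params.impact_peak * w * math.sqrt(2 * math.pi) * trunc
    return total


def true_impact_peak(params: StanceParams) -> float | None:
    """Ground-truth impact-peak value (BW): the first local maximum of the
    continuous stance curve, or None when the curve has no local maximum in
    the first 10% of stance.

    Evaluated by a fine brute-force scan (10 microsecond grid) of the
    analytic waveform, independent of any sampled-signal code path.
    """
    if not params.has_impact:
        return None
    tc = params.contact_time
    t = np.arange(0.0, 0.12 * tc, 1e-5)
    y = stance_waveform(t, params)
    d = np.diff(y)
    sign_change = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0))
    for idx in sign_change:
        if t[idx + 1] <= 0.10 * tc:
            return float(y[idx + 1])
    return None


def analytic_crossing_times(
    params: StanceParams, mass: float, threshold_n: float
) -> tuple[float, float]:
    """Times (s from IC) at which the continuous force curve crosses a force
    threshold on the way up and on the way down.

    Root-found on the analytic waveform; used as the oracle for the offset
    between threshold-detected and true contact times.
    """
    thr_bw = threshold_n / (mass * GRAVITY)
    tc = params.contact_time

    def f(t: float) -> float:
        return float(stance_waveform(np.array([t]), params)[0]) - thr_bw

    t_mid = tc / 2.0
    if f(1e-9) >= 0 or f(t_mid) <= 0:
        raise ValueError("threshold does not bracket the stance onset")
    t_on = brentq(f, 1e-9, t_mid, xtol=1e-10)
    t_off = brentq(f, t_mid, tc - 1e-9, xtol=1e-10)
    return float(t_on), float(t_off)


def simulate_stance_vgrf(
    params: StanceParams, mass: float, rate: float
) -> SampledSignal:
    """Sample one stance's vertical GRF in Newtons at ``rate`` over [0, T_c]."""
    params.validate()
    if mass <= 0 or rate <= 0:
        raise ValueError("mass and rate must be strictly positive")
    n = int(math.floor(params.contact_time * rate)) + 1
    t = np.arange(n) / rate
    values = mass * GRAVITY * stance_waveform(t, params)
    return SampledSignal(np.maximum(values, 0.0), rate, "N", "grf")


def derive_vertical_acceleration(vgrf: SampledSignal, mass: float) -> SampledSignal:
    """Vertical CoM acceleration implied by a vGRF via Newton's second law.

    a(t) = F(t)/(m*g) - 1 in gravity-subtracted g units: flight maps to
    -1 g, quiet standing at body weight to 0 g.
    """
    if mass <= 0:
        raise ValueError("mass must be strictly positive")
    if np.any(vgrf.values < 0):
        raise ValueError("vGRF must be nonnegative")
    return SampledSignal(
        vgrf.values / (mass * GRAVITY) - 1.0, vgrf.rate, "g", "accel_v"
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectTraits:
    """Latent per-subject offsets, persistent across that subject's trials."""

    info: SubjectInfo
    active_offset: float = 0.0    # BW, stiffness-like shift of peaks
    contact_offset: float = 0.0   # s
    period_offset: float = 0.0    # s


@dataclass(frozen=True)
class SimStep:
    """Ground truth for one simulated step."""

    ic_time: float
    to_time: float
    params: StanceParams

    @property
    def active_peak_bw(self) -> float:
        return self.params.active_peak

    @property
    def impulse_bw_s(self) -> float:
        return stance_impulse_closed_form(self.params)

    @property
    def contact_time_s(self) -> float:
        return self.params.contact_time


@dataclass(frozen=True)
class SimulatedTrial:
    record: TrialRecord
    steps: list[SimStep]


def draw_subject(index: int, rng: np.random.Generator) -> SubjectTraits:
    """Draw one subject's anthropometrics and latent gait offsets."""
    mass = float(np.clip(rng.normal(MASS_MEAN, MASS_SD), 50.0, 105.0))
    leg = float(np.clip(rng.normal(LEG_LENGTH_MEAN, LEG_LENGTH_SD), 0.75, 1.10))
    pref = float(np.clip(rng.normal(3.06, 0.30), 2.3, 3.8))
    return SubjectTraits(
        info=SubjectInfo(f"S{index:03d}", mass, leg, pref),
        active_offset=float(rng.normal(0.0, ACTIVE_SUBJECT_SD)),
        contact_offset=float(rng.normal(0.0, CONTACT_SUBJECT_SD)),
        period_offset=float(rng.normal(0.0, PERIOD_SUBJECT_SD)),
    )


def draw_stance_params(
    traits: SubjectTraits,
    speed: float,
    impact_probability: float,
    rng: np.random.Generator,
) -> StanceParams:
    """Draw one step's stance parameters for a subject at a given speed."""
    dv = speed - REF_SPEED
    a = ACTIVE_MEAN + ACTIVE_SPEED_SLOPE * dv + traits.active_offset
    a = float(np.clip(a + rng.normal(0.0, ACTIVE_STEP_SD), 1.7, 3.2))
    tc = CONTACT_MEAN + CONTACT_SPEED_SLOPE * dv + traits.contact_offset
    tc = float(np.clip(tc + rng.normal(0.0, CONTACT_STEP_SD), 0.175, 0.395))
    period = PERIOD_MEAN + PERIOD_SPEED_SLOPE * dv + traits.period_offset
    period = float(
        max(period + rng.normal(0.0, PERIOD_STEP_SD), tc + 0.05)
    )
    impact = None
    frac, width = 0.05, 0.006
    if rng.random() < impact_probability:
        frac = float(rng.uniform(0.045, 0.09))
        width = float(min(rng.uniform(0.004, 0.007), frac * tc / 3.0))
        carrier = a * math.sin(math.pi * frac)
        # amplitude large enough that the bump forms an unambiguous local
        # maximum over the rising half-sine (slope-dominance condition)
        i_min = 2.0 * width * a * math.pi * math.cos(math.pi * frac) / (0.607 * tc)
        i_draw = IMPACT_APEX_MEAN + rng.normal(0.0, IMPACT_APEX_SD) - carrier
        impact = float(np.clip(max(i_draw, i_min), 0.45, 0.72 * a - carrier))
    return StanceParams(
        active_peak=a,
        contact_time=tc,
        step_period=period,
        impact_peak=impact,
        impact_time_frac=frac,
        impact_width=width,
    )


def simulate_trial_from_params(
    subject: SubjectInfo,
    speed: float,
    steps: list[StanceParams],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedTrial:
    """Assemble a trial from an explicit per-step parameter list.

    Steps are laid end to end starting at t=0; each step occupies
    [ic, ic + step_period) with the stance in [ic, ic + contact_time].
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not steps:
        raise ValueError("at least one step is required")
    n_grf = int(math.floor(config.trial_duration * config.grf_rate)) + 1
    grf = np.zeros(n_grf)
    sim_steps: list[SimStep] = []
    t0 = 0.0
    for params in steps:
        params.validate()
        if t0 + params.step_period > config.trial_duration + 1e-12:
            break
        i0 = int(math.ceil(t0 * config.grf_rate - 1e-9))
        i1 = min(int(math.floor((t0 + params.contact_time) * config.grf_rate + 1e-9)), n_grf - 1)
        t_local = np.arange(i0, i1 + 1) / config.grf_rate - t0
        grf[i0 : i1 + 1] += massg(subject.mass) * stance_waveform(t_local, params)
        sim_steps.append(SimStep(t0, t0 + params.contact_time, params))
        t0 += params.step_period
    if not sim_steps:
        raise ValueError(
            "trial_duration too short for one step "
            f"({config.trial_duration} s < {steps[0].step_period} s)"
        )

    grf_clean = SampledSignal(np.maximum(grf, 0.0), config.grf_rate, "N", "grf")
    accel_true = derive_vertical_acceleration(grf_clean, subject.mass)
    if config.accel_rate != config.grf_rate:
        t_acc = np.arange(
            int(math.floor(accel_true.duration * config.accel_rate)) + 1
        ) / config.accel_rate
        acc_v = np.interp(t_acc, accel_true.times(), accel_true.values)
    else:
        acc_v = accel_true.values.copy()
    n_acc = len(acc_v)

    sd = config.noise_sd_accel
    acc_v_noisy = acc_v + (rng.normal(0.0, sd, n_acc) if sd > 0 else 0.0)
    acc_neck = acc_v + (rng.normal(0.0, sd, n_acc) if sd > 0 else 0.0)
    acc_l5 = acc_v + (rng.normal(0.0, sd, n_acc) if sd > 0 else 0.0)
    acc_ap = rng.normal(0.0, sd, n_acc) if sd > 0 else np.zeros(n_acc)
    acc_ml = rng.normal(0.0, 0.8 * sd, n_acc) if sd > 0 else np.zeros(n_acc)
    grf_noisy = grf_clean.values + (
        rng.normal(0.0, config.noise_sd_grf, n_grf) if config.noise_sd_grf > 0 else 0.0
    )
    offset = 0.0 if config.gravity_subtracted else 1.0

    def acc_sig(values: np.ndarray, label: str) -> SampledSignal:
        return SampledSignal(values, config.accel_rate, "g", label)

    record = TrialRecord(
        subject=subject,
        speed=speed,
        grf=SampledSignal(grf_noisy, config.grf_rate, "N", "grf"),
        accel_v=acc_sig(acc_v_noisy + offset, "accel_v"),
        accel_ap=acc_sig(acc_ap, "accel_ap"),
        accel_ml=acc_sig(acc_ml, "accel_ml"),
        accel_neck_v=acc_sig(acc_neck + offset, "accel_neck_v"),
        accel_l5_v=acc_sig(acc_l5 + offset, "accel_l5_v"),
    )
    return SimulatedTrial(record, sim_steps)


def massg(mass: float) -> float:
    """Body weight in Newtons."""
    return mass * GRAVITY


def simulate_trial(
    subject: SubjectInfo,
    speed: float,
    config: CohortConfig,
    rng: np.random.Generator,
    traits: SubjectTraits | None = None,
) -> SimulatedTrial:
    """Simulate one trial, drawing per-step stance parameters."""
    if traits is None:
        traits = SubjectTraits(info=subject)
    n_max = int(math.ceil(config.trial_duration / 0.2)) + 1
    steps: list[StanceParams] = []
    t_acc = 0.0
    for _ in range(n_max):
        p = draw_stance_params(traits, speed, config.impact_probability, rng)
        if t_acc + p.step_period > config.trial_duration + 1e-12:
            break
        steps.append(p)
        t_acc += p.step_period
    if not steps:
        raise ValueError("trial_duration too short for one step")
    return simulate_trial_from_params(subject, speed, steps, config, rng)


def simulate_cohort(config: CohortConfig) -> tuple[list[SimulatedTrial], pd.DataFrame]:
    """Simulate one trial per (subject, speed) pair.

    Randomness is split per subject from the single cohort seed, so a
    subject's data is unchanged when the cohort is enlarged.  Returns the
    trials and a ground-truth table with one row per simulated step.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_subjects)
    trials: list[SimulatedTrial] = []
    rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        traits = draw_subject(i, rng)
        for speed in config.speeds:
            trial = simulate_trial(traits.info, speed, config, rng, traits=traits)
            trials.append(trial)
            for k, step in enumerate(trial.steps):
                imp = true_impact_peak(step.params)
                rows.append(
                    {
                        "subject_id": traits.info.subject_id,
                        "speed": speed,
                        "step_index": k,
                        "ic_time_s": step.ic_time,
                        "to_time_s": step.to_time,
                        "active_peak_bw": step.active_peak_bw,
                        "impact_peak_bw": np.nan if imp is None else imp,
                        "impulse_bw_s": step.impulse_bw_s,
                        "contact_time_s": step.contact_time_s,
                        "step_period_s": step.params.step_period,
                    }
                )
    return trials, pd.DataFrame(rows)
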