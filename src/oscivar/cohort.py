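"""Synthetic home-monitoring oscillometry cohorts with known ground truth.

Generates daily 2-minute recordings of mouth pressure and airflow for three
clinical groups (asthma, healthy, COPD) whose mid-inspiratory resistance
statistics follow configurable group distributions.  Each subject has a
long-run baseline resistance and a true day-to-day coefficient of variation;
each day's resistance level is drawn from a lognormal around the baseline, and
each recording superimposes a 5 Hz sinusoidal pressure forcing on a tidal
breathing waveform through a single-compartment respiratory model
(resistance + elastance + inertance).

Within a breath, true resistance is modulated by two mechanisms that motivate
mid-inspiratory sampling in the first place: a transient elevation at the
onset of inspiration (airway re-opening after end-expiratory events, decaying
linearly over the first 20% of inspiration) and a sustained surcharge during
expiration (dynamic compression / expiratory flow limitation, largest in
COPD).  The central 20-80% of inspiration therefore carries the clean daily
resistance level, which is what the processing pipeline must recover.

Every stochastic choice flows from a single root seed through per-subject and
per-day spawned generators, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._signal import bandpass
from .recording import Recording

GROUPS = ("asthma", "healthy", "copd")

FORCING_FREQ_HZ = 5.0  # single-frequency forcing


class CohortError(ValueError):
    """Invalid cohort or subject specification."""


# ---------------------------------------------------------------------------
# specifications


@dataclass
class SubjectSpec:
    """Ground-truth physiological parameters of one simulated subject.

    Units: resistances cmH2O·s/L, elastance cmH2O/L, inertance cmH2O·s²/L,
    breath_period s, tidal_volume L; CVs and surcharges are dimensionless
    fractions.
    """

    subject_id: str
    group: str
    R_base: float  # long-run median mid-inspiratory resistance
    day_cv: float  # true day-to-day CV of mid-inspiratory resistance
    breath_cv: float = 0.08  # breath-to-breath multiplicative noise SD
    exp_surcharge: float = 0.0  # fractional R increase during expiration
    early_insp_surcharge: float = 0.0  # fractional elevation at insp onset
    elastance: float = 10.0
    inertance: float = 0.01
    breath_period: float = 4.0
    tidal_volume: float = 0.5
    adherence_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(f"unknown group '{self.group}'")
        if self.R_base <= 0:
            raise CohortError("R_base must be positive")
        if self.day_cv < 0 or self.breath_cv < 0:
            raise CohortError("CVs must be non-negative")
        if self.exp_surcharge < 0 or self.early_insp_surcharge < 0:
            raise CohortError("surcharges must be non-negative")
        if not 0.0 <= self.adherence_prob <= 1.0:
            raise CohortError("adherence_prob must lie in [0, 1]")
        if not 1.5 <= self.breath_period <= 15.0:
            raise CohortError("breath_period must lie in [1.5, 15] s")


@dataclass
class GroupParams:
    """Between-subject distributions for one clinical group.

    Normally distributed fields are given as (mean, sd) pairs and truncated
    from below at sampling time so that draws remain physiological.
    """

    r_base: tuple[float, float]  # cmH2O·s/L
    day_cv: tuple[float, float]  # dimensionless
    breath_cv: float = 0.08
    exp_surcharge: float = 0.0
    early_insp_surcharge: float = 0.0
    elastance: float = 10.0
    inertance: float = 0.01
    breath_period: tuple[float, float] = (4.0, 0.4)
    tidal_volume: tuple[float, float] = (0.5, 0.06)
    adherence_prob: float = 0.9

    R_BASE_FLOOR: float = 0.5
    DAY_CV_FLOOR: float = 0.005
    BREATH_PERIOD_BOUNDS: tuple[float, float] = (2.0, 8.0)
    TIDAL_VOLUME_FLOOR: float = 0.25


#: Defaults calibrated to the validation-phase group statistics: group mean
#: (SD) of mid-inspiratory meanR 3.72 (1.03) / 2.59 (0.50) / 5.08 (1.09) and
#: day-to-day CVR 0.14 (0.05) / 0.07 (0.02) / 0.09 (0.04) for
#: asthma / healthy / COPD.  Intra-breath surcharges are largest in COPD
#: (expiratory flow limitation) and smallest in healthy subjects.
DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "asthma": GroupParams(
        r_base=(3.72, 1.03),
        day_cv=(0.14, 0.05),
        early_insp_surcharge=0.15,
        exp_surcharge=0.25,
    ),
    "healthy": GroupParams(
        r_base=(2.59, 0.50),
        day_cv=(0.07, 0.02),
        early_insp_surcharge=0.05,
        exp_surcharge=0.10,
    ),
    "copd": GroupParams(
        r_base=(5.08, 1.09),
        day_cv=(0.09, 0.04),
        early_insp_surcharge=0.25,
        exp_surcharge=0.60,
        elastance=12.0,
    ),
}

#: Validation-phase group sizes after exclusions (asthma / healthy / COPD).
VALIDATION_GROUP_SIZES = {"asthma": 45, "healthy": 33, "copd": 20}
#: Development-phase group sizes and observation length.
DEVELOPMENT_GROUP_SIZES = {"asthma": 10, "healthy": 10, "copd": 10}


@dataclass
class CohortSpec:
    """Design of a simulated cohort: group sizes, schedule and acquisition."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(VALIDATION_GROUP_SIZES)
    )
    group_params: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    n_days: int = 14
    forcing_freq: float = FORCING_FREQ_HZ
    forcing_amplitude: float = 1.5  # cmH2O peak
    sampling_rate: float = 200.0  # Hz
    duration: float = 120.0  # s, 2-minute recordings
    noise_sd_pressure: float = 0.01  # cmH2O white measurement noise
    noise_sd_flow: float = 0.002  # L/s
    artifact_rate: float = 0.0  # per-breath corruption probability
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise CohortError(f"unknown group '{g}'")
            if n < 1:
                raise CohortError(f"group '{g}' must have >= 1 subject")
        if not self.group_sizes:
            raise CohortError("cohort must contain at least one group")
        if self.n_days < 1:
            raise CohortError("n_days must be >= 1")
        if self.sampling_rate < 8 * self.forcing_freq:
            raise CohortError("sampling_rate must be >= 8x forcing frequency")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise CohortError("artifact_rate must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Generator-side truth for one recording (never read by the pipeline).

    breath_bounds are (start, insp_end, end) times in seconds for each
    simulated breath; true_mid_insp is the time-average of true resistance
    over the central 20-80% of each inspiration.
    """

    daily_R: float
    r_t: np.ndarray  # true resistance at every sample
    breath_bounds: list[tuple[float, float, float]]
    true_mid_insp: np.ndarray  # per breath
    corrupted_breaths: list[int] = field(default_factory=list)
    corrupted_kinds: dict[int, str] = field(default_factory=dict)

    @property
    def true_mid_insp_mean(self) -> float:
        return float(np.mean(self.true_mid_insp))


# ---------------------------------------------------------------------------
# sampling


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, upper: float = np.inf
) -> float:
    """One draw from a normal truncated to [lower, upper]."""
    if lower >= upper:
        raise CohortError(f"degenerate truncation bounds [{lower}, {upper}]")
    if sd < 0:
        raise CohortError("sd must be non-negative")
    if sd == 0:
        if not lower <= mean <= upper:
            raise CohortError(
                f"degenerate distribution: mean {mean} outside [{lower}, {upper}]"
            )
        return mean
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_subject(
    group: str,
    rng: np.random.Generator,
    subject_id: str | None = None,
    params: GroupParams | None = None,
) -> SubjectSpec:
    """Draw one subject's physiological parameters from the group distributions.

    Baseline resistance and day-to-day CV are truncated-normal draws (floors
    0.5 cmH2O·s/L and 0.005 respectively); breath period and tidal volume are
    likewise truncated to physiological ranges.
    """
    if params is None:
        params = DEFAULT_GROUP_PARAMS[group]
    if subject_id is None:
        subject_id = f"{group}_{rng.integers(10**8):08d}"
    lo_t, hi_t = params.BREATH_PERIOD_BOUNDS
    return SubjectSpec(
        subject_id=subject_id,
        group=group,
        R_base=_trunc_normal(rng, *params.r_base, params.R_BASE_FLOOR),
        day_cv=_trunc_normal(rng, *params.day_cv, params.DAY_CV_FLOOR),
        breath_cv=params.breath_cv,
        exp_surcharge=params.exp_surcharge,
        early_insp_surcharge=params.early_insp_surcharge,
        elastance=params.elastance,
        inertance=params.inertance,
        breath_period=_trunc_normal(rng, *params.breath_period, lo_t, hi_t),
        tidal_volume=_trunc_normal(
            rng, *params.tidal_volume, params.TIDAL_VOLUME_FLOOR
        ),
        adherence_prob=params.adherence_prob,
    )


def simulate_day_resistance(
    spec: SubjectSpec, rng: np.random.Generator, n_days: int = 1
) -> np.ndarray:
    """Draw daily mid-inspiratory resistance levels for one subject.

    Days are independent lognormal draws with median ``R_base`` and log-SD
    sigma = sqrt(ln(1 + day_cv^2)), which makes the coefficient of variation
    of the daily level exactly ``day_cv``.
    """
    sigma = math.sqrt(math.log1p(spec.day_cv**2))
    return spec.R_base * np.exp(sigma * rng.standard_normal(n_days))


# ---------------------------------------------------------------------------
# raw-signal synthesis


def _true_resistance_profile(
    spec: SubjectSpec,
    daily_R: float,
    t: np.ndarray,
    breath_factors: np.ndarray,
) -> np.ndarray:
    """True R(t): daily level x per-breath noise x intra-breath modulation.

    The early-inspiratory surcharge decays linearly to zero over the first
    20% of inspiration; the expiratory surcharge is a constant factor over
    the whole expiration.  The central 20-80% of inspiration is unmodulated.
    """
    T = spec.breath_period
    phase = (t % T) / T  # breath phase in [0, 1); inspiration first half
    breath_idx = np.minimum((t // T).astype(int), len(breath_factors) - 1)
    r = daily_R * breath_factors[breath_idx]
    insp = phase < 0.5
    fi = phase / 0.5  # fraction of inspiration elapsed
    early = np.where(insp, np.maximum(0.0, 1.0 - fi / 0.2), 0.0)
    r = r * (1.0 + spec.early_insp_surcharge * early)
    r = np.where(insp, r, r * (1.0 + spec.exp_surcharge))
    return r


def synthesize_recording(
    spec: SubjectSpec,
    daily_R: float,
    rng: np.random.Generator,
    *,
    day_index: int = 1,
    forcing_freq: float = FORCING_FREQ_HZ,
    forcing_amplitude: float = 1.5,
    duration: float = 120.0,
    sampling_rate: float = 200.0,
    noise_sd_pressure: float = 0.01,
    noise_sd_flow: float = 0.002,
) -> tuple[Recording, GroundTruth]:
    """Synthesize one 2-minute recording for a subject-day.

    The measured pressure is the forcing sinusoid plus the low-frequency
    breathing pressure (elastance x volume + R x breathing flow) plus white
    noise; the measured flow is the tidal breathing flow plus the oscillatory
    flow A/|Z| · sin(2·pi·f0·t - theta) driven through the instantaneous
    impedance Z(t) = R(t) + i(2·pi·f0·I - E/(2·pi·f0)).
    """
    if sampling_rate < 8 * forcing_freq:
        raise CohortError("sampling rate must be >= 8x forcing frequency")
    if duration < 10 * spec.breath_period:
        raise CohortError("recording must span at least 10 breath periods")

    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    T = spec.breath_period
    n_breaths = int(math.ceil(duration / T))

    # per-breath multiplicative noise, floored away from zero
    factors = np.maximum(1.0 + spec.breath_cv * rng.standard_normal(n_breaths), 0.2)
    r_t = _true_resistance_profile(spec, daily_R, t, factors)

    # tidal breathing: sinusoidal flow, inspiration (positive) first half-cycle
    w_b = 2 * np.pi / T
    q_breath = (np.pi * spec.tidal_volume / T) * np.sin(w_b * t)
    volume = 0.5 * spec.tidal_volume * (1.0 - np.cos(w_b * t))

    # oscillatory components through the single-compartment impedance
    w0 = 2 * np.pi * forcing_freq
    X0 = w0 * spec.inertance - spec.elastance / w0
    z_mag = np.hypot(r_t, X0)
    if np.any(z_mag < 1e-9):
        raise CohortError("impedance magnitude below numeric floor")
    theta = np.arctan2(X0, r_t)
    q_osc = (forcing_amplitude / z_mag) * np.sin(w0 * t - theta)

    pressure = (
        forcing_amplitude * np.sin(w0 * t)
        + spec.elastance * volume
        + r_t * q_breath
    )
    flow = q_breath + q_osc
    if noise_sd_pressure > 0:
        pressure = pressure + noise_sd_pressure * rng.standard_normal(n)
    if noise_sd_flow > 0:
        flow = flow + noise_sd_flow * rng.standard_normal(n)

    rec = Recording(
        subject_id=spec.subject_id,
        day_index=day_index,
        time=t,
        pressure=pressure,
        flow=flow,
        sampling_rate=sampling_rate,
    )

    bounds: list[tuple[float, float, float]] = []
    true_mid: list[float] = []
    for k in range(n_breaths):
        t0, t1 = k * T, min((k + 1) * T, duration)
        if t1 - t0 < T - 1e-9:  # trailing incomplete breath
            break
        t_ie = t0 + 0.5 * T
        bounds.append((t0, t_ie, t1))
        lo, hi = t0 + 0.2 * 0.5 * T, t0 + 0.8 * 0.5 * T
        sel = (t >= lo) & (t < hi)
        true_mid.append(float(np.mean(r_t[sel])))
    gt = GroundTruth(
        daily_R=daily_R,
        r_t=r_t,
        breath_bounds=bounds,
        true_mid_insp=np.asarray(true_mid),
    )
    return rec, gt


# ---------------------------------------------------------------------------
# artifacts

_ARTIFACT_KINDS = ("spike", "leak", "clip")


def inject_artifacts(
    rec: Recording,
    gt: GroundTruth,
    artifact_rate: float,
    rng: np.random.Generator,
    forcing_freq: float = FORCING_FREQ_HZ,
) -> tuple[Recording, GroundTruth]:
    """Corrupt randomly selected breaths; record their indices in the truth.

    Three artifact families emulate home-measurement failures: a transient
    flow spike (cough/swallow), an oscillatory-pressure dropout (mouthpiece
    leak), and flow clipping.  Returns a new Recording; the input is left
    untouched.
    """
    if not 0.0 <= artifact_rate <= 1.0:
        raise CohortError("artifact_rate must lie in [0, 1]")
    if artifact_rate == 0.0 or not gt.breath_bounds:
        return rec, gt

    flow = rec.flow.copy()
    pressure = rec.pressure.copy()
    fs = rec.sampling_rate
    n_b = len(gt.breath_bounds)
    # all randomness drawn up front: on a fixed seed, raising the rate only
    # grows the corrupted set (rejection counts are then monotone in the rate)
    hit = rng.random(n_b) < artifact_rate
    kinds = rng.integers(len(_ARTIFACT_KINDS), size=n_b)
    spike_pos = rng.random(n_b)
    spike_sign = np.where(rng.random(n_b) < 0.5, -1.0, 1.0)
    corrupted: list[int] = []
    kind_map: dict[int, str] = {}
    p_osc = None  # lazily band-passed forcing component, for leak injection
    for k, (t0, _, t1) in enumerate(gt.breath_bounds):
        if not hit[k]:
            continue
        corrupted.append(k)
        i0, i1 = int(t0 * fs), min(int(t1 * fs), rec.n_samples)
        kind = _ARTIFACT_KINDS[kinds[k]]
        kind_map[k] = kind
        if kind == "spike":
            tc = t0 + 0.1 + spike_pos[k] * (t1 - t0 - 0.2)
            width = 0.05  # s
            pulse = 5.0 * np.exp(-0.5 * ((rec.time - tc) / width) ** 2)
            flow += spike_sign[k] * pulse
        elif kind == "leak":
            if p_osc is None:
                p_osc = bandpass(
                    rec.pressure, fs, (forcing_freq / 2.5, forcing_freq * 1.6)
                )
            pressure[i0:i1] -= 0.85 * p_osc[i0:i1]
        else:  # clip: flow saturates hard, crushing the oscillatory component
            ceiling = 0.15 * np.max(np.abs(flow[i0:i1]))
            flow[i0:i1] = np.clip(flow[i0:i1], -ceiling, ceiling)

    new_rec = replace(rec, time=rec.time.copy(), pressure=pressure, flow=flow)
    new_gt = replace(
        gt,
        corrupted_breaths=sorted(set(gt.corrupted_breaths) | set(corrupted)),
        corrupted_kinds={**gt.corrupted_kinds, **kind_map},
    )
    return new_rec, new_gt


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class CohortData:
    """In-memory bundle produced by :func:`generate_cohort`."""

    spec: CohortSpec
    subjects: list[SubjectSpec]
    recordings: dict[tuple[str, int], Recording]
    ground_truth: dict[tuple[str, int], GroundTruth]
    daily_R: dict[str, np.ndarray]  # scheduled daily levels per subject
    presence: dict[str, list[int]]  # 1-based day indices with a recording

    def manifest(self, include_truth: bool = False) -> dict:
        """JSON-serializable manifest: spec echo, subject table, day presence."""
        spec = self.spec
        man = {
            "n_days": spec.n_days,
            "forcing_freq": spec.forcing_freq,
            "forcing_amplitude": spec.forcing_amplitude,
            "sampling_rate": spec.sampling_rate,
            "duration": spec.duration,
            "artifact_rate": spec.artifact_rate,
            "rng_seed": spec.rng_seed,
            "group_sizes": dict(sorted(spec.group_sizes.items())),
            "subjects": [
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "days_present": list(self.presence[s.subject_id]),
                }
                for s in self.subjects
            ],
        }
        if include_truth:
            for row, s in zip(man["subjects"], self.subjects):
                row["true_R_base"] = s.R_base
                row["true_day_cv"] = s.day_cv
        return man


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate a full cohort: subjects, schedules, recordings, ground truth.

    For each subject and scheduled day a recording is produced with
    probability ``adherence_prob``; the daily resistance level is drawn for
    every scheduled day (so the truth is defined even on missing days).
    Fully reproducible from ``spec.rng_seed``.
    """
    root = np.random.SeedSequence(spec.rng_seed)
    groups = sorted(spec.group_sizes)
    n_total = sum(spec.group_sizes.values())
    seeds = root.spawn(n_total)

    subjects: list[SubjectSpec] = []
    recordings: dict[tuple[str, int], Recording] = {}
    ground_truth: dict[tuple[str, int], GroundTruth] = {}
    daily_levels: dict[str, np.ndarray] = {}
    presence: dict[str, list[int]] = {}

    si = 0
    for group in groups:
        params = spec.group_params[group]
        for j in range(spec.group_sizes[group]):
            sub_rng = np.random.default_rng(seeds[si])
            si += 1
            sid = f"{group[0].upper()}{j + 1:03d}"
            sub = sample_subject(group, sub_rng, subject_id=sid, params=params)
            subjects.append(sub)
            levels = simulate_day_resistance(sub, sub_rng, n_days=spec.n_days)
            daily_levels[sid] = levels
            attend = sub_rng.random(spec.n_days) < sub.adherence_prob
            present: list[int] = []
            for d in range(spec.n_days):
                if not attend[d]:
                    continue
                day_rng = np.random.default_rng(
                    np.random.SeedSequence([spec.rng_seed, si, d])
                )
                rec, gt = synthesize_recording(
                    sub,
                    levels[d],
                    day_rng,
                    day_index=d + 1,
                    forcing_freq=spec.forcing_freq,
                    forcing_amplitude=spec.forcing_amplitude,
                    duration=spec.duration,
                    sampling_rate=spec.sampling_rate,
                    noise_sd_pressure=spec.noise_sd_pressure,
                    noise_sd_flow=spec.noise_sd_flow,
                )
                if spec.artifact_rate > 0:
                    rec, gt = inject_artifacts(
                        rec, gt, spec.artifact_rate, day_rng, spec.forcing_freq
                    )
                recordings[(sid, d + 1)] = rec
                ground_truth[(sid, d + 1)] = gt
                present.append(d + 1)
            presence[sid] = present
    return CohortData(
        spec=spec,
        subjects=subjects,
        recordings=recordings,
        ground_truth=ground_truth,
        daily_R=daily_levels,
        presence=presence,
    )
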