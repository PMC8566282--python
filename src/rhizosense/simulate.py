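"""Synthetic field simulator with ground truth.

Generates raw per-electrode charge-voltage streams for a whole trial, built
from the phenomenology seen on real in-soil impedance sensors:

* soil near an electrode dries exponentially between wetting events, and
  drying moves the electrode along a characteristic trajectory in
  (log R, log C) space — resistance up, capacitance down; wetting reverses
  it along the same trajectory;
* a diurnal oscillation (temperature/moisture cycling) modulates the
  signal, attenuated with depth;
* a root touching or growing close to an electrode produces a localized,
  persistent deflection whose resistance:capacitance change ratio is
  *smaller* than the wetting-trajectory slope (roots are less conductive
  than freshly watered soil), which is the detectable signature;
* irrigation or rain causes rapid coherent change on most electrodes at
  once (the detector masks these windows);
* devices suffer occasional downtime during which no data exist.

Root arrivals are an inhomogeneous Poisson process per device (detections
are counted per day and analysed as daily rates), with a configurable depth
profile and per-window rate multipliers to program treatment effects.
Every injected contact is recorded in a truth log so detector output can be
scored; watering windows and downtime are recorded as mask truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circuit import ElectricalConstants, simulate_charge_voltages
from .device import DeviceGeometry

__all__ = [
    "SoilParams",
    "IrrigationEvent",
    "IrrigationSchedule",
    "RootContactModel",
    "DowntimeModel",
    "TreatmentSpec",
    "TrialConfig",
    "DeviceSim",
    "moisture_to_rc",
    "wetting_slope",
    "simulate_moisture",
    "inject_root_events",
    "sample_root_events",
    "simulate_device",
    "iter_device_sims",
    "simulate_trial",
    "shallow_depth_profile",
    "deep_depth_profile",
]

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class SoilParams:
    """Electrical response of the soil around an electrode.

    Resistance/capacitance endpoints anchor a log-linear moisture map:
    normalized moisture 1 gives the wet endpoints, 0 the dry endpoints.
    Drying raises resistance and lowers capacitance.

    ``noise_sd`` is the multiplicative measurement noise (standard
    deviation of log R and log C per 5-minute sample).
    """

    moisture_wet: float = 0.9  # equilibrium during/after wetting
    moisture_dry: float = 0.1  # equilibrium of prolonged drying
    drying_time_constant: float = 4.0  # days
    wetting_time_constant_hours: float = 1.0
    res_at_wet: float = 5e3  # ohms
    res_at_dry: float = 5e4  # ohms
    cap_at_wet: float = 2e-9  # farads
    cap_at_dry: float = 5e-10  # farads
    diurnal_amplitude: float = 0.02  # moisture fraction, surface value
    diurnal_depth_scale_cm: float = 12.0  # e-folding depth of the diurnal term
    noise_sd: float = 0.01  # multiplicative, on R and C

    def __post_init__(self) -> None:
        if not self.res_at_dry > self.res_at_wet:
            raise ValueError("drying must raise resistance: res_at_dry > res_at_wet")
        if not self.cap_at_dry < self.cap_at_wet:
            raise ValueError("drying must lower capacitance: cap_at_dry < cap_at_wet")
        if self.drying_time_constant <= 0 or self.wetting_time_constant_hours <= 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class IrrigationEvent:
    """One watering event: start (minutes from trial start), duration, reach."""

    start_minutes: float
    duration_hours: float
    depth_reach_cm: float = 30.0


@dataclass(frozen=True)
class IrrigationSchedule:
    """Time-ordered sequence of irrigation/rain events."""

    events: tuple[IrrigationEvent, ...] = ()

    def __post_init__(self) -> None:
        starts = [e.start_minutes for e in self.events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("irrigation events must be time-ordered")
        if any(e.duration_hours < 0 for e in self.events):
            raise ValueError("irrigation durations must be non-negative")

    @classmethod
    def weekly(
        cls,
        n_days: int,
        events_per_week: int = 2,
        duration_hours: float = 3.0,
        start_hour: float = 8.0,
        depth_reach_cm: float = 30.0,
        until_day: int | None = None,
    ) -> "IrrigationSchedule":
        """Evenly spaced irrigation, optionally stopping at ``until_day``."""
        period_days = 7.0 / events_per_week
        events = []
        day = 1.0
        while day < n_days:
            if until_day is not None and day >= until_day:
                break
            events.append(
                IrrigationEvent(
                    start_minutes=day * MINUTES_PER_DAY + start_hour * 60.0,
                    duration_hours=duration_hours,
                    depth_reach_cm=depth_reach_cm,
                )
            )
            day += period_days
        return cls(tuple(events))


@dataclass(frozen=True)
class RootContactModel:
    """Localized signal deflection of a root contact.

    The contact adds ``(delta_logres, delta_logcap)`` to one electrode's
    (log R, log C) as a ramp over ``onset_minutes``; a touched root stays
    near the electrode, so the deflection persists by default.  The
    defaults give a resistance:capacitance change ratio of 1:3, well inside
    the root sector (smaller than the wetting slope).
    """

    delta_logres: float = -0.10
    delta_logcap: float = 0.30
    onset_minutes: float = 60.0
    persist: bool = True
    recovery_minutes: float = 360.0  # only used when persist=False

    def magnitude(self) -> float:
        return float(np.hypot(self.delta_logres, self.delta_logcap))


@dataclass(frozen=True)
class DowntimeModel:
    """Device outages: daily Bernoulli start, exponential outage length."""

    prob_per_day: float = 0.0
    mean_hours: float = 4.0
    max_hours: float = 24.0


def shallow_depth_profile(
    geometry: DeviceGeometry, center_index: float = 4.0, sd_index: float = 4.0
) -> np.ndarray:
    """Truncated-Gaussian depth weights centred shallow (crown-root zone)."""
    i = np.arange(geometry.electrodes_per_paddle, dtype=float)
    w = np.exp(-0.5 * ((i - center_index) / sd_index) ** 2)
    return w / w.sum()


def deep_depth_profile(
    geometry: DeviceGeometry, center_index: float = 17.0, sd_index: float = 3.0
) -> np.ndarray:
    """Depth weights concentrated in the deeper half (primed deep growth)."""
    i = np.arange(geometry.electrodes_per_paddle, dtype=float)
    w = np.exp(-0.5 * ((i - center_index) / sd_index) ** 2)
    return w / w.sum()


@dataclass(frozen=True)
class TreatmentSpec:
    """Per-treatment experimental programme.

    ``rate_multipliers`` are ``(start_day, end_day, factor)`` windows
    (end-exclusive) scaling the base root-arrival rate — e.g. a factor of
    0.64 during a drought window programs 36% fewer new roots per day.
    ``depth_profile_windows`` optionally replace the arrival depth profile
    inside a day window (programmed deep-growth phenotypes).
    """

    schedule: IrrigationSchedule = field(default_factory=IrrigationSchedule)
    root_arrival_rate: float = 2.0  # roots/day/device
    rate_multipliers: tuple[tuple[float, float, float], ...] = ()
    depth_profile: np.ndarray | None = None  # defaults to shallow profile
    depth_profile_windows: tuple[tuple[float, float, np.ndarray], ...] = ()


@dataclass(frozen=True)
class TrialConfig:
    """Complete description of one simulated trial."""

    n_days: int = 30
    seed: int = 0
    geometry: DeviceGeometry = field(default_factory=DeviceGeometry)
    soil: SoilParams = field(default_factory=SoilParams)
    contact: RootContactModel = field(default_factory=RootContactModel)
    constants: ElectricalConstants = field(default_factory=ElectricalConstants)
    treatments: dict[str, TreatmentSpec] = field(
        default_factory=lambda: {"well_watered": TreatmentSpec()}
    )
    n_devices: dict[str, int] = field(default_factory=lambda: {"well_watered": 2})
    genotypes: tuple[str, ...] = ("HYB001",)
    downtime: DowntimeModel = field(default_factory=DowntimeModel)
    field_map: pd.DataFrame | None = None
    start: str = "2021-05-01"

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for name, spec in self.treatments.items():
            if spec.root_arrival_rate < 0:
                raise ValueError(f"negative arrival rate for treatment {name!r}")

    @property
    def n_times(self) -> int:
        return self.n_days * self.geometry.samples_per_day

    def times_minutes(self) -> np.ndarray:
        return np.arange(self.n_times) * self.geometry.cadence_minutes

    def timestamps(self) -> pd.DatetimeIndex:
        t0 = pd.Timestamp(self.start)
        return t0 + pd.to_timedelta(self.times_minutes(), unit="m")

    def device_table(self) -> pd.DataFrame:
        """One row per device: device_id, treatment, genotype."""
        if self.field_map is not None:
            df = self.field_map
            cols = ["device_id", "treatment", "genotype"]
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise KeyError(f"field map missing columns: {missing}")
            return df[cols].reset_index(drop=True)
        rows = []
        for name in self.treatments:
            n = self.n_devices.get(name, 0)
            for i in range(n):
                rows.append(
                    {
                        "device_id": f"{name[:2].upper()}{i:04d}",
                        "treatment": name,
                        "genotype": self.genotypes[i % len(self.genotypes)],
                    }
                )
        return pd.DataFrame(rows, columns=["device_id", "treatment", "genotype"])


# ---------------------------------------------------------------------------
# Soil moisture and the R-C trajectory


def moisture_to_rc(
    moisture: float | np.ndarray, soil: SoilParams
) -> tuple[np.ndarray, np.ndarray]:
    """Map normalized moisture to (resistance, capacitance).

    Log-linear interpolation between the dry (moisture 0) and wet
    (moisture 1) endpoints, so any moisture change moves the electrode
    along a straight line in (log R, log C) space — the characteristic
    wetting/drying trajectory.  Out-of-range moisture is clipped with a
    warning.
    """
    m = np.asarray(moisture, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        warnings.warn("moisture outside [0, 1] clipped", stacklevel=2)
        m = np.clip(m, 0.0, 1.0)
    log_res = np.log(soil.res_at_dry) + m * (
        np.log(soil.res_at_wet) - np.log(soil.res_at_dry)
    )
    log_cap = np.log(soil.cap_at_dry) + m * (
        np.log(soil.cap_at_wet) - np.log(soil.cap_at_dry)
    )
    return np.exp(log_res), np.exp(log_cap)


def wetting_slope(soil: SoilParams) -> float:
    """|d log R / d log C| along the wetting/drying trajectory."""
    dlr = np.log(soil.res_at_wet) - np.log(soil.res_at_dry)
    dlc = np.log(soil.cap_at_wet) - np.log(soil.cap_at_dry)
    return abs(dlr / dlc)


def _check_contact_vs_soil(contact: RootContactModel, soil: SoilParams) -> None:
    slope = wetting_slope(soil)
    if contact.delta_logcap == 0 or not (
        abs(contact.delta_logres / contact.delta_logcap) < slope
    ):
        raise ValueError(
            "root-contact deflection must have |dlogR/dlogC| smaller than "
            f"the wetting slope ({slope:.3g}); got "
            f"{contact.delta_logres}/{contact.delta_logcap}"
        )


def simulate_moisture(
    schedule: IrrigationSchedule,
    soil: SoilParams,
    n_days: int,
    cadence_minutes: float = 5.0,
    depth_cm: float = 1.9,
    seed: int | None = None,
    start_moisture: float | None = None,
) -> np.ndarray:
    """Normalized soil moisture series at one depth.

    Piecewise-exponential: during an irrigation event whose water reaches
    ``depth_cm`` the moisture relaxes toward ``moisture_wet`` with the fast
    wetting time constant; between events it relaxes toward
    ``moisture_dry`` with the slow drying time constant.  A diurnal
    sinusoid, attenuated exponentially with depth, is superimposed.

    The series is deterministic given its arguments; ``seed`` is accepted
    for interface symmetry with the stochastic generators and is unused.
    """
    n_times = int(round(n_days * MINUTES_PER_DAY / cadence_minutes))
    t = np.arange(n_times) * cadence_minutes
    m = np.empty(n_times)

    reached = [e for e in schedule.events if e.depth_reach_cm >= depth_cm]
    bounds: list[tuple[float, float]] = [
        (e.start_minutes, e.start_minutes + e.duration_hours * 60.0) for e in reached
    ]
    # segment boundaries: event starts/ends clipped to the trial span
    cuts = sorted(
        {0.0, n_times * cadence_minutes}
        | {b for se in bounds for b in se if 0.0 < b < n_times * cadence_minutes}
    )
    tau_dry = soil.drying_time_constant * MINUTES_PER_DAY
    tau_wet = soil.wetting_time_constant_hours * 60.0
    m0 = soil.moisture_wet if start_moisture is None else float(start_moisture)
    for a, b in zip(cuts, cuts[1:]):
        wet = any(s <= a < e for s, e in bounds)
        target, tau = (
            (soil.moisture_wet, tau_wet) if wet else (soil.moisture_dry, tau_dry)
        )
        sel = (t >= a) & (t < b)
        m[sel] = target + (m0 - target) * np.exp(-(t[sel] - a) / tau)
        m0 = target + (m0 - target) * np.exp(-(b - a) / tau)

    hours = t / 60.0
    amp = soil.diurnal_amplitude * np.exp(-depth_cm / soil.diurnal_depth_scale_cm)
    m = m - amp * np.sin(2.0 * np.pi * (hours - 14.0) / 24.0)
    return np.clip(m, 0.0, 1.0)


def _moisture_by_depth(
    schedule: IrrigationSchedule,
    soil: SoilParams,
    geometry: DeviceGeometry,
    n_days: int,
) -> np.ndarray:
    """(electrodes_per_paddle, n_times) moisture matrix, shallow first."""
    from .device import electrode_depths

    rows = [
        simulate_moisture(
            schedule, soil, n_days, geometry.cadence_minutes, depth_cm=d
        )
        for d in electrode_depths(geometry)
    ]
    return np.stack(rows)


# ---------------------------------------------------------------------------
# Root events


def sample_root_events(
    spec: TreatmentSpec,
    geometry: DeviceGeometry,
    n_days: int,
    rng: np.random.Generator,
    min_separation_days: float = 2.0,
) -> pd.DataFrame:
    """Draw root-arrival events for one device (inhomogeneous Poisson).

    Daily rates are the base rate scaled by any multiplier window covering
    that day; arrival times are uniform within their day.  Depth indices
    are drawn from the treatment's depth profile (or its windowed
    override); paddles uniformly.  Two arrivals on the same electrode
    closer than ``min_separation_days`` are thinned to one, since a second
    touch inside the detector's refractory window is indistinguishable.

    Returns a truth-log frame with columns ``time_index_minutes``,
    ``paddle_index``, ``depth_index``, ``day``.
    """
    days = np.arange(n_days, dtype=float)
    rate = np.full(n_days, spec.root_arrival_rate)
    for a, b, f in spec.rate_multipliers:
        rate[(days >= a) & (days < b)] *= f
    total = rate.sum()
    n = rng.poisson(total) if total > 0 else 0
    if n == 0:
        return pd.DataFrame(
            columns=["time_minutes", "paddle_index", "depth_index", "day"]
        )
    day_of = rng.choice(n_days, size=n, p=rate / total) if total > 0 else None
    t_min = (day_of + rng.random(n)) * MINUTES_PER_DAY
    # a contact whose onset ramp cannot complete before the trial ends is
    # unobservable by any detector; arrivals are clamped so the full
    # deflection develops inside the record
    t_min = np.minimum(t_min, n_days * MINUTES_PER_DAY - 90.0)
    order = np.argsort(t_min)
    t_min, day_of = t_min[order], day_of[order]

    base_profile = (
        spec.depth_profile
        if spec.depth_profile is not None
        else shallow_depth_profile(geometry)
    )
    depth_idx = np.empty(n, dtype=int)
    for i, d in enumerate(day_of):
        profile = base_profile
        for a, b, p in spec.depth_profile_windows:
            if a <= d < b:
                profile = p
                break
        depth_idx[i] = rng.choice(geometry.electrodes_per_paddle, p=profile)
    paddle_idx = rng.integers(0, geometry.n_paddles, size=n)

    keep = np.ones(n, dtype=bool)
    last_touch: dict[tuple[int, int], float] = {}
    for i in range(n):
        key = (int(paddle_idx[i]), int(depth_idx[i]))
        prev = last_touch.get(key)
        if prev is not None and t_min[i] - prev < min_separation_days * MINUTES_PER_DAY:
            keep[i] = False
        else:
            last_touch[key] = t_min[i]
    return pd.DataFrame(
        {
            "time_minutes": t_min[keep],
            "paddle_index": paddle_idx[keep],
            "depth_index": depth_idx[keep],
            "day": day_of[keep].astype(int),
        }
    )


def inject_root_events(
    log_res: np.ndarray,
    log_cap: np.ndarray,
    events: pd.DataFrame,
    model: RootContactModel,
    geometry: DeviceGeometry,
    copy: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Add root-contact deflections to a device's (log R, log C) arrays.

    ``log_res``/``log_cap`` are ``(n_electrodes, n_times)`` with electrodes
    flattened as ``paddle_index * electrodes_per_paddle + depth_index``.
    Each event adds a ramped step of ``(delta_logres, delta_logcap)`` over
    ``onset_minutes`` to exactly one electrode; all other electrodes are
    untouched.  Events outside the trial span are rejected with a warning.
    """
    if copy:
        log_res = log_res.copy()
        log_cap = log_cap.copy()
    n_el, n_t = log_res.shape
    cad = geometry.cadence_minutes
    n_onset = max(1, int(round(model.onset_minutes / cad)))
    for row in events.itertuples(index=False):
        t_idx = int(row.time_minutes // cad)
        if not 0 <= t_idx < n_t:
            warnings.warn(
                f"root event at t={row.time_minutes} min outside trial span",
                stacklevel=2,
            )
            continue
        el = int(row.paddle_index) * geometry.electrodes_per_paddle + int(
            row.depth_index
        )
        ramp_end = min(t_idx + n_onset, n_t)
        frac = np.arange(1, ramp_end - t_idx + 1) / n_onset
        log_res[el, t_idx:ramp_end] += model.delta_logres * frac
        log_cap[el, t_idx:ramp_end] += model.delta_logcap * frac
        if model.persist:
            log_res[el, ramp_end:] += model.delta_logres
            log_cap[el, ramp_end:] += model.delta_logcap
        else:
            n_rec = max(1, int(round(model.recovery_minutes / cad)))
            rec_end = min(ramp_end + n_rec, n_t)
            down = 1.0 - np.arange(1, rec_end - ramp_end + 1) / n_rec
            log_res[el, ramp_end:rec_end] += model.delta_logres * down
            log_cap[el, ramp_end:rec_end] += model.delta_logcap * down
    return log_res, log_cap


# ---------------------------------------------------------------------------
# Device and trial simulation


@dataclass
class DeviceSim:
    """Simulated raw data and ground truth for one device."""

    device_id: str
    treatment: str
    genotype: str
    V1: np.ndarray  # (n_electrodes, n_times); nan during downtime
    V2: np.ndarray
    truth: pd.DataFrame  # injected root contacts
    downtime: np.ndarray  # (n_times,) bool
    watering_windows: list[tuple[float, float]]  # minutes, mask truth


def _downtime_mask(
    model: DowntimeModel,
    n_days: int,
    cadence_minutes: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n_times = int(round(n_days * MINUTES_PER_DAY / cadence_minutes))
    mask = np.zeros(n_times, dtype=bool)
    if model.prob_per_day <= 0:
        return mask
    t = np.arange(n_times) * cadence_minutes
    for day in range(n_days):
        if rng.random() < model.prob_per_day:
            start = (day + rng.random()) * MINUTES_PER_DAY
            length = min(rng.exponential(model.mean_hours), model.max_hours) * 60.0
            mask |= (t >= start) & (t < start + length)
    return mask


def simulate_device(
    config: TrialConfig,
    treatment: str,
    rng: np.random.Generator,
    device_id: str = "DV0000",
    genotype: str = "HYB001",
    moisture: np.ndarray | None = None,
) -> DeviceSim:
    """Simulate one device end to end: moisture -> R,C -> roots -> voltages.

    ``moisture`` may pass a precomputed per-depth moisture matrix for the
    treatment's schedule (it is deterministic, so it can be shared across
    devices of a treatment).
    """
    geom = config.geometry
    soil = config.soil
    spec = config.treatments[treatment]
    _check_contact_vs_soil(config.contact, soil)
    if moisture is None:
        moisture = _moisture_by_depth(spec.schedule, soil, geom, config.n_days)

    res_d, cap_d = moisture_to_rc(moisture, soil)  # (n_depth, n_t)
    # single precision throughout the bulk arrays: noise and deflections are
    # O(1e-2) in log units, far above float32 resolution, and it halves the
    # memory traffic of whole-trial scoring runs
    log_res = np.tile(np.log(res_d).astype(np.float32), (geom.n_paddles, 1))
    log_cap = np.tile(np.log(cap_d).astype(np.float32), (geom.n_paddles, 1))

    truth = sample_root_events(spec, geom, config.n_days, rng)
    log_res, log_cap = inject_root_events(
        log_res, log_cap, truth, config.contact, geom, copy=False
    )

    if soil.noise_sd > 0:
        log_res += soil.noise_sd * rng.standard_normal(
            log_res.shape, dtype=np.float32
        )
        log_cap += soil.noise_sd * rng.standard_normal(
            log_cap.shape, dtype=np.float32
        )

    cst = config.constants
    V1, V2 = simulate_charge_voltages(
        np.exp(log_res), np.exp(log_cap), cst.Vs, cst.ResVD, cst.TC
    )

    downtime = _downtime_mask(
        config.downtime, config.n_days, geom.cadence_minutes, rng
    )
    V1[:, downtime] = np.nan
    V2[:, downtime] = np.nan

    watering = [
        (
            e.start_minutes,
            e.start_minutes + e.duration_hours * 60.0,
        )
        for e in spec.schedule.events
    ]
    truth = truth.assign(device_id=device_id)
    return DeviceSim(
        device_id=device_id,
        treatment=treatment,
        genotype=genotype,
        V1=V1,
        V2=V2,
        truth=truth,
        downtime=downtime,
        watering_windows=watering,
    )


def iter_device_sims(config: TrialConfig):
    """Yield a :class:`DeviceSim` per device, deterministically seeded.

    Each device draws from its own child of ``SeedSequence(config.seed)``,
    so results are independent of iteration order and identical across
    runs with the same config and seed.  Per-treatment moisture matrices
    are computed once and shared.
    """
    devices = config.device_table()
    children = np.random.SeedSequence(config.seed).spawn(len(devices))
    moisture_cache: dict[str, np.ndarray] = {}
    for (row, child) in zip(devices.itertuples(index=False), children):
        trt = row.treatment
        if trt not in moisture_cache:
            moisture_cache[trt] = _moisture_by_depth(
                config.treatments[trt].schedule,
                config.soil,
                config.geometry,
                config.n_days,
            )
        rng = np.random.default_rng(child)
        yield simulate_device(
            config,
            trt,
            rng,
            device_id=row.device_id,
            genotype=row.genotype,
            moisture=moisture_cache[trt],
        )


def simulate_trial(
    config: TrialConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a whole trial into tabular form.

    Returns
    -------
    stream
        Long-format raw measurement stream (one row per electrode per
        cadence tick, downtime gaps omitted) with columns
        ``timestamp, device_id, paddle_index, depth_index, V1_volts,
        V2_volts, TC_seconds, Vs_volts, ResVD_ohms``.
    truth
        Root-contact truth log: ``device_id, timestamp, paddle_index,
        depth_index``.
    mask_truth
        Watering windows and downtime spans per device:
        ``device_id, kind, start, end`` (timestamps).

    Intended for modest configurations (the long format materialises
    ``n_devices * 264 * 288 * n_days`` rows); large scoring runs should
    use :func:`iter_device_sims` and operate on the per-device arrays.
    """
    geom = config.geometry
    ts = config.timestamps()
    n_t = config.n_times
    n_el = geom.n_paddles * geom.electrodes_per_paddle
    paddle_of = np.repeat(np.arange(geom.n_paddles), geom.electrodes_per_paddle)
    depth_of = np.tile(np.arange(geom.electrodes_per_paddle), geom.n_paddles)
    cst = config.constants
    t0 = pd.Timestamp(config.start)

    frames, truths, masks = [], [], []
    for sim in iter_device_sims(config):
        present = ~sim.downtime
        idx_t = np.nonzero(present)[0]
        stream = pd.DataFrame(
            {
                "timestamp": np.repeat(ts[idx_t].values, n_el),
                "device_id": sim.device_id,
                "paddle_index": np.tile(paddle_of, idx_t.size),
                "depth_index": np.tile(depth_of, idx_t.size),
                "V1_volts": sim.V1[:, idx_t].T.ravel(),
                "V2_volts": sim.V2[:, idx_t].T.ravel(),
                "TC_seconds": cst.TC,
                "Vs_volts": cst.Vs,
                "ResVD_ohms": cst.ResVD,
            }
        )
        frames.append(stream)
        tr = sim.truth.copy()
        tr["timestamp"] = t0 + pd.to_timedelta(tr["time_minutes"], unit="m")
        truths.append(tr[["device_id", "timestamp", "paddle_index", "depth_index"]])
        for a, b in sim.watering_windows:
            masks.append(
                {
                    "device_id": sim.device_id,
                    "kind": "watering",
                    "start": t0 + pd.Timedelta(minutes=a),
                    "end": t0 + pd.Timedelta(minutes=b),
                }
            )
        if sim.downtime.any():
            d = np.flatnonzero(
                np.diff(np.concatenate(([0], sim.downtime.astype(int), [0])))
            )
            for a, b in zip(d[::2], d[1::2]):
                masks.append(
                    {
                        "device_id": sim.device_id,
                        "kind": "downtime",
                        "start": ts[a],
                        "end": ts[min(b, n_t - 1)],
                    }
                )
    stream = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=["device_id", "timestamp", "paddle_index", "depth_index"])
    )
    mask_truth = pd.DataFrame(masks, columns=["device_id", "kind", "start", "end"])
    return stream, truth, mask_truth
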