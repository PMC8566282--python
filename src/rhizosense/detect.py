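"""Masking, uptime and root-touch detection.

The raw signal of an in-soil impedance electrode drifts slowly with drying,
oscillates diurnally, and jumps coherently across the whole device when the
field is watered.  A root contact, by contrast, is a fast, localized
deflection in (log R, log C) space whose resistance:capacitance change
ratio is smaller than the wetting-trajectory slope.

The detector therefore works in three stages:

1. **Masking** — windows of device-wide rapid coherent change (rain or
   irrigation), samples with voltages below the resolution floor or
   otherwise unresolvable R-C estimates, and downtime gaps are flagged as
   unreliable.  Masked samples can never fire a detection; they reduce the
   device's daily fractional uptime instead.
2. **Uptime** — ``Ut`` is the unmasked fraction of a device-day's expected
   samples (288 per electrode at 5-minute cadence); ``Utd`` is the same
   per electrode depth.  Daily detection counts are later normalized by
   these (see :mod:`rhizosense.stats`).
3. **Detection** — candidate deflections are two-hour windowed changes of
   (log R, log C); the device-wide median change is subtracted (removing
   coherent drift) and each residual is scored against the robust
   (median/MAD) scale of contemporaneous residuals across all electrodes.
   A detection fires when the normalized magnitude exceeds ``k`` MADs and
   an absolute deflection floor, the change direction lies in the root
   sector (more than ``angle_margin_deg`` away from the wetting line and
   with |dlogR/dlogC| below the wetting slope), and the sample is
   unmasked; at most one detection per electrode per refractory day.

Thresholds, window lengths and the quorum are calibration constants of
this implementation, declared in :class:`DetectorParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import ElectricalConstants, estimate_rc_arrays
from .device import DeviceGeometry
from .simulate import SoilParams, TrialConfig, iter_device_sims, wetting_slope

__all__ = [
    "DetectorParams",
    "MASK_NONE",
    "MASK_DOWNTIME",
    "MASK_LOW_VOLTAGE",
    "MASK_WATERING",
    "compute_masks",
    "daily_uptime",
    "detect_roots",
    "process_device",
    "run_trial",
    "TrialResult",
    "score_detections",
    "arrays_from_stream",
]

# mask reason codes; each masked sample carries exactly one primary reason
MASK_NONE = 0
MASK_DOWNTIME = 1
MASK_LOW_VOLTAGE = 2
MASK_WATERING = 3


@dataclass(frozen=True)
class DetectorParams:
    """Calibration constants of the detector (not field-measured values)."""

    k: float = 5.0  # MAD threshold on the normalized deflection magnitude
    min_magnitude: float = 0.08  # absolute deflection floor, log units
    window_minutes: float = 120.0  # candidate change window
    refractory_days: float = 1.0  # one detection per electrode per day
    angle_margin_deg: float = 20.0  # min angle from the wetting line
    wetting_slope: float = field(
        default_factory=lambda: wetting_slope(SoilParams())
    )  # |dlogR/dlogC| of the wetting trajectory
    scale_floor: float = 1e-3  # MAD floor, log units (guards noise-free data)
    watering_window_minutes: float = 30.0  # coherent-change lookback
    watering_threshold: float = 0.05  # |dlogR| per window flagged as rapid
    watering_quorum: float = 0.5  # fraction of electrodes changing together
    watering_pad_minutes: float = 30.0  # mask dilation on each side


def _lagged_diff(x: np.ndarray, lag: int) -> np.ndarray:
    """x[t] - x[t-lag] along axis 1, with partial windows at the start.

    For ``t < lag`` the change is measured against the first sample, so
    deflections within the first window of a record are still visible;
    ``t = 0`` has no reference and is nan.
    """
    out = np.empty_like(x)
    np.subtract(x[:, 1:lag], x[:, :1], out=out[:, 1:lag])
    out[:, 0] = np.nan
    np.subtract(x[:, lag:], x[:, :-lag], out=out[:, lag:])
    return out


def _median_electrodes(x: np.ndarray) -> np.ndarray:
    """Exact median across electrodes (axis 0) via a two-pivot partition."""
    n = x.shape[0]
    lo, hi = (n - 1) // 2, n // 2
    part = np.partition(x, (lo, hi), axis=0)
    return 0.5 * (part[lo] + part[hi])


def compute_masks(
    log_res: np.ndarray,
    valid: np.ndarray,
    geometry: DeviceGeometry,
    params: DetectorParams = DetectorParams(),
) -> np.ndarray:
    """Per-electrode reason-coded mask over a device's measurement grid.

    Parameters
    ----------
    log_res
        ``(n_electrodes, n_times)`` log-resistance (nan where missing).
    valid
        Same shape; False where the R-C estimate is unreliable (below the
        voltage resolution floor, saturated, unresolvable) or missing.

    Reason codes: downtime (whole device silent) takes precedence over
    low-voltage (electrode-local invalid estimate), which takes precedence
    over watering (device-wide coherent rapid change over the watering
    window, flagged when at least the quorum fraction of electrodes move
    by more than the change threshold, then dilated by the pad).
    """
    n_el, n_t = log_res.shape
    mask = np.zeros((n_el, n_t), dtype=np.uint8)

    downtime_t = ~np.isfinite(log_res).any(axis=0)
    mask[:, downtime_t] = MASK_DOWNTIME

    low = ~valid & (mask == MASK_NONE)
    mask[low] = MASK_LOW_VOLTAGE

    cad = geometry.cadence_minutes
    lag = max(1, int(round(params.watering_window_minutes / cad)))
    dlr = _lagged_diff(log_res, lag)
    rapid = np.abs(dlr) > params.watering_threshold
    n_obs = np.isfinite(dlr).sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_obs > 0, rapid.sum(axis=0) / np.maximum(n_obs, 1), 0.0)
    watering_t = frac >= params.watering_quorum
    pad = max(1, int(round(params.watering_pad_minutes / cad)))
    if watering_t.any():
        idx = np.flatnonzero(watering_t)
        dilated = np.zeros(n_t, dtype=bool)
        for i in idx:
            dilated[max(0, i - pad) : min(n_t, i + pad + 1)] = True
        watering_t = dilated
    mask[:, watering_t] = np.where(
        mask[:, watering_t] == MASK_NONE, MASK_WATERING, mask[:, watering_t]
    )
    return mask


def daily_uptime(
    mask: np.ndarray,
    geometry: DeviceGeometry,
    device_id: str = "DV0000",
    start: str | pd.Timestamp = "2021-05-01",
) -> pd.DataFrame:
    """Daily fractional uptime per device and per electrode depth.

    ``Ut`` is the unmasked fraction of the device-day's expected samples
    (samples-per-day x electrodes); ``Utd_<k>`` the analogue restricted to
    depth index ``k`` (aggregating that depth's electrodes over all
    paddles).  Days at the end of a partial grid use the actual number of
    grid columns that day as the denominator.
    """
    n_el, n_t = mask.shape
    spd = geometry.samples_per_day
    n_days = int(np.ceil(n_t / spd))
    depth_of = np.tile(
        np.arange(geometry.electrodes_per_paddle), geometry.n_paddles
    )
    t0 = pd.Timestamp(start)
    rows = []
    unmasked = mask == MASK_NONE
    for day in range(n_days):
        sl = slice(day * spd, min((day + 1) * spd, n_t))
        block = unmasked[:, sl]
        row: dict[str, object] = {
            "device_id": device_id,
            "day": day,
            "date": (t0 + pd.Timedelta(days=day)).date(),
            "Ut": block.mean(),
        }
        for d in range(geometry.electrodes_per_paddle):
            row[f"Utd_{d}"] = block[depth_of == d].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def detect_roots(
    log_res: np.ndarray,
    log_cap: np.ndarray,
    mask: np.ndarray,
    geometry: DeviceGeometry,
    params: DetectorParams = DetectorParams(),
) -> pd.DataFrame:
    """Root-touch detections from one device's (log R, log C) grids.

    Returns a frame with ``time_index``, ``paddle_index``, ``depth_index``
    and ``score`` (normalized deflection magnitude in MADs).  See the
    module docstring for the algorithm; no detection ever falls on a
    masked sample.
    """
    n_el, n_t = log_res.shape
    cad = geometry.cadence_minutes
    lag = max(1, int(round(params.window_minutes / cad)))

    dr = _lagged_diff(log_res, lag)
    dc = _lagged_diff(log_cap, lag)
    finite = np.isfinite(dr) & np.isfinite(dc)
    # median across electrodes removes coherent drift (diurnal, drying,
    # residual wetting); fill invalid entries with 0 first — with hundreds
    # of electrodes a handful of fills cannot move the median materially
    dr[~finite] = 0.0
    dc[~finite] = 0.0
    r_res = dr - _median_electrodes(dr)
    c_res = dc - _median_electrodes(dc)

    mag = np.hypot(r_res, c_res)
    med = _median_electrodes(mag)
    mad = _median_electrodes(np.abs(mag - med))
    scale = np.maximum(1.4826 * mad, params.scale_floor)
    z = (mag - med) / scale

    slope = params.wetting_slope
    # unit vector along the wetting line in (dlogR, dlogC) space
    norm = np.hypot(slope, 1.0)
    u_r, u_c = -slope / norm, 1.0 / norm
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_angle = np.abs(r_res * u_r + c_res * u_c) / np.maximum(mag, 1e-30)
    in_sector = (np.abs(r_res) < slope * np.abs(c_res)) & (
        cos_angle < np.cos(np.deg2rad(params.angle_margin_deg))
    )

    cand = (
        finite
        & (mask == MASK_NONE)
        & (z >= params.k)
        & (mag >= params.min_magnitude)
        & in_sector
    )

    refractory = int(round(params.refractory_days * geometry.samples_per_day))
    events = []
    for el in range(n_el):
        idx = np.flatnonzero(cand[el])
        last = -1 - refractory
        for t in idx:
            if t - last >= refractory:
                events.append((t, el, float(z[el, t])))
                last = t
    epp = geometry.electrodes_per_paddle
    return pd.DataFrame(
        [
            {
                "time_index": t,
                "paddle_index": el // epp,
                "depth_index": el % epp,
                "score": s,
            }
            for t, el, s in events
        ],
        columns=["time_index", "paddle_index", "depth_index", "score"],
    )


# ---------------------------------------------------------------------------
# Device / trial orchestration


def process_device(
    V1: np.ndarray,
    V2: np.ndarray,
    geometry: DeviceGeometry,
    constants: ElectricalConstants = ElectricalConstants(),
    params: DetectorParams = DetectorParams(),
    device_id: str = "DV0000",
    start: str | pd.Timestamp = "2021-05-01",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw voltages -> (detections, daily uptime) for one device."""
    res, cap, valid = estimate_rc_arrays(V1, V2, constants)
    with np.errstate(invalid="ignore"):
        log_res = np.log(res)
        log_cap = np.log(cap)
    mask = compute_masks(log_res, valid, geometry, params)
    uptime = daily_uptime(mask, geometry, device_id=device_id, start=start)
    det = detect_roots(log_res, log_cap, mask, geometry, params)
    det.insert(0, "device_id", device_id)
    t0 = pd.Timestamp(start)
    det["timestamp"] = t0 + pd.to_timedelta(
        det["time_index"] * geometry.cadence_minutes, unit="m"
    )
    det["day"] = det["time_index"] // geometry.samples_per_day
    return det, uptime


@dataclass
class TrialResult:
    """Detector output for a simulated trial, plus the simulator's truth."""

    detections: pd.DataFrame  # device_id, time_index, paddle/depth, score, day
    uptime: pd.DataFrame  # device_id, day, date, Ut, Utd_*
    truth: pd.DataFrame  # injected contacts
    devices: pd.DataFrame  # device_id, treatment, genotype


def run_trial(
    config: TrialConfig, params: DetectorParams | None = None
) -> TrialResult:
    """Simulate every device of a trial and run the full detector on each.

    Streams device by device (arrays are never held for more than one
    device at a time), so trials of hundreds of devices fit comfortably in
    memory.
    """
    if params is None:
        params = DetectorParams(wetting_slope=wetting_slope(config.soil))
    det_frames, up_frames, truth_frames = [], [], []
    for sim in iter_device_sims(config):
        det, up = process_device(
            sim.V1,
            sim.V2,
            config.geometry,
            config.constants,
            params,
            device_id=sim.device_id,
            start=config.start,
        )
        det_frames.append(det)
        up_frames.append(up)
        truth_frames.append(sim.truth)
    detections = pd.concat(det_frames, ignore_index=True)
    uptime = pd.concat(up_frames, ignore_index=True)
    truth = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(
            columns=["time_minutes", "paddle_index", "depth_index", "day", "device_id"]
        )
    )
    return TrialResult(detections, uptime, truth, config.device_table())


def score_detections(
    detections: pd.DataFrame,
    truth: pd.DataFrame,
    geometry: DeviceGeometry = DeviceGeometry(),
    tol_days: float = 1.0,
) -> dict[str, float]:
    """Precision/recall/F1 of detections against the simulator truth log.

    A detection matches a truth contact when it names the same electrode
    (device, paddle, depth) and lies within ``tol_days`` of the contact
    time; each truth contact absorbs at most one detection and vice versa
    (greedy in time order).
    """
    det = detections.copy()
    tru = truth.copy()
    if len(det):
        det["t_min"] = det["time_index"] * geometry.cadence_minutes
    else:
        det["t_min"] = pd.Series(dtype=float)
    tol = tol_days * 1440.0
    tp = 0
    det_used = np.zeros(len(det), dtype=bool)
    det_groups = {
        key: grp.sort_values("t_min")
        for key, grp in det.groupby(["device_id", "paddle_index", "depth_index"])
    } if len(det) else {}
    for key, tgrp in tru.groupby(["device_id", "paddle_index", "depth_index"]):
        dgrp = det_groups.get(key)
        if dgrp is None:
            continue
        d_times = dgrp["t_min"].to_numpy()
        d_pos = dgrp.index.to_numpy()
        used = np.zeros(len(d_times), dtype=bool)
        for t in np.sort(tgrp["time_minutes"].to_numpy()):
            ok = np.flatnonzero(~used & (np.abs(d_times - t) <= tol))
            if ok.size:
                used[ok[0]] = True
                tp += 1
        det_used[np.searchsorted(det.index.to_numpy(), d_pos[used])] = True
    n_det, n_tru = len(det), len(tru)
    precision = tp / n_det if n_det else 1.0
    recall = tp / n_tru if n_tru else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "tp": tp,
        "n_detections": n_det,
        "n_truth": n_tru,
    }


def arrays_from_stream(
    stream: pd.DataFrame, geometry: DeviceGeometry
) -> dict[str, tuple[pd.Timestamp, np.ndarray, np.ndarray]]:
    """Re-grid a long-format measurement stream into per-device arrays.

    Returns ``{device_id: (start_timestamp, V1, V2)}`` with arrays of
    shape ``(n_electrodes, n_times)`` on a contiguous cadence grid from
    the earliest to the latest timestamp in the stream; missing samples
    (downtime) are nan.
    """
    out = {}
    ts = pd.to_datetime(stream["timestamp"])
    t_start = ts.min().floor("D")
    cad = geometry.cadence_minutes
    epp = geometry.electrodes_per_paddle
    n_el = geometry.n_paddles * epp
    t_idx_all = ((ts - t_start).dt.total_seconds() / 60.0 / cad).round().astype(int)
    n_t = int(t_idx_all.max()) + 1
    el_all = stream["paddle_index"].to_numpy() * epp + stream["depth_index"].to_numpy()
    for dev, grp_idx in stream.groupby("device_id").indices.items():
        V1 = np.full((n_el, n_t), np.nan)
        V2 = np.full((n_el, n_t), np.nan)
        el = el_all[grp_idx]
        ti = t_idx_all.to_numpy()[grp_idx]
        V1[el, ti] = stream["V1_volts"].to_numpy()[grp_idx]
        V2[el, ti] = stream["V2_volts"].to_numpy()[grp_idx]
        out[dev] = (t_start, V1, V2)
    return out
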