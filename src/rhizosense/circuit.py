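"""Parallel-RC circuit model linking charge voltages to soil resistance/capacitance.

Each electrode is charged through a voltage divider while its neighbours are
grounded; the soil between them behaves, to first order, as a resistor and a
capacitor in parallel.  Two voltage readings are taken per measurement
cycle:

* ``V2`` — after charging long enough for the capacitor to be fully charged
  (no capacitive current), so the electrode sits at the divider voltage set
  by the soil resistance ``Res`` against the divider resistance ``ResVD``:

      Res = ResVD * V2 / (Vs - V2)

* ``V1`` — after a short charge of duration ``TC`` (microseconds), still on
  the rising exponential, from which the capacitance follows:

      Cap = -TC * (Res + ResVD) / (Res * ResVD *
            ln(1 - (V1 / Vs) * (Res + ResVD) / Res))

The exact forward model (:func:`simulate_charge_voltages`) inverts this pair
analytically and is used both by the synthetic field simulator and by
round-trip tests: simulate -> estimate recovers (Res, Cap) to floating-point
precision.

All functions are ufunc-like: they accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElectricalConstants",
    "ChargeMeasurement",
    "RCEstimate",
    "SaturatedReadingError",
    "DeadChannelError",
    "UnresolvableCapacitanceError",
    "estimate_resistance",
    "estimate_capacitance",
    "estimate_rc",
    "estimate_rc_arrays",
    "simulate_charge_voltages",
]


def _as_float(x) -> np.ndarray:
    """Coerce to a floating array, preserving an existing float dtype."""
    arr = np.asarray(x)
    return arr.astype(float) if arr.dtype.kind != "f" else arr


class SaturatedReadingError(ValueError):
    """V2 at or above the source voltage: resistance is unresolvable."""


class DeadChannelError(ValueError):
    """Non-positive voltage reading: electrode not charging."""


class UnresolvableCapacitanceError(ValueError):
    """V1 at or beyond the charging asymptote: log argument non-positive."""


@dataclass(frozen=True)
class ElectricalConstants:
    """Charging-circuit constants.

    ``TC`` (the short charge time) is one microsecond; the source voltage
    and divider resistance are typical microcontroller front-end values and
    are configurable.
    """

    Vs: float = 3.3  # source voltage, volts
    ResVD: float = 10_000.0  # divider resistance, ohms
    TC: float = 1e-6  # short charge time, seconds
    v_floor: float = 0.01  # resolution floor, volts; below it readings are unreliable

    def __post_init__(self) -> None:
        if self.Vs <= 0 or self.ResVD <= 0 or self.TC <= 0:
            raise ValueError("Vs, ResVD and TC must all be positive")


@dataclass(frozen=True)
class ChargeMeasurement:
    """One electrode charge event: a (short, long) charge-voltage pair."""

    timestamp: object
    V1: float
    V2: float
    TC: float = 1e-6
    Vs: float = 3.3
    ResVD: float = 10_000.0
    device_id: str | None = None
    paddle_index: int | None = None
    depth_index: int | None = None


@dataclass(frozen=True)
class RCEstimate:
    """Resistance/capacitance estimate with a validity flag.

    Invalid estimates (saturated or dead readings, unresolvable
    capacitance) are flagged rather than raised when produced in bulk, so
    that downstream masking can convert them into reduced uptime.
    """

    Res: float
    Cap: float
    valid: bool = True
    reason: str = ""


def estimate_resistance(
    V2: float | np.ndarray,
    Vs: float = 3.3,
    ResVD: float = 10_000.0,
) -> float | np.ndarray:
    """Soil resistance (ohms) from the long-charge voltage.

    ``Res = ResVD * V2 / (Vs - V2)``; strictly increasing in ``V2``.

    Raises
    ------
    SaturatedReadingError
        If ``V2 >= Vs`` (scalar input only; arrays yield ``nan``).
    DeadChannelError
        If ``V2 <= 0`` (scalar input only; arrays yield ``nan``).
    """
    if np.isscalar(V2):
        if V2 >= Vs:
            raise SaturatedReadingError(f"V2={V2} V >= Vs={Vs} V")
        if V2 <= 0:
            raise DeadChannelError(f"V2={V2} V is non-positive")
        return ResVD * V2 / (Vs - V2)
    V2 = _as_float(V2)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = ResVD * V2 / (Vs - V2)
    return np.where((V2 > 0) & (V2 < Vs), res, np.nan)


def estimate_capacitance(
    V1: float | np.ndarray,
    res: float | np.ndarray,
    Vs: float = 3.3,
    ResVD: float = 10_000.0,
    TC: float = 1e-6,
) -> float | np.ndarray:
    """Soil capacitance (farads) from the short-charge voltage.

    Inverts the rising exponential of a parallel-RC circuit charged for
    ``TC`` seconds through the divider.  The log argument
    ``1 - (V1/Vs) * (res + ResVD) / res`` must be positive: ``V1`` cannot
    exceed the steady-state voltage the divider would reach.

    Raises
    ------
    UnresolvableCapacitanceError
        If the log argument is non-positive (scalar input only; arrays
        yield ``nan``).
    ValueError
        If ``res`` is non-positive (scalar input only).
    """
    scalar = np.isscalar(V1) and np.isscalar(res)
    if scalar:
        if res <= 0:
            raise ValueError(f"res={res} ohm must be positive")
        if V1 <= 0:
            raise DeadChannelError(f"V1={V1} V is non-positive")
        arg = 1.0 - (V1 / Vs) * (res + ResVD) / res
        if arg <= 0:
            raise UnresolvableCapacitanceError(
                f"V1={V1} V at or beyond the charging asymptote "
                f"Vs*res/(res+ResVD)={Vs * res / (res + ResVD):.4g} V"
            )
        return -TC * (res + ResVD) / (res * ResVD * np.log(arg))
    V1 = _as_float(V1)
    res = _as_float(res)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = 1.0 - (V1 / Vs) * (res + ResVD) / res
        cap = -TC * (res + ResVD) / (res * ResVD * np.log(arg))
    ok = (res > 0) & (V1 > 0) & (arg > 0)
    return np.where(ok, cap, np.nan)


def estimate_rc(m: ChargeMeasurement) -> RCEstimate:
    """Full two-stage estimate for one measurement, flagging invalid readings."""
    if m.V2 >= m.Vs:
        return RCEstimate(np.nan, np.nan, False, "saturated_reading")
    if m.V2 <= 0 or m.V1 <= 0:
        return RCEstimate(np.nan, np.nan, False, "dead_channel")
    res = estimate_resistance(m.V2, m.Vs, m.ResVD)
    try:
        cap = estimate_capacitance(m.V1, res, m.Vs, m.ResVD, m.TC)
    except UnresolvableCapacitanceError:
        return RCEstimate(res, np.nan, False, "unresolvable_capacitance")
    return RCEstimate(res, cap, True)


def estimate_rc_arrays(
    V1: np.ndarray,
    V2: np.ndarray,
    constants: ElectricalConstants = ElectricalConstants(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (Res, Cap, valid) over arrays of charge-voltage pairs.

    Saturated, dead, below-floor and unresolvable readings yield
    ``valid=False`` with ``nan`` estimates; missing samples (``nan``
    voltages, e.g. downtime) are likewise invalid.
    """
    V1 = _as_float(V1)
    V2 = _as_float(V2)
    res = estimate_resistance(V2, constants.Vs, constants.ResVD)
    cap = estimate_capacitance(V1, res, constants.Vs, constants.ResVD, constants.TC)
    valid = (
        np.isfinite(res)
        & np.isfinite(cap)
        & (V1 >= constants.v_floor)
        & (V2 >= constants.v_floor)
    )
    return res, cap, valid


def simulate_charge_voltages(
    res: float | np.ndarray,
    cap: float | np.ndarray,
    Vs: float = 3.3,
    ResVD: float = 10_000.0,
    TC: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact forward model: charge voltages of a parallel-RC soil load.

    The long charge reaches the divider steady state
    ``V2 = Vs * res / (res + ResVD)``; the short charge of duration ``TC``
    sits on the rising exponential with time constant
    ``tau = cap * res * ResVD / (res + ResVD)``:
    ``V1 = V2 * (1 - exp(-TC / tau))``.

    For positive inputs ``0 < V1 < V2 < Vs`` always holds.
    """
    res = _as_float(res)
    cap = _as_float(cap)
    V2 = Vs * res / (res + ResVD)
    tau = cap * res * ResVD / (res + ResVD)
    V1 = V2 * -np.expm1(-TC / tau)
    return V1, V2
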