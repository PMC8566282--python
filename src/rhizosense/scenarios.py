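"""Reference simulation scenarios used for validation and recovery studies.

Each function returns a fully specified :class:`~rhizosense.simulate.TrialConfig`.
The scenarios are the package's study conditions: the detector is scored
against the simulator's truth log on them, and programmed treatment
effects (rate reductions, depth shifts) are recovered through the full
pipeline.  Scenario parameters are fixed here — they define the
conditions, they are not tuning knobs.

* ``reference_noise_free`` — drying + diurnal + root contacts, no
  measurement noise, no irrigation, no downtime: the detector should be
  exact (precision = recall = 1).
* ``reference_noisy`` — adds 1% multiplicative measurement noise, twice-
  weekly irrigation and random downtime: the realistic operating point.
* ``wetting_only`` — irrigation pulses and no roots, noise-free: wetting
  moves the signal along the trajectory the detector must ignore, so any
  detection is a false positive.
* ``drought_recovery`` — two treatments of 300 devices; the drought
  treatment stops irrigation at day 10 and carries a programmed x0.64
  arrival-rate multiplier (36% fewer new roots per day) over days 10-19.
* ``depth_shift`` — two treatments of 150 devices; the primed treatment
  concentrates post-drought arrivals in the deeper half of electrode
  depths over days 10-19.
"""

from __future__ import annotations

from .device import DeviceGeometry
from .simulate import (
    DowntimeModel,
    IrrigationSchedule,
    SoilParams,
    TreatmentSpec,
    TrialConfig,
    deep_depth_profile,
)

__all__ = [
    "reference_noise_free",
    "reference_noisy",
    "wetting_only",
    "drought_recovery",
    "depth_shift",
    "DROUGHT_WINDOW",
]

#: Analysis day window (inclusive) of the drought / depth-shift scenarios.
DROUGHT_WINDOW = (10, 19)


def reference_noise_free(
    seed: int = 1, n_devices: int = 100, n_days: int = 30
) -> TrialConfig:
    """Noise-free detection oracle: drying, diurnal cycle and roots only."""
    return TrialConfig(
        n_days=n_days,
        seed=seed,
        soil=SoilParams(noise_sd=0.0),
        treatments={"well_watered": TreatmentSpec(root_arrival_rate=2.0)},
        n_devices={"well_watered": n_devices},
    )


def reference_noisy(
    seed: int = 1, n_devices: int = 100, n_days: int = 30
) -> TrialConfig:
    """Realistic operating point: noise, irrigation, downtime and roots."""
    return TrialConfig(
        n_days=n_days,
        seed=seed,
        treatments={
            "well_watered": TreatmentSpec(
                root_arrival_rate=2.0,
                schedule=IrrigationSchedule.weekly(
                    n_days, events_per_week=2, duration_hours=3.0
                ),
            )
        },
        n_devices={"well_watered": n_devices},
        downtime=DowntimeModel(prob_per_day=0.1, mean_hours=4.0),
    )


def wetting_only(seed: int = 1, n_devices: int = 20, n_days: int = 30) -> TrialConfig:
    """Irrigation pulses, zero roots, noise-free: any detection is spurious."""
    return TrialConfig(
        n_days=n_days,
        seed=seed,
        soil=SoilParams(noise_sd=0.0),
        treatments={
            "well_watered": TreatmentSpec(
                root_arrival_rate=0.0,
                schedule=IrrigationSchedule.weekly(
                    n_days, events_per_week=2, duration_hours=3.0
                ),
            )
        },
        n_devices={"well_watered": n_devices},
    )


def drought_recovery(
    seed: int = 1,
    n_per_group: int = 300,
    n_days: int = 20,
    rate_multiplier: float = 0.64,
) -> TrialConfig:
    """Programmed drought response: x0.64 arrival rate during days 10-19.

    The well-watered treatment is irrigated throughout; the drought
    treatment's irrigation stops at day 10, and its root-arrival rate
    carries the programmed multiplier over the drought window, emulating
    a 36% reduction in new roots per day.
    """
    a, _ = DROUGHT_WINDOW
    return TrialConfig(
        n_days=n_days,
        seed=seed,
        treatments={
            "well_watered": TreatmentSpec(
                root_arrival_rate=2.0,
                schedule=IrrigationSchedule.weekly(n_days, events_per_week=2),
            ),
            "drought": TreatmentSpec(
                root_arrival_rate=2.0,
                schedule=IrrigationSchedule.weekly(
                    n_days, events_per_week=2, until_day=a
                ),
                rate_multipliers=((a, n_days, rate_multiplier),),
            ),
        },
        n_devices={"well_watered": n_per_group, "drought": n_per_group},
        downtime=DowntimeModel(prob_per_day=0.05, mean_hours=4.0),
    )


def depth_shift(
    seed: int = 1, n_per_group: int = 150, n_days: int = 20
) -> TrialConfig:
    """Primed deep growth: post-drought arrivals concentrated deep.

    Both treatments keep the same overall arrival rate; the primed
    treatment's arrival depth profile switches to the deep profile over
    days 10-19, emulating the deeper-half growth excess of a priming
    response.
    """
    a, _ = DROUGHT_WINDOW
    geometry = DeviceGeometry()
    return TrialConfig(
        n_days=n_days,
        seed=seed,
        geometry=geometry,
        treatments={
            "well_watered": TreatmentSpec(
                root_arrival_rate=2.0,
                schedule=IrrigationSchedule.weekly(n_days, events_per_week=2),
            ),
            "primed": TreatmentSpec(
                root_arrival_rate=2.0,
                schedule=IrrigationSchedule.weekly(
                    n_days, events_per_week=2, until_day=a
                ),
                depth_profile_windows=(
                    (a, n_days, deep_depth_profile(geometry)),
                ),
            ),
        },
        n_devices={"well_watered": n_per_group, "primed": n_per_group},
        downtime=DowntimeModel(prob_per_day=0.05, mean_hours=4.0),
    )
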