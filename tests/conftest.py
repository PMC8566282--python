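import numpy as np
import pandas as pd
import pytest

from rhizosense.device import DeviceGeometry
from rhizosense.simulate import (
    DowntimeModel,
    IrrigationSchedule,
    SoilParams,
    TreatmentSpec,
    TrialConfig,
)


@pytest.fixture(scope="session")
def geometry() -> DeviceGeometry:
    return DeviceGeometry()


@pytest.fixture(scope="session")
def tiny_geometry() -> DeviceGeometry:
    """Small geometry for fast long-format / CLI round trips."""
    return DeviceGeometry(
        n_paddles=2, electrodes_per_paddle=4, cadence_minutes=15.0
    )


@pytest.fixture(scope="session")
def tiny_config(tiny_geometry) -> TrialConfig:
    """3-day, 6-device two-treatment trial on the tiny geometry."""
    return TrialConfig(
        n_days=3,
        seed=7,
        geometry=tiny_geometry,
        treatments={
            "well_watered": TreatmentSpec(
                root_arrival_rate=1.0,
                schedule=IrrigationSchedule.weekly(3, events_per_week=2),
            ),
            "drought": TreatmentSpec(root_arrival_rate=0.5),
        },
        n_devices={"well_watered": 3, "drought": 3},
        genotypes=("HYB001", "HYB002"),
        downtime=DowntimeModel(prob_per_day=0.2),
    )


@pytest.fixture(scope="session")
def small_noisy_result():
    """Shared full-pipeline run: 6 devices, 12 days, noise + irrigation."""
    from rhizosense.detect import run_trial

    cfg = TrialConfig(
        n_days=12,
        seed=11,
        treatments={
            "well_watered": TreatmentSpec(
                root_arrival_rate=2.0,
                schedule=IrrigationSchedule.weekly(12, events_per_week=2),
            )
        },
        n_devices={"well_watered": 6},
        downtime=DowntimeModel(prob_per_day=0.1),
    )
    return cfg, run_trial(cfg)


@pytest.fixture
def uptime_frame(geometry):
    """Hand-built uptime table for rate arithmetic tests: one device, 5 days."""
    rows = []
    uts = [1.0, 0.8, 0.04, 0.5, 0.0]
    for day, ut in enumerate(uts):
        row = {"device_id": "DV0000", "day": day, "date": f"2021-05-0{day+1}",
               "Ut": ut}
        for d in range(geometry.electrodes_per_paddle):
            row[f"Utd_{d}"] = ut
        rows.append(row)
    return pd.DataFrame(rows)
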