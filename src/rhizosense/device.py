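"""Device geometry and field-experiment layout.

The sensing device is a cylinder of vertical circuit-board paddles driven
into the soil around a planted seed.  Each paddle carries a vertical array
of equally spaced impedance-sensing electrodes; with the default geometry
(12 paddles x 22 electrodes) a device exposes 264 electrodes spanning
1.9-16.1 cm below the soil surface, each charged on a 5-minute cadence.

A field trial is described by a *field map*: one row per device giving its
location, genotype, treatment and status flags.  Devices with no plant,
physical damage, non-functional electronics, missing tags or duplicate IDs
are culled before any statistics are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DeviceGeometry",
    "ElectrodeAddress",
    "InvalidGeometryError",
    "electrode_depths",
    "total_electrodes",
    "paddle_azimuths",
    "cull_field_map",
    "CULL_FLAGS",
]

#: Status flags that remove a device from all statistical calculations.
CULL_FLAGS = frozenset(
    {"no_plant", "damaged", "nonfunctional", "missing_tag", "duplicate_id"}
)


class InvalidGeometryError(ValueError):
    """Raised when a device geometry violates its physical invariants."""


@dataclass(frozen=True)
class DeviceGeometry:
    """Physical layout of one sensing device.

    Parameters
    ----------
    n_paddles
        Number of vertical paddles arranged around the cylinder.
    electrodes_per_paddle
        Electrodes per paddle, equally spaced in depth.
    depth_shallow_cm, depth_deep_cm
        Depths of the shallowest and deepest electrode below the soil
        surface (positive cm downward).
    cadence_minutes
        Measurement cadence: every electrode is charged once per cadence.
    diameter_cm
        Outer diameter of the cylinder; used by the image ground-truth
        region of interest, not by the detection statistics.
    """

    n_paddles: int = 12
    electrodes_per_paddle: int = 22
    depth_shallow_cm: float = 1.9
    depth_deep_cm: float = 16.1
    cadence_minutes: float = 5.0
    diameter_cm: float = 10.0

    def __post_init__(self) -> None:
        if self.n_paddles < 1:
            raise InvalidGeometryError("n_paddles must be >= 1")
        if self.electrodes_per_paddle < 2:
            raise InvalidGeometryError("electrodes_per_paddle must be >= 2")
        if not self.depth_deep_cm > self.depth_shallow_cm:
            raise InvalidGeometryError(
                "depth_deep_cm must exceed depth_shallow_cm"
            )
        if self.cadence_minutes <= 0:
            raise InvalidGeometryError("cadence_minutes must be positive")

    @property
    def depth_spacing_cm(self) -> float:
        """Vertical spacing between neighbouring electrodes on a paddle."""
        return (self.depth_deep_cm - self.depth_shallow_cm) / (
            self.electrodes_per_paddle - 1
        )

    @property
    def samples_per_day(self) -> int:
        """Expected measurements per electrode per day (288 at 5-min cadence)."""
        return int(round(24 * 60 / self.cadence_minutes))

    def depth_cm(self, depth_index: int) -> float:
        """Depth of electrode ``depth_index`` (0 = shallowest)."""
        if not 0 <= depth_index < self.electrodes_per_paddle:
            raise IndexError(f"depth_index {depth_index} out of range")
        return self.depth_shallow_cm + depth_index * self.depth_spacing_cm


@dataclass(frozen=True)
class ElectrodeAddress:
    """Position of one electrode on a device: (paddle, depth rank, depth)."""

    paddle_index: int
    depth_index: int
    depth_cm: float

    @classmethod
    def from_geometry(
        cls, geometry: DeviceGeometry, paddle_index: int, depth_index: int
    ) -> "ElectrodeAddress":
        return cls(paddle_index, depth_index, geometry.depth_cm(depth_index))


def electrode_depths(geometry: DeviceGeometry) -> np.ndarray:
    """Ordered electrode depths (cm, shallowest first) for one paddle.

    The returned sequence is arithmetic: equally spaced from
    ``depth_shallow_cm`` to ``depth_deep_cm`` inclusive.
    """
    return np.linspace(
        geometry.depth_shallow_cm,
        geometry.depth_deep_cm,
        geometry.electrodes_per_paddle,
    )


def total_electrodes(geometry: DeviceGeometry) -> int:
    """Total electrode count of one device (paddles x electrodes per paddle)."""
    return geometry.n_paddles * geometry.electrodes_per_paddle


def paddle_azimuths(geometry: DeviceGeometry) -> np.ndarray:
    """Azimuth (degrees) of each paddle, uniformly spaced around the cylinder.

    Carried for completeness (growth-orientation summaries); unused by the
    core detection statistics.
    """
    return np.arange(geometry.n_paddles) * (360.0 / geometry.n_paddles)


# ---------------------------------------------------------------------------
# Field map


_FIELD_MAP_COLUMNS = ["device_id", "row", "position", "genotype", "treatment", "status"]


def _status_flags(status: object) -> set[str]:
    """Parse a status cell into a set of flags. Empty / 'ok' means unflagged."""
    if status is None or (isinstance(status, float) and np.isnan(status)):
        return set()
    text = str(status).strip().lower()
    if text in {"", "ok", "none", "nan"}:
        return set()
    return {tok.strip() for tok in text.replace(",", ";").split(";") if tok.strip()}


def cull_field_map(
    field_map: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove devices unfit for analysis and log the reason for each removal.

    A device is removed if its status carries any of :data:`CULL_FLAGS`
    (no plant from poor germination or premature death, physical damage,
    non-functional electronics, missing tag) or if its ID occurs more than
    once.  Duplicate IDs remove *all* entries sharing the ID: ambiguous
    provenance taints every copy.

    Parameters
    ----------
    field_map
        One row per device with at least ``device_id`` and ``status``
        columns (see :func:`rhizosense.io.read_field_map`).

    Returns
    -------
    retained, removal_log
        ``retained`` is the culled map (unique device IDs).
        ``removal_log`` has columns ``device_id`` and ``reason``.

    Notes
    -----
    Culling is idempotent: applying it to its own output is the identity.
    An empty retained map is a warning, not an error.
    """
    df = field_map.copy()
    if "device_id" not in df.columns:
        raise KeyError("field map requires a 'device_id' column")
    status = (
        df["status"] if "status" in df.columns else pd.Series("", index=df.index)
    )
    removals: list[tuple[object, str]] = []
    drop = pd.Series(False, index=df.index)

    dup_ids = df["device_id"][df["device_id"].duplicated(keep=False)].unique()
    for idx in df.index:
        flags = _status_flags(status.loc[idx]) & CULL_FLAGS
        if df.at[idx, "device_id"] in dup_ids:
            flags = flags | {"duplicate_id"}
        if flags:
            drop.loc[idx] = True
            removals.append((df.at[idx, "device_id"], ";".join(sorted(flags))))

    retained = df.loc[~drop].reset_index(drop=True)
    removal_log = pd.DataFrame(removals, columns=["device_id", "reason"])
    if len(retained) == 0 and len(df) > 0:
        warnings.warn("culling removed every device in the field map", stacklevel=2)
    return retained, removal_log
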