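"""Needle-array geometry and pulse-train definitions.

Models the two four-needle electrochemotherapy electrodes compared in the
feline nasal-planum study -- a "standard" array built from 20 G hypodermic
needles and a "thin" array with the same layout built from 25 G needles --
as well as arbitrary user-defined arrays.  The needles stand in two parallel
rows; one row is wired as the anode, the other as the cathode, and the pulse
generator applies a voltage chosen so that voltage / row gap equals the
nominal treatment field (1000 V/cm for the clinical protocol).

Lengths are millimetres throughout the public surface; the field solver
converts to SI internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

__all__ = [
    "Polarity",
    "Needle",
    "ElectrodeArray",
    "PulseProtocol",
    "GAUGE_OUTER_DIAMETER_MM",
    "gauge_to_diameter",
    "build_array",
    "build_pulse_protocol",
    "delivered_charge",
]


class Polarity(str, Enum):
    ANODE = "anode"
    CATHODE = "cathode"


#: Nominal outer diameters of hypodermic needles (ISO 9626), in mm.
GAUGE_OUTER_DIAMETER_MM: dict[int, float] = {
    18: 1.2,
    19: 1.1,
    20: 0.9,
    21: 0.8,
    22: 0.7,
    23: 0.6,
    24: 0.55,
    25: 0.5,
    26: 0.45,
    27: 0.4,
}


def gauge_to_diameter(gauge: int) -> float:
    """Nominal outer diameter (mm) of a hypodermic needle of the given gauge.

    Raises :class:`ValueError` for gauges outside the supported table.
    """
    try:
        return GAUGE_OUTER_DIAMETER_MM[int(gauge)]
    except (KeyError, TypeError):
        supported = ", ".join(str(g) for g in sorted(GAUGE_OUTER_DIAMETER_MM))
        raise ValueError(
            f"unsupported gauge {gauge!r}; supported gauges: {supported}"
        ) from None


@dataclass(frozen=True)
class Needle:
    """A single needle, seen as a conducting disk in the modelled cross-section.

    ``center_x``/``center_y`` locate the needle axis in the tissue plane at
    mid-insertion depth; ``radius`` is the conductor radius (half the nominal
    outer diameter); ``insertion_depth`` is the length of needle in contact
    with tissue, used to scale per-unit-length 2-D currents to amperes.
    """

    center_x: float
    center_y: float
    radius: float
    insertion_depth: float
    polarity: Polarity

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("needle radius must be positive")
        if self.insertion_depth <= 0:
            raise ValueError("insertion depth must be positive")


@dataclass(frozen=True)
class ElectrodeArray:
    """A set of needles with fixed wiring, plus the layout gaps that built it."""

    needles: tuple[Needle, ...]
    row_gap: float
    within_row_gap: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "needles", tuple(self.needles))
        if len(self.needles) < 2:
            raise ValueError("an electrode array needs at least two needles")
        pols = {n.polarity for n in self.needles}
        if pols != {Polarity.ANODE, Polarity.CATHODE}:
            raise ValueError("array needs at least one anode and one cathode")
        for i, a in enumerate(self.needles):
            for b in self.needles[i + 1 :]:
                gap = math.hypot(a.center_x - b.center_x, a.center_y - b.center_y)
                if gap <= a.radius + b.radius:
                    raise ValueError(
                        f"needle disks overlap: centers {gap:.3f} mm apart, "
                        f"radii {a.radius:.3f} + {b.radius:.3f} mm"
                    )

    @property
    def extent(self) -> float:
        """Largest span of the array including needle bodies, in mm."""
        span = max(
            math.hypot(a.center_x - b.center_x, a.center_y - b.center_y)
            + a.radius
            + b.radius
            for a in self.needles
            for b in self.needles
        )
        return span

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "row_gap_mm": self.row_gap,
            "within_row_gap_mm": self.within_row_gap,
            "needles": [
                {
                    "center_x_mm": n.center_x,
                    "center_y_mm": n.center_y,
                    "radius_mm": n.radius,
                    "insertion_depth_mm": n.insertion_depth,
                    "polarity": n.polarity.value,
                }
                for n in self.needles
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class PulseProtocol:
    """A monopolar square-wave pulse train.

    The clinical protocol is eight 100 µs pulses of 400 V (a 1000 V/cm
    voltage-to-distance ratio over the 4 mm row gap) at 5 kHz.
    """

    n_pulses: int
    pulse_width_us: float
    voltage: float
    repetition_frequency_hz: float
    voltage_to_distance_v_per_cm: float
    row_gap_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("a pulse train needs at least one pulse")
        for name in ("pulse_width_us", "voltage", "repetition_frequency_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        expected = self.voltage_to_distance_v_per_cm * self.row_gap_mm / 10.0
        if not math.isclose(self.voltage, expected, rel_tol=1e-3):
            raise ValueError(
                "inconsistent pulse protocol: voltage "
                f"{self.voltage} V vs voltage_to_distance x row_gap = {expected} V"
            )


ARRAY_KINDS = {"standard": 20, "thin": 25}


def build_array(
    kind: str,
    row_gap: float = 4.0,
    within_row_gap: float = 4.0,
    insertion_depth: float = 5.0,
) -> ElectrodeArray:
    """Build one of the two study arrays (or the same layout at another gauge).

    Four needles sit at the corners of a ``within_row_gap`` x ``row_gap``
    rectangle centred on the origin.  The row at positive *y* is the anode
    row, the row at negative *y* the cathode row.  ``kind`` selects the
    needle gauge: ``"standard"`` -> 20 G (0.45 mm radius), ``"thin"`` -> 25 G
    (0.25 mm radius).
    """
    if kind not in ARRAY_KINDS:
        raise ValueError(f"unknown array kind {kind!r}; expected one of {sorted(ARRAY_KINDS)}")
    if row_gap <= 0 or within_row_gap <= 0:
        raise ValueError("gaps must be positive")
    radius = gauge_to_diameter(ARRAY_KINDS[kind]) / 2.0
    half_w, half_r = within_row_gap / 2.0, row_gap / 2.0
    needles = [
        Needle(-half_w, +half_r, radius, insertion_depth, Polarity.ANODE),
        Needle(+half_w, +half_r, radius, insertion_depth, Polarity.ANODE),
        Needle(-half_w, -half_r, radius, insertion_depth, Polarity.CATHODE),
        Needle(+half_w, -half_r, radius, insertion_depth, Polarity.CATHODE),
    ]
    # ElectrodeArray.__post_init__ re-checks all pairs; this gives the clearer
    # message for the common mistake of rows closer than the needle bodies.
    if row_gap <= 2 * radius or within_row_gap <= 2 * radius:
        raise ValueError(
            f"gaps ({within_row_gap} x {row_gap} mm) too small for needle "
            f"radius {radius} mm: disks would overlap"
        )
    return ElectrodeArray(tuple(needles), row_gap, within_row_gap, label=kind)


def build_pulse_protocol(
    voltage: float = 400.0,
    row_gap: float = 4.0,
    n_pulses: int = 8,
    width_us: float = 100.0,
    freq_hz: float = 5000.0,
) -> PulseProtocol:
    """Pulse train with the voltage-to-distance ratio derived from the row gap."""
    if voltage <= 0 or row_gap <= 0:
        raise ValueError("voltage and row gap must be positive")
    vtd = voltage / (row_gap / 10.0)  # V per cm
    return PulseProtocol(
        n_pulses=n_pulses,
        pulse_width_us=width_us,
        voltage=voltage,
        repetition_frequency_hz=freq_hz,
        voltage_to_distance_v_per_cm=vtd,
        row_gap_mm=row_gap,
    )


def delivered_charge(protocol: PulseProtocol, mean_current: float) -> float:
    """Total charge (C) passed by the pulse train at the given mean current (A).

    Q = n_pulses x pulse_width x I.  A coarse proxy for the electrolytic load
    at the electrode surfaces; the electrochemistry itself is out of scope.
    """
    if mean_current < 0:
        raise ValueError("mean current must be non-negative")
    return protocol.n_pulses * protocol.pulse_width_us * 1e-6 * mean_current
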