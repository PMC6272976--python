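"""Deterministic assay arithmetic.

Enzyme activity is measured by the DNS (3,5-dinitrosalicylic acid) reducing
sugar method read at 540 nm.  One unit (U) is the enzyme releasing 1 ug of
d-galactose per minute.  Activity follows

    EA (U/mL) = (A * slope + intercept) * V * n / (v * T)

where A is the absorbance, V the total reaction volume (mL), n the dilution
factor, v the enzyme volume (mL) and T the digestion time (min).  The
default slope 640.5 and intercept 13.99 come from a d-galactose standard
curve and can be overridden for a different calibration.

Medium viscosity from a rotary viscometer is the rotor coefficient times
the instrument reading: eta = k * reading.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AssayReading",
    "ViscosityReading",
    "InvalidReadingError",
    "enzyme_activity",
    "viscosity",
    "DNS_SLOPE",
    "DNS_INTERCEPT",
]

DNS_SLOPE = 640.5
DNS_INTERCEPT = 13.99


class InvalidReadingError(ValueError):
    """An assay reading violates its positivity constraints."""


@dataclass(frozen=True)
class AssayReading:
    """One DNS assay observation.

    A: absorbance at 540 nm (>= 0); V: total reaction volume in mL (> 0);
    n: dilution factor (>= 1); v: enzyme volume in mL (> 0); T: digestion
    time in minutes (> 0).
    """

    A: float
    V: float
    n: float
    v: float
    T: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise InvalidReadingError(f"absorbance must be >= 0, got {self.A}")
        if self.V <= 0:
            raise InvalidReadingError(f"reaction volume must be > 0, got {self.V}")
        if self.n < 1:
            raise InvalidReadingError(f"dilution factor must be >= 1, got {self.n}")
        if self.v <= 0:
            raise InvalidReadingError(f"enzyme volume must be > 0, got {self.v}")
        if self.T <= 0:
            raise InvalidReadingError(f"digestion time must be > 0, got {self.T}")


@dataclass(frozen=True)
class ViscosityReading:
    """Rotary viscometer observation: rotor coefficient k (> 0) and
    instrument reading (>= 0)."""

    k: float
    reading: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise InvalidReadingError(f"rotor coefficient must be > 0, got {self.k}")
        if self.reading < 0:
            raise InvalidReadingError(f"reading must be >= 0, got {self.reading}")


def enzyme_activity(
    r: AssayReading,
    slope: float = DNS_SLOPE,
    intercept: float = DNS_INTERCEPT,
) -> float:
    """Enzyme activity in U/mL from one DNS reading."""
    return (r.A * slope + intercept) * r.V * r.n / (r.v * r.T)


def viscosity(r: ViscosityReading) -> float:
    """Viscosity eta = k * reading."""
    return r.k * r.reading
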