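"""NASA 7-coefficient polynomial thermodynamics.

Standard two-range representation of dimensionless heat capacity, enthalpy
and entropy:

    cp/R  = a1 + a2*T + a3*T^2 + a4*T^3 + a5*T^4
    H/RT  = a1 + a2*T/2 + a3*T^2/3 + a4*T^3/4 + a5*T^4/5 + a6/T
    S/R   = a1*ln(T) + a2*T + a3*T^2/2 + a4*T^3/3 + a5*T^4/4 + a7

The low-range coefficient set applies for T <= T_mid, the high-range set
above.  The isothermal reactor model never consumes these values — they are
evaluated on demand for reporting and for compatibility with standard
mechanism databases.  No coefficients for the lumped lipid-oxidation species
ship with the package; fixtures used in tests are synthetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import MechanismParseError, ThermoRangeError


@dataclass(frozen=True)
class Nasa7Record:
    """Two-range NASA-7 polynomial record for one species."""

    species_name: str
    T_low: float
    T_mid: float
    T_high: float
    coeffs_low: tuple[float, ...]
    coeffs_high: tuple[float, ...]

    def __post_init__(self):
        if not (self.T_low < self.T_mid < self.T_high):
            raise ValueError(
                f"require T_low < T_mid < T_high, got "
                f"{self.T_low}, {self.T_mid}, {self.T_high}"
            )
        for name in ("coeffs_low", "coeffs_high"):
            c = tuple(float(x) for x in getattr(self, name))
            if len(c) != 7:
                raise ValueError(f"{name} must have 7 entries, got {len(c)}")
            object.__setattr__(self, name, c)

    def _coeffs(self, T: float) -> tuple[float, ...]:
        if not (self.T_low <= T <= self.T_high):
            raise ThermoRangeError(
                f"T={T} K outside [{self.T_low}, {self.T_high}] for {self.species_name}"
            )
        return self.coeffs_low if T <= self.T_mid else self.coeffs_high


def cp_over_R(rec: Nasa7Record, T: float) -> float:
    """Dimensionless heat capacity cp/R at ``T`` kelvin."""
    a = rec._coeffs(T)
    return a[0] + a[1] * T + a[2] * T**2 + a[3] * T**3 + a[4] * T**4


def h_over_RT(rec: Nasa7Record, T: float) -> float:
    """Dimensionless enthalpy H/(R*T) at ``T`` kelvin."""
    a = rec._coeffs(T)
    return (
        a[0]
        + a[1] * T / 2
        + a[2] * T**2 / 3
        + a[3] * T**3 / 4
        + a[4] * T**4 / 5
        + a[5] / T
    )


def s_over_R(rec: Nasa7Record, T: float) -> float:
    """Dimensionless entropy S/R at ``T`` kelvin."""
    a = rec._coeffs(T)
    return (
        a[0] * math.log(T)
        + a[1] * T
        + a[2] * T**2 / 2
        + a[3] * T**3 / 3
        + a[4] * T**4 / 4
        + a[6]
    )


def check_midpoint_continuity(rec: Nasa7Record, rtol: float = 1e-4) -> bool:
    """True when low- and high-range cp/R agree at T_mid within ``rtol`` relative."""
    low = sum(c * rec.T_mid**i for i, c in enumerate(rec.coeffs_low[:5]))
    high = sum(c * rec.T_mid**i for i, c in enumerate(rec.coeffs_high[:5]))
    scale = max(abs(low), abs(high), 1e-300)
    return abs(low - high) / scale <= rtol


# ---------------------------------------------------------------------------
# Fixed-column NASA thermo card I/O ("THERMO" ... "END" blocks, 4 lines/species)


def _card_floats(line: str, n: int) -> list[float]:
    out = []
    for i in range(n):
        field = line[15 * i : 15 * (i + 1)]
        out.append(float(field))
    return out


def read_thermo_cards(text: str) -> list[Nasa7Record]:
    """Parse 4-line fixed-column NASA-7 thermo cards.

    Layout: optional ``THERMO`` header (with an optional global temperature
    line), then per species one header line (name in columns 1-18, T_low,
    T_high, T_mid in columns 46-75, a ``1`` in column 80) and three coefficient
    lines of five, five and four 15-column floats: a1..a5 high, a6 a7 high +
    a1..a3 low, a4..a7 low.
    """
    lines = [ln.rstrip("\n") for ln in text.splitlines()]
    records: list[Nasa7Record] = []
    i = 0
    while i < len(lines):
        stripped = lines[i].strip()
        if not stripped or stripped.upper().startswith("THERMO"):
            i += 1
            # a THERMO header may be followed by a global T-range line
            if records == [] and i < len(lines):
                toks = lines[i].split()
                if len(toks) == 3:
                    try:
                        [float(t) for t in toks]
                        i += 1
                    except ValueError:
                        pass
            continue
        if stripped.upper() == "END":
            break
        if i + 3 >= len(lines):
            raise MechanismParseError("truncated thermo card", i + 1)
        header = lines[i]
        name = header[:18].split()[0]
        try:
            T_low = float(header[45:55])
            T_high = float(header[55:65])
            T_mid = float(header[65:75])
        except ValueError:
            raise MechanismParseError(
                f"malformed thermo card header for {name!r}", i + 1
            ) from None
        try:
            row2 = _card_floats(lines[i + 1], 5)
            row3 = _card_floats(lines[i + 2], 5)
            row4 = _card_floats(lines[i + 3], 4)
        except ValueError:
            raise MechanismParseError(
                f"malformed coefficient line in thermo card for {name!r}", i + 2
            ) from None
        high = tuple(row2 + row3[:2])
        low = tuple(row3[2:] + row4)
        records.append(Nasa7Record(name, T_low, T_mid, T_high, low, high))
        i += 4
    return records


def write_thermo_cards(records: Sequence[Nasa7Record]) -> str:
    """Serialize records to the fixed-column card format read back by
    :func:`read_thermo_cards`."""

    def fmt(vals: Sequence[float]) -> str:
        return "".join(f"{v: 15.8E}" for v in vals)

    out = ["THERMO"]
    for rec in records:
        # cols 1-18 name, 19-24 date, 25-44 atoms, 45 phase, 46-75 T range
        out.append(
            f"{rec.species_name:<18}{'':26}G{rec.T_low:10.3f}{rec.T_high:10.3f}"
            f"{rec.T_mid:10.3f}    1"
        )
        a = rec.coeffs_high
        b = rec.coeffs_low
        out.append(fmt(a[:5]) + "    2")
        out.append(fmt(list(a[5:7]) + list(b[:3])) + "    3")
        out.append(fmt(b[3:7]) + "    4")
    out.append("END")
    return "\n".join(out) + "\n"
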