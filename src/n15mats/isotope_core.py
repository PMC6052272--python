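"""MIMS signal processing and excess-¹⁵N bookkeeping.

Membrane-inlet mass spectrometry (MIMS) reports dissolved Ar, O₂ and the
three N₂ isotopologues (masses 28, 29, 30) as instrument signals.  This
module turns those signals into concentrations and into the tracer
quantities a ¹⁵N labelling experiment needs:

* drift correction against repeated standards along the run index,
* two-point calibration between an instrument blank and an air-saturated
  seawater standard of known gas content,
* excess ²⁹N₂ / ³⁰N₂ relative to the binomial isotopologue composition of
  atmospheric N₂, and the total excess ¹⁵N
  ``[¹⁵N]ex = [²⁹N₂]ex + 2·[³⁰N₂]ex``,
* a QC gate for the hypobromite conversion of NH₄⁺ to N₂ used to measure
  [¹⁵N]NH₄⁺ (accepted only above 95% conversion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GASES",
    "MIMSReading",
    "CalibrationSet",
    "AirIsotopeRatios",
    "GasConcentrations",
    "ExcessIsotopes",
    "drift_correct",
    "calibrate",
    "excess_n2",
    "total_excess15N",
    "check_conversion_efficiency",
    "read_mims_csv",
]

#: Gas channels every MIMS reading must carry.
GASES = ("Ar", "O2", "N28", "N29", "N30")

#: Natural ¹⁵N atom fraction of atmospheric N₂.
NATURAL_15N_FRACTION = 0.003663


@dataclass(frozen=True)
class MIMSReading:
    """One MIMS measurement: raw (or drift-corrected) per-gas signals."""

    sample_id: str
    run_index: int
    time_h: float
    signals: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [g for g in GASES if g not in self.signals]
        if missing:
            raise ValueError(f"{self.sample_id}: missing gas signals {missing}")
        if self.run_index < 0:
            raise ValueError("run_index must be non-negative")
        object.__setattr__(self, "signals", dict(self.signals))


@dataclass(frozen=True)
class CalibrationSet:
    """Blank and air-saturated standard bracketing the instrument response.

    ``reference_concentrations`` are the dissolved-gas concentrations
    (μmol·L⁻¹) of the air-saturated standard at the stated temperature and
    salinity; they are supplied explicitly rather than computed from a
    solubility function.
    """

    blank: MIMSReading
    air_saturated: MIMSReading
    reference_concentrations: Mapping[str, float]
    temperature_c: float = 4.0
    salinity: float = 0.035

    def __post_init__(self) -> None:
        for g in GASES:
            if self.air_saturated.signals[g] <= self.blank.signals[g]:
                raise ValueError(
                    f"standard signal for {g} not above blank; calibration degenerate"
                )
        object.__setattr__(
            self, "reference_concentrations", dict(self.reference_concentrations)
        )


@dataclass(frozen=True)
class AirIsotopeRatios:
    """Isotopologue ratios of atmospheric N₂ at a given ¹⁵N atom fraction.

    Air N₂ is binomial in ¹⁵N: with atom fraction x, R29 = ²⁹/²⁸ = 2x/(1−x)
    and R30 = ³⁰/²⁸ = x²/(1−x)².
    """

    atom_fraction_15N: float = NATURAL_15N_FRACTION
    r29: float = field(init=False)
    r30: float = field(init=False)

    def __post_init__(self) -> None:
        x = self.atom_fraction_15N
        if not 0.0 < x < 1.0:
            raise ValueError("atom fraction must be in (0, 1)")
        object.__setattr__(self, "r29", 2 * x / (1 - x))
        object.__setattr__(self, "r30", (x / (1 - x)) ** 2)


@dataclass(frozen=True)
class GasConcentrations:
    """Calibrated dissolved-gas concentrations in μmol·L⁻¹.

    Negative calibrated values (blank over-subtraction) are clipped to zero
    and flagged via ``clipped_gases``.
    """

    concentrations: Mapping[str, float]
    clipped_gases: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", dict(self.concentrations))

    def __getitem__(self, gas: str) -> float:
        return self.concentrations[gas]


@dataclass(frozen=True)
class ExcessIsotopes:
    """Excess ²⁹N₂/³⁰N₂ above air composition and the total excess ¹⁵N."""

    excess29: float
    excess30: float

    @property
    def total_excess15N(self) -> float:
        return total_excess15N(self)


def drift_correct(
    readings: Sequence[MIMSReading],
    standards: Sequence[MIMSReading],
) -> List[MIMSReading]:
    """Remove instrument drift using repeated standards along the run.

    For each gas, the standard signal is interpolated linearly in run index
    between bracketing standard measurements (constant extrapolation beyond
    the first/last standard); each sample signal is divided by the
    interpolated standard and rescaled to the first standard's signal, so a
    drift-free run is returned unchanged.
    """
    if not standards:
        raise ValueError("at least one standard measurement required")
    std_sorted = sorted(standards, key=lambda r: r.run_index)
    idx = np.array([r.run_index for r in std_sorted], dtype=float)
    out: List[MIMSReading] = []
    per_gas: Dict[str, np.ndarray] = {}
    for g in GASES:
        sig = np.array([r.signals[g] for r in std_sorted], dtype=float)
        if np.any(sig <= 0):
            raise ValueError(f"zero/negative standard signal for {g}")
        per_gas[g] = sig
    for r in readings:
        corrected = {}
        for g in GASES:
            interp = float(np.interp(r.run_index, idx, per_gas[g]))
            corrected[g] = r.signals[g] / interp * per_gas[g][0]
        out.append(replace(r, signals=corrected))
    return out


def calibrate(reading: MIMSReading, cal: CalibrationSet) -> GasConcentrations:
    """Two-point (blank / air-saturated standard) calibration of one reading."""
    conc: Dict[str, float] = {}
    clipped: List[str] = []
    for g in GASES:
        blank = cal.blank.signals[g]
        std = cal.air_saturated.signals[g]
        ref = cal.reference_concentrations[g]
        value = (reading.signals[g] - blank) * ref / (std - blank)
        if value < 0:
            clipped.append(g)
            value = 0.0
        conc[g] = value
    return GasConcentrations(conc, clipped_gases=tuple(clipped))


def excess_n2(conc: GasConcentrations, ratios: AirIsotopeRatios) -> ExcessIsotopes:
    """Excess ²⁹N₂ and ³⁰N₂ relative to air composition.

    The measured ²⁸N₂ pins the air-derived background: any ²⁹N₂ above
    ``R29·[²⁸N₂]`` (and ³⁰N₂ above ``R30·[²⁸N₂]``) is tracer-derived.
    Negative excesses from measurement noise are propagated, not clipped.
    """
    for g in ("N28", "N29", "N30"):
        if g not in conc.concentrations:
            raise ValueError(f"missing isotopologue {g}")
    c28 = conc["N28"]
    if c28 <= 0:
        raise ValueError("non-positive [28N2]; excess undefined")
    return ExcessIsotopes(
        excess29=conc["N29"] - ratios.r29 * c28,
        excess30=conc["N30"] - ratios.r30 * c28,
    )


def total_excess15N(e: ExcessIsotopes) -> float:
    """Total excess ¹⁵N: each ²⁹N₂ carries one ¹⁵N atom, each ³⁰N₂ two."""
    return e.excess29 + 2.0 * e.excess30


def check_conversion_efficiency(measured_fraction: float) -> bool:
    """QC gate for hypobromite conversion of NH₄⁺ to N₂: pass iff > 95%."""
    if not 0.0 <= measured_fraction <= 1.0 or math.isnan(measured_fraction):
        raise ValueError("conversion fraction must lie in [0, 1]")
    return measured_fraction > 0.95


_CSV_COLUMNS = {
    "sample_id": "sample_id",
    "run_index": "run_index",
    "time_h": "time_h",
    "sig_Ar": "Ar",
    "sig_O2": "O2",
    "sig_28N2": "N28",
    "sig_29N2": "N29",
    "sig_30N2": "N30",
}


def read_mims_csv(path) -> List[MIMSReading]:
    """Read a MIMS export CSV into readings, ordered by run index."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"MIMS CSV missing columns: {sorted(missing)}")
    readings = [
        MIMSReading(
            sample_id=str(row["sample_id"]),
            run_index=int(row["run_index"]),
            time_h=float(row["time_h"]),
            signals={
                gas: float(row[col])
                for col, gas in _CSV_COLUMNS.items()
                if col.startswith("sig_")
            },
        )
        for _, row in df.iterrows()
    ]
    return sorted(readings, key=lambda r: r.run_index)
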