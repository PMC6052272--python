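"""Argon-based correction for gas leakage out of incubation syringes.

Polyethylene syringes are not perfectly gas tight: over a day-long
incubation, dissolved gases exchange across the wall toward an apparent
saturation.  Argon, which is biologically inert, tracks this exchange — a
steady argon rise signals gas influx, and the same process drains
tracer-derived excess ¹⁵N-N₂ out of the syringe.  The correction rescales
the cumulative excess ¹⁵N at each time point by

    factor_i = ([Ar]app − [Ar]min) / ([Ar]app − [Ar]i)

where [Ar]i is the argon concentration at that time point, [Ar]min the run
minimum, and [Ar]app the apparent saturation the leak drives argon toward.
[Ar]app is estimated from the data as the highest value whose correction
still compensates the worst observed ¹⁵N loss over a designated low-activity
window (by default the post-destruction tail of each series, where filament
activity has been stopped and any decline must be leak).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Sample",
    "IncubationSeries",
    "ArCorrection",
    "ArAppEstimate",
    "ar_correction_factor",
    "apply_correction",
    "estimate_ar_app",
]

PHASES = ("intact", "destroyed")


@dataclass(frozen=True)
class Sample:
    """One subsample of an incubation: time, phase and measured state."""

    time_h: float
    phase: str
    ar_conc: float  # μmol Ar L^-1
    excess15n: float  # μmol 15N L^-1 (may be negative from noise)
    volume_l: float
    protein_ug: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.volume_l <= 0 or self.protein_ug <= 0:
            raise ValueError("volume and protein must be positive")


@dataclass(frozen=True)
class IncubationSeries:
    """Ordered subsamples of one syringe incubation.

    The series spans the two experimental phases: ``intact`` (whole mat,
    filaments present) followed by ``destroyed`` (filaments mechanically
    destroyed, epibionts only).  Exactly one phase transition is required.
    """

    series_id: str
    samples: Tuple[Sample, ...]
    mat: str = ""
    site: str = ""
    treatment: str = "SW"
    analyte: str = "N2"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        if len(samples) < 2:
            raise ValueError(f"{self.series_id}: need at least two samples")
        times = [s.time_h for s in samples]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"{self.series_id}: times must strictly increase")
        phases = [s.phase for s in samples]
        transitions = sum(p1 != p2 for p1, p2 in zip(phases, phases[1:]))
        if transitions != 1 or phases[0] != "intact":
            raise ValueError(
                f"{self.series_id}: expected exactly one intact->destroyed transition"
            )
        for phase in PHASES:
            vols = [s.volume_l for s in samples if s.phase == phase]
            if any(v1 < v2 - 1e-12 for v1, v2 in zip(vols, vols[1:])):
                raise ValueError(
                    f"{self.series_id}: volumes must be non-increasing within a phase"
                )
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def destruction_index(self) -> int:
        """Index of the first post-destruction sample."""
        for i, s in enumerate(self.samples):
            if s.phase == "destroyed":
                return i
        raise AssertionError("unreachable: invariant guarantees a transition")

    @property
    def ar_min(self) -> float:
        """Minimum argon measured during this set of samples."""
        return min(s.ar_conc for s in self.samples)

    @property
    def ar_max(self) -> float:
        return max(s.ar_conc for s in self.samples)

    def phase_samples(self, phase: str) -> Tuple[Sample, ...]:
        return tuple(s for s in self.samples if s.phase == phase)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "series_id": self.series_id,
                "time_h": [s.time_h for s in self.samples],
                "phase": [s.phase for s in self.samples],
                "ar_um": [s.ar_conc for s in self.samples],
                "excess15n_um": [s.excess15n for s in self.samples],
                "volume_l": [s.volume_l for s in self.samples],
                "protein_ug": [s.protein_ug for s in self.samples],
            }
        )


@dataclass(frozen=True)
class ArCorrection:
    """Record of an applied argon correction."""

    ar_app: float
    ar_min: float
    factors: Tuple[float, ...]
    flagged_below_min: Tuple[int, ...] = ()


def ar_correction_factor(ar_app: float, ar_min: float, ar_i: float) -> float:
    """The per-sample rescaling ``([Ar]app − [Ar]min)/([Ar]app − [Ar]i)``.

    Equals 1 when argon is at its run minimum and grows as argon approaches
    the apparent saturation; values below 1 (argon below the run minimum)
    are returned as-is, never clamped.
    """
    if ar_i >= ar_app:
        raise ValueError(
            f"argon at/above apparent saturation ({ar_i} >= {ar_app}); "
            "correction undefined"
        )
    if ar_min >= ar_app:
        raise ValueError("ar_min must lie below ar_app")
    return (ar_app - ar_min) / (ar_app - ar_i)


def apply_correction(
    series: IncubationSeries, ar_app: float
) -> Tuple[IncubationSeries, ArCorrection]:
    """Rescale every excess ¹⁵N value in the series by its argon factor.

    ``ar_min`` is the minimum argon of this series (one syringe's set of
    samples).  Returns the corrected series plus a record of the factors
    used; samples whose argon lies below the run minimum would yield factors
    < 1 and are flagged (impossible here since ar_min is the run minimum,
    but kept for externally supplied minima via :class:`ArCorrection`).
    """
    ar_min = series.ar_min
    factors = []
    flagged = []
    corrected = []
    for i, s in enumerate(series.samples):
        f = ar_correction_factor(ar_app, ar_min, s.ar_conc)
        if f < 1.0 - 1e-12:
            flagged.append(i)
        factors.append(f)
        corrected.append(replace(s, excess15n=s.excess15n * f))
    new_series = replace(
        series,
        samples=tuple(corrected),
        metadata={**series.metadata, "ar_app": ar_app, "ar_min": ar_min},
    )
    return new_series, ArCorrection(
        ar_app=ar_app,
        ar_min=ar_min,
        factors=tuple(factors),
        flagged_below_min=tuple(flagged),
    )


@dataclass(frozen=True)
class ArAppEstimate:
    """Result of estimating the apparent argon saturation from data."""

    ar_app: Optional[float]  # None: flat argon / no 15N loss, no correction
    no_correction: bool
    diagnostics: dict = field(default_factory=dict)


def _window_loss(series: IncubationSeries, ar_app: float, window: slice) -> float:
    """Decline of corrected excess ¹⁵N from its window maximum to the final
    window point (positive = net loss)."""
    corrected, _ = apply_correction(series, ar_app)
    values = [s.excess15n for s in corrected.samples[window]]
    if len(values) < 2:
        return 0.0
    return max(values) - values[-1]


def _collection_loss(
    collection: Sequence[IncubationSeries], ar_app: float,
    windows: Sequence[slice],
) -> float:
    return max(
        _window_loss(series, ar_app, window)
        for series, window in zip(collection, windows)
    )


def estimate_ar_app(
    collection: Sequence[IncubationSeries],
    tolerance: float = 0.0,
    windows: Optional[Sequence[slice]] = None,
    upper_bound_factor: float = 10.0,
    grid_points: int = 200,
    refine_tol: float = 1e-6,
) -> ArAppEstimate:
    """Estimate [Ar]app as the highest value compensating the worst ¹⁵N loss.

    A candidate passes when, after correction, no series' corrected excess
    ¹⁵N declines from its window maximum to the window's final point by more
    than ``tolerance`` (μM ¹⁵N).  The window defaults to each series'
    post-destruction tail, where production has been stopped and any decline
    is leak.  The passing set is searched from above on a grid over
    (max observed argon, upper_bound_factor × max observed argon] and the
    boundary refined by bisection.

    Returns a no-correction sentinel when even the upper bound (a correction
    so weak it is effectively none) leaves every series within tolerance.
    """
    if not collection:
        raise ValueError("empty collection")
    if windows is None:
        windows = [slice(s.destruction_index, len(s)) for s in collection]
    ar_max = max(s.ar_max for s in collection)
    if ar_max <= 0:
        raise ValueError("non-positive argon concentrations")
    upper = upper_bound_factor * ar_max

    if _collection_loss(collection, upper, windows) <= tolerance:
        return ArAppEstimate(
            ar_app=None,
            no_correction=True,
            diagnostics={"upper_bound": upper, "reason": "no 15N loss to compensate"},
        )

    # Loss after correction grows with ar_app (weaker correction), so the
    # passing region is an interval just above ar_max.  Grid scan from above
    # for the first passing candidate, then bisect the pass/fail boundary.
    grid = np.linspace(upper, ar_max, grid_points, endpoint=False)
    lo = None  # highest passing
    hi = upper  # lowest failing seen
    for cand in grid:
        if _collection_loss(collection, float(cand), windows) <= tolerance:
            lo = float(cand)
            break
        hi = float(cand)
    if lo is None:
        raise ValueError(
            "no apparent argon saturation below "
            f"{upper:.3g} μM compensates the observed 15N loss; "
            f"max observed argon {ar_max:.3g} μM — check the activity window"
        )
    while hi - lo > refine_tol:
        mid = 0.5 * (lo + hi)
        if _collection_loss(collection, mid, windows) <= tolerance:
            lo = mid
        else:
            hi = mid
    return ArAppEstimate(
        ar_app=lo,
        no_correction=False,
        diagnostics={
            "upper_bound": upper,
            "max_observed_ar": ar_max,
            "tolerance": tolerance,
            "residual_loss": _collection_loss(collection, lo, windows),
        },
    )
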