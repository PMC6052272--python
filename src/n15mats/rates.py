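"""Protein-normalized production rates and FLSB/epibiont decomposition.

The experimental design measures each syringe twice: first with the mat
intact (whole-mat activity), then after the filaments are mechanically
destroyed (epibiont activity only).  Concentration changes between
subsamples are converted to protein-normalized increments

    Δ¹⁵N = ([¹⁵N]_ti − [¹⁵N]_ti−1) × 1000 × V / P    (nmol ¹⁵N · μg⁻¹)

accumulated into a cumulative series, and each phase's production rate is
the OLS slope of cumulative Δ¹⁵N versus time (standard error of the slope as
uncertainty), reported in pmol N · (μg protein)⁻¹ · h⁻¹.  The time point
immediately after filament destruction is excluded from the epibiont fit
(carry-over / incomplete mixing).  The filament-only (FLSB) rate is the
whole-mat rate minus the epibiont rate, clipped at zero, with the standard
errors combined in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .leak_correction import IncubationSeries

__all__ = [
    "NormalizedIncrement",
    "PhaseRate",
    "RateDecomposition",
    "normalize_increment",
    "cumulative_series",
    "fit_phase_rate",
    "series_rates",
    "decompose",
    "rate_table",
]


@dataclass(frozen=True)
class NormalizedIncrement:
    """Volume- and protein-normalized ¹⁵N change over one sampling interval."""

    t_prev: float
    t_curr: float
    delta15n: float  # nmol 15N per μg protein
    volume_l: float
    protein_ug: float

    def __post_init__(self) -> None:
        if not self.t_prev < self.t_curr:
            raise ValueError("interval must be ordered")
        if not math.isfinite(self.delta15n):
            raise ValueError("delta15N must be finite")


@dataclass(frozen=True)
class PhaseRate:
    """OLS slope (and its SE) of cumulative Δ¹⁵N vs time for one phase.

    Units: pmol N · (μg protein)⁻¹ · h⁻¹.  ``se`` is NaN when fewer than
    three points were available (slope defined, uncertainty not).
    """

    phase: str  # "whole_mat" or "epibionts"
    slope: float
    se: float
    n_points: int

    def __post_init__(self) -> None:
        if self.phase not in ("whole_mat", "epibionts"):
            raise ValueError("phase must be whole_mat or epibionts")
        if self.n_points >= 3 and not (self.se >= 0 or math.isnan(self.se)):
            raise ValueError("se must be non-negative")


@dataclass(frozen=True)
class RateDecomposition:
    """Whole-mat, epibiont and derived FLSB rate for one mat piece/analyte."""

    whole_mat: PhaseRate
    epibionts: PhaseRate
    flsb_rate: float
    flsb_se: float
    clipped: bool
    mat: str = ""
    site: str = ""
    treatment: str = ""
    analyte: str = ""
    protein_conc_ug_per_l: float = float("nan")


def normalize_increment(
    c_prev: float, c_curr: float, volume_l: float, protein_ug: float,
    t_prev: float = 0.0, t_curr: float = 1.0,
) -> NormalizedIncrement:
    """Normalize a concentration change (μM ¹⁵N) by volume and protein.

    The ×1000 converts μmol to nmol, so the result is nmol ¹⁵N per μg
    protein over the interval.
    """
    if volume_l <= 0:
        raise ValueError("volume must be positive")
    if protein_ug <= 0:
        raise ValueError("protein must be positive")
    return NormalizedIncrement(
        t_prev=t_prev,
        t_curr=t_curr,
        delta15n=(c_curr - c_prev) * 1000.0 * volume_l / protein_ug,
        volume_l=volume_l,
        protein_ug=protein_ug,
    )


def cumulative_series(
    increments: Sequence[NormalizedIncrement],
) -> Tuple[np.ndarray, np.ndarray]:
    """Running sum of increments, anchored at 0 at the first time point.

    Intervals must be contiguous: each increment starts where the previous
    one ended.
    """
    if not increments:
        raise ValueError("no increments")
    for a, b in zip(increments, increments[1:]):
        if not math.isclose(a.t_curr, b.t_prev, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                f"intervals not contiguous: {a.t_curr} -> {b.t_prev}"
            )
    times = np.array(
        [increments[0].t_prev] + [inc.t_curr for inc in increments], dtype=float
    )
    cumulative = np.concatenate(
        [[0.0], np.cumsum([inc.delta15n for inc in increments])]
    )
    return times, cumulative


def _ols_slope(t: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Unweighted OLS slope and its standard error (free intercept)."""
    res = stats.linregress(t, y)
    return float(res.slope), float(res.stderr)


def fit_phase_rate(
    times: np.ndarray,
    cumulative: np.ndarray,
    phase: str,
    destruction_index: Optional[int] = None,
    exclude_first_post_destruction: bool = True,
) -> PhaseRate:
    """Fit one phase's production rate from the cumulative series.

    ``times``/``cumulative`` are the points belonging to the phase (for the
    epibiont phase, including the point immediately after destruction, which
    is dropped here when the exclusion rule is on — it is typically
    disproportionately high from carry-over).  ``destruction_index`` marks
    that first post-destruction point within the arrays (default 0 for the
    epibiont phase).  Slope/SE are converted from nmol to pmol (×1000).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(cumulative, dtype=float)
    if phase == "epibionts" and exclude_first_post_destruction:
        drop = 0 if destruction_index is None else destruction_index
        t = np.delete(t, drop)
        y = np.delete(y, drop)
    if len(t) < 2:
        raise ValueError(f"fewer than 2 usable points for {phase} fit")
    slope, se = _ols_slope(t, y)
    if len(t) < 3:
        se = float("nan")
    return PhaseRate(phase=phase, slope=slope * 1000.0, se=se * 1000.0, n_points=len(t))


def series_rates(
    series: IncubationSeries,
    exclude_first_post_destruction: bool = True,
    protein_mode: str = "total",
) -> RateDecomposition:
    """Full per-series pipeline: increments → cumulative → two fits → FLSB.

    Uses each interval's ending sample for V and P (the volume present
    during the interval, and the protein in the syringe when it was drawn).
    ``protein_mode`` fixes how the per-sample protein field is read:
    ``"total"`` (μg in the incubation; the default) or
    ``"concentration_times_volume"`` (μg·L⁻¹, multiplied by the sample's
    volume to get micrograms).  The whole-mat fit uses all intact-phase
    points; the epibiont fit uses the post-destruction points minus the
    first.
    """
    if protein_mode not in ("total", "concentration_times_volume"):
        raise ValueError(f"unknown protein_mode {protein_mode!r}")
    samples = series.samples

    def protein_ug(s) -> float:
        if protein_mode == "concentration_times_volume":
            return s.protein_ug * s.volume_l
        return s.protein_ug

    increments = [
        normalize_increment(
            prev.excess15n, curr.excess15n, curr.volume_l, protein_ug(curr),
            t_prev=prev.time_h, t_curr=curr.time_h,
        )
        for prev, curr in zip(samples, samples[1:])
    ]
    times, cumulative = cumulative_series(increments)
    d = series.destruction_index
    whole = fit_phase_rate(times[:d], cumulative[:d], "whole_mat")
    epi = fit_phase_rate(
        times[d:], cumulative[d:], "epibionts",
        destruction_index=0,
        exclude_first_post_destruction=exclude_first_post_destruction,
    )
    protein_conc = (
        samples[0].protein_ug
        if protein_mode == "concentration_times_volume"
        else samples[0].protein_ug / samples[0].volume_l
    )
    return decompose(
        whole, epi,
        mat=series.mat, site=series.site, treatment=series.treatment,
        analyte=series.analyte, protein_conc_ug_per_l=protein_conc,
    )


def decompose(
    whole: PhaseRate,
    epi: PhaseRate,
    **labels,
) -> RateDecomposition:
    """FLSB rate = whole-mat − epibionts, clipped at zero, SEs in quadrature.

    Clipping encodes that the filament contribution cannot be negative; the
    quadrature SE is computed from the unclipped difference and is left
    untouched by the clip.
    """
    if whole.phase != "whole_mat" or epi.phase != "epibionts":
        raise ValueError("decompose expects a whole_mat and an epibionts rate")
    raw = whole.slope - epi.slope
    se_w = 0.0 if math.isnan(whole.se) else whole.se
    se_e = 0.0 if math.isnan(epi.se) else epi.se
    return RateDecomposition(
        whole_mat=whole,
        epibionts=epi,
        flsb_rate=max(raw, 0.0),
        flsb_se=math.hypot(se_w, se_e),
        clipped=raw < 0,
        **labels,
    )


def _fmt(value: float, se: float) -> str:
    return f"{round(value):,.0f} ± {round(se):,.0f}"


def rate_table(decompositions: Iterable[RateDecomposition]) -> pd.DataFrame:
    """Report table: one row per mat piece and analyte, integer pmol rendering.

    Rounding to integer pmol happens here, after subtraction and quadrature,
    so derived cells stay arithmetically consistent with their precursors at
    full precision.
    """
    rows: List[dict] = []
    for d in decompositions:
        rows.append(
            {
                "mat": d.mat,
                "site": d.site,
                "treatment": d.treatment,
                "analyte": d.analyte,
                "protein_ug_per_l": d.protein_conc_ug_per_l,
                "whole_mat": _fmt(d.whole_mat.slope, d.whole_mat.se),
                "epibionts": _fmt(d.epibionts.slope, d.epibionts.se),
                "flsb": _fmt(d.flsb_rate, d.flsb_se),
                "clipped": d.clipped,
            }
        )
    columns = [
        "mat", "site", "treatment", "analyte", "protein_ug_per_l",
        "whole_mat", "epibionts", "flsb", "clipped",
    ]
    return pd.DataFrame(rows, columns=columns)
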