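"""Forward simulator for ¹⁵N-tracer syringe incubations of sulfur-mat pieces.

The simulated experiment mirrors the two-phase syringe design: a mat piece
pre-loaded with ¹⁵NO₃⁻ incubates in a 60-ml syringe; four ~10.5-ml
subsamples are drawn while the filaments are intact; at ~20 h the filaments
are mechanically destroyed, the medium is replaced, and four more
subsamples follow.  Between samplings every dissolved gas follows a
first-order exchange across the syringe wall,

    dC/dt = production/V − k·(C − C_eq),

with C_eq the apparent saturation for argon and the air-equilibrium value
for N₂ isotopologues (so tracer-derived excess ¹⁵N decays toward zero at
the same rate argon relaxes toward saturation — the limit in which the
argon-based correction is exact).  NH₄⁺ is non-volatile and does not leak.
Filament (FLSB) production stops (or is scaled down) at destruction;
epibiont production continues unchanged.  Subsampling removes volume, not
concentration.  Gaussian measurement noise is added per quantity, and all
randomness flows from a single seed.

Simulated production rates are rates of ¹⁵N *product* formation
(pmol ¹⁵N · μg protein⁻¹ · h⁻¹), matching what the measurement pipeline can
recover; the ¹⁵N label fraction F of the reducible NO₃⁻ pool only controls
how ¹⁵N-N₂ splits into ²⁹N₂ and ³⁰N₂ by random (binomial) isotope pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .leak_correction import IncubationSeries, Sample

__all__ = [
    "IncubationScenario",
    "SimulatedTruth",
    "pair_isotopologues",
    "simulate_incubation",
    "paperlike_campaign",
]

#: Default subsampling schedule (h): four intact-phase and four
#: post-destruction draws, destruction at ~20 h.
DEFAULT_SAMPLING_TIMES = (0.0, 3.0, 8.0, 19.0, 21.0, 23.0, 28.5, 32.0)


@dataclass(frozen=True)
class IncubationScenario:
    """Complete parameterisation of one simulated syringe incubation.

    Rates are ¹⁵N-product formation rates in pmol ¹⁵N·μg⁻¹·h⁻¹ split by
    organism (filaments vs epibionts) and pathway (denitrification → N₂,
    DNRA → NH₄⁺).  ``post_destruction_rate_factor`` scales the *filament*
    rates after destruction (0 = destruction stops them completely);
    epibiont rates always continue unchanged.
    """

    seed: int = 0
    label_fraction_f: float = 0.5
    flsb_denitrification_rate: float = 600.0
    flsb_dnra_rate: float = 200.0
    epibiont_denitrification_rate: float = 50.0
    epibiont_dnra_rate: float = 20.0
    protein_conc_ug_per_l: float = 10.0
    initial_volume_l: float = 0.060
    subsample_volume_l: float = 0.0105
    sampling_times_h: Tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    destruction_time_h: float = 20.0
    refill_volume_l: float = 0.060
    residual_volume_l: float = 0.005
    leak_constant_per_h: float = 0.01
    ar_saturation_um: float = 9.4
    initial_ar_um: float = 8.8
    noise_sd: Dict[str, float] = field(
        default_factory=lambda: {"ar": 0.0, "excess15n": 0.0}
    )
    conversion_efficiency: float = 0.98
    post_destruction_rate_factor: Dict[str, float] = field(
        default_factory=lambda: {"denitrification": 0.0, "dnra": 0.0}
    )
    mat: str = "white"
    site: str = "UM"
    treatment: str = "SW"

    def __post_init__(self) -> None:
        if not 0.0 < self.label_fraction_f <= 1.0:
            raise ValueError("label fraction must be in (0, 1]")
        rates = (
            self.flsb_denitrification_rate, self.flsb_dnra_rate,
            self.epibiont_denitrification_rate, self.epibiont_dnra_rate,
        )
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        times = self.sampling_times_h
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("sampling times must strictly increase")
        if not times[0] < self.destruction_time_h < times[-1]:
            raise ValueError("destruction time must fall inside the sampling range")
        if self.initial_ar_um >= self.ar_saturation_um:
            raise ValueError("initial argon must lie below apparent saturation")
        n_intact = sum(t < self.destruction_time_h for t in times)
        min_volume = self.initial_volume_l - n_intact * self.subsample_volume_l
        if min_volume <= 0:
            raise ValueError("subsampling would exhaust the syringe volume")


@dataclass(frozen=True)
class SimulatedTruth:
    """Ground truth behind one simulated incubation (noise-free)."""

    n2_rates: Dict[str, float]  # phase -> pmol 15N·μg⁻¹·h⁻¹
    nh4_rates: Dict[str, float]
    true_flsb_n2_rate: float
    true_flsb_nh4_rate: float
    ar_saturation_um: float
    leak_constant_per_h: float
    noiseless_samples: Dict[str, Tuple[Sample, ...]]


def pair_isotopologues(f: float, n2_amount: float) -> Tuple[float, float, float]:
    """Split an N₂ amount into ²⁸/²⁹/³⁰ by random isotope pairing at label
    fraction ``f``: binomial fractions (1−f)², 2f(1−f), f²."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("label fraction must lie in [0, 1]")
    return (
        (1 - f) ** 2 * n2_amount,
        2 * f * (1 - f) * n2_amount,
        f**2 * n2_amount,
    )


def _relax(c0: float, c_eq: float, prod_per_vol: float, k: float, dt: float) -> float:
    """Advance dC/dt = prod_per_vol − k (C − C_eq) by dt (closed form)."""
    if k == 0.0:
        return c0 + prod_per_vol * dt
    c_star = c_eq + prod_per_vol / k
    return c_star + (c0 - c_star) * math.exp(-k * dt)


def simulate_incubation(
    scenario: IncubationScenario,
) -> Tuple[IncubationSeries, IncubationSeries, SimulatedTruth]:
    """Simulate one incubation; returns (N₂ series, NH₄⁺ series, truth).

    Both series carry the same argon record.  The NH₄⁺ channel reflects the
    hypobromite measurement: the recorded excess ¹⁵N is the true value times
    the conversion efficiency.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    k = sc.leak_constant_per_h
    factor = sc.post_destruction_rate_factor

    def rates_at(phase: str) -> Tuple[float, float]:
        """(n2, nh4) total production rate, pmol 15N·μg⁻¹·h⁻¹."""
        if phase == "intact":
            return (
                sc.flsb_denitrification_rate + sc.epibiont_denitrification_rate,
                sc.flsb_dnra_rate + sc.epibiont_dnra_rate,
            )
        return (
            sc.flsb_denitrification_rate * factor.get("denitrification", 0.0)
            + sc.epibiont_denitrification_rate,
            sc.flsb_dnra_rate * factor.get("dnra", 0.0) + sc.epibiont_dnra_rate,
        )

    times = sc.sampling_times_h
    n_intact = sum(t < sc.destruction_time_h for t in times)

    # Total protein in the syringe (μg).  Phase 1: filaments settle during
    # subsampling, so biomass (and protein) stays in the syringe.  Phase 2:
    # the destroyed mat is homogenised, so each subsample removes protein in
    # proportion to the volume drawn.
    protein = sc.protein_conc_ug_per_l * sc.initial_volume_l

    volume = sc.initial_volume_l
    ar = sc.initial_ar_um
    exc_n2 = 0.0  # μM excess 15N in the N2 pool
    exc_nh4 = 0.0  # μM excess 15N in the NH4+ pool (non-volatile)
    t_now = times[0]
    phase = "intact"

    noiseless_n2: List[Sample] = []
    noiseless_nh4: List[Sample] = []
    noisy_n2: List[Sample] = []
    noisy_nh4: List[Sample] = []

    def record(t: float) -> None:
        sd_ar = sc.noise_sd.get("ar", 0.0)
        sd_ex = sc.noise_sd.get("excess15n", 0.0)
        meas_nh4 = exc_nh4 * sc.conversion_efficiency
        for store, ex in ((noiseless_n2, exc_n2), (noiseless_nh4, meas_nh4)):
            store.append(
                Sample(t, phase, ar, ex, volume, protein)
            )
        ar_noisy = ar + (rng.normal(0.0, sd_ar) if sd_ar > 0 else 0.0)
        for store, ex in ((noisy_n2, exc_n2), (noisy_nh4, meas_nh4)):
            noise = rng.normal(0.0, sd_ex) if sd_ex > 0 else 0.0
            store.append(
                Sample(t, phase, ar_noisy, ex + noise, volume, protein)
            )

    def advance(t_to: float) -> None:
        nonlocal ar, exc_n2, exc_nh4, t_now
        dt = t_to - t_now
        if dt <= 0:
            return
        r_n2, r_nh4 = rates_at(phase)
        # pmol·μg⁻¹·h⁻¹ × μg / L → pmol·L⁻¹·h⁻¹ → ×1e-6 μM·h⁻¹
        p_n2 = r_n2 * protein / volume * 1e-6
        p_nh4 = r_nh4 * protein / volume * 1e-6
        ar = _relax(ar, sc.ar_saturation_um, 0.0, k, dt)
        exc_n2 = _relax(exc_n2, 0.0, p_n2, k, dt)
        exc_nh4 = exc_nh4 + p_nh4 * dt  # non-volatile: no leak
        t_now = t_to

    for i, t in enumerate(times):
        if phase == "intact" and t >= sc.destruction_time_h:
            # Destruction: advance to the destruction time, draw the medium
            # down to the residual volume, destroy filaments, refill with
            # fresh seawater (dilutes gases; argon resets to the fill value).
            advance(sc.destruction_time_h)
            dilution = sc.residual_volume_l / sc.refill_volume_l
            exc_n2 *= dilution
            exc_nh4 *= dilution
            ar = sc.initial_ar_um + (ar - sc.initial_ar_um) * dilution
            volume = sc.refill_volume_l
            phase = "destroyed"
        advance(t)
        record(t)
        volume -= sc.subsample_volume_l
        if phase == "destroyed":
            # Homogenised mat: protein leaves with the subsample.
            protein *= volume / (volume + sc.subsample_volume_l)

    def build(samples: List[Sample], analyte: str) -> IncubationSeries:
        return IncubationSeries(
            series_id=f"{sc.mat}-{sc.site}-{sc.treatment}-{analyte}-seed{sc.seed}",
            samples=tuple(samples),
            mat=sc.mat,
            site=sc.site,
            treatment=sc.treatment,
            analyte=analyte,
            metadata={"seed": sc.seed},
        )

    fac_dn = factor.get("denitrification", 0.0)
    fac_dnra = factor.get("dnra", 0.0)
    truth = SimulatedTruth(
        n2_rates={
            "whole_mat": sc.flsb_denitrification_rate + sc.epibiont_denitrification_rate,
            "epibionts": sc.flsb_denitrification_rate * fac_dn
            + sc.epibiont_denitrification_rate,
        },
        nh4_rates={
            "whole_mat": (sc.flsb_dnra_rate + sc.epibiont_dnra_rate)
            * sc.conversion_efficiency,
            "epibionts": (sc.flsb_dnra_rate * fac_dnra + sc.epibiont_dnra_rate)
            * sc.conversion_efficiency,
        },
        true_flsb_n2_rate=sc.flsb_denitrification_rate * (1 - fac_dn),
        true_flsb_nh4_rate=sc.flsb_dnra_rate * (1 - fac_dnra)
        * sc.conversion_efficiency,
        ar_saturation_um=sc.ar_saturation_um,
        leak_constant_per_h=k,
        noiseless_samples={
            "N2": tuple(noiseless_n2),
            "NH4": tuple(noiseless_nh4),
        },
    )
    return build(noisy_n2, "N2"), build(noisy_nh4, "NH4"), truth


#: Site/treatment layout of one campaign: two sites, three syringes each.
_CAMPAIGN_LAYOUT = (
    ("UM", "SW"), ("UM", "SW"), ("UM", "+HS-"),
    ("CH", "SW"), ("CH", "+HS-"), ("CH", "+DOC"),
)

#: Rate ranges (pmol 15N·μg⁻¹·h⁻¹) bracketing the observed campaign spread.
_TEMPLATES = {
    "white": {
        "flsb_denitrification": (150.0, 1200.0),
        "flsb_dnra": (80.0, 650.0),
        "epibiont_denitrification": (0.0, 200.0),
        "epibiont_dnra": (0.0, 50.0),
    },
    "orange": {
        "flsb_denitrification": (0.0, 0.0),
        "flsb_dnra": (50.0, 950.0),
        "epibiont_denitrification": (0.0, 270.0),
        "epibiont_dnra": (0.0, 25.0),
    },
}

#: Measurement noise (μM) giving slope SEs of the order seen in practice
#: (tens of percent of the rate for typical protein loads).
DEFAULT_NOISE_SD = {"ar": 0.03, "excess15n": 0.004}


def paperlike_campaign(
    template: str,
    seed: int,
    noise_sd: Optional[Dict[str, float]] = None,
) -> List[IncubationScenario]:
    """Six scenarios emulating one mat type's campaign (two sites × three
    treatments).

    ``white`` mats run both pathways with denitrification dominant in every
    syringe; ``orange`` mats run filament DNRA only (filament
    denitrification zero, any N₂ production is epibiont).
    """
    if template not in _TEMPLATES:
        raise ValueError(f"template must be one of {sorted(_TEMPLATES)}")
    ranges = _TEMPLATES[template]
    rng = np.random.default_rng(seed)
    noise = dict(DEFAULT_NOISE_SD if noise_sd is None else noise_sd)
    scenarios: List[IncubationScenario] = []
    for i, (site, treatment) in enumerate(_CAMPAIGN_LAYOUT):
        flsb_dn = float(rng.uniform(*ranges["flsb_denitrification"]))
        flsb_dnra = float(rng.uniform(*ranges["flsb_dnra"]))
        if template == "white" and flsb_dn <= flsb_dnra:
            # Denitrification dominates in every white-mat syringe.
            flsb_dn, flsb_dnra = max(flsb_dn, flsb_dnra) * 1.5, min(flsb_dn, flsb_dnra)
        scenarios.append(
            IncubationScenario(
                seed=int(rng.integers(0, 2**31 - 1)),
                label_fraction_f=0.5,
                flsb_denitrification_rate=flsb_dn,
                flsb_dnra_rate=flsb_dnra,
                epibiont_denitrification_rate=float(
                    rng.uniform(*ranges["epibiont_denitrification"])
                ),
                epibiont_dnra_rate=float(rng.uniform(*ranges["epibiont_dnra"])),
                protein_conc_ug_per_l=float(rng.uniform(1.2, 23.0)),
                noise_sd=noise,
                mat=template,
                site=site,
                treatment=treatment,
            )
        )
    return scenarios
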