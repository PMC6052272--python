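# Methods

## The measurement model

A syringe incubation is a closed, imperfectly gas-tight volume containing a
mat piece whose filaments were pre-loaded with ¹⁵NO₃⁻. Tracer reduced to N₂
appears as excess ²⁹N₂/³⁰N₂ above the binomial air composition; tracer
reduced to NH₄⁺ is measured after chemical (hypobromite) conversion to N₂.
The analysis chain is

    MIMS signals → drift correction → two-point calibration →
    excess isotopologues → argon leak correction →
    volume/protein normalization → per-phase OLS slopes →
    whole-mat − epibiont decomposition.

Each stage is a pure function with an explicit contract; the composite is
deterministic given a config and seed.

### Excess isotopologues

Air N₂ is treated as exactly binomial in ¹⁵N at atom fraction
x = 0.003663 (the standard atmospheric value; configurable), giving
R29 = 2x/(1−x) ≈ 7.347×10⁻³ and R30 = (x/(1−x))² ≈ 1.352×10⁻⁵. Excess is
the plain subtraction `[²⁹N₂] − R29·[²⁸N₂]` (and likewise for mass 30);
total excess ¹⁵N counts mass-30 molecules twice. Negative excesses from
noise are propagated, never clipped, so downstream regression statistics
stay unbiased. Variants that additionally correct for O₂ interference or
use N₂/Ar ratios exist in the MIMS literature; the subtraction used here
is the minimal form and is isolated behind `excess_n2` so a different
convention can be swapped in.

Drift correction is per-gas multiplicative: the standard signal is
interpolated linearly in run index between repeated standards (constant
extrapolation at the ends) and each sample is rescaled to the first
standard. This is the simplest monotone scheme; it is exact for linear
drift and is deliberately kept behind a single operation.

Calibration is two-point (instrument blank, air-saturated seawater of known
gas content). Reference concentrations are supplied explicitly in config
rather than computed from temperature/salinity internally, so no particular
solubility formulation is baked in; a helper can fill them from published
functions if desired.

### Argon leak correction

The wall leak is modeled (in the simulator, and implicitly by the
correction) as first-order relaxation toward an apparent saturation A:
`dC/dt = production/V − k(C − C_eq)`, with C_eq = A for argon and the
air-equilibrium value for N₂ isotopologues, so excess ¹⁵N decays toward
zero at the same relative rate argon relaxes toward A. Under that equal
relative-equilibration assumption the rescaling

    f_i = (A − [Ar]min) / (A − [Ar]i)

is exact: the corrected excess is constant whenever production is zero
(proof: with [Ar]i = A − (A − Ar₀)e^(−kt) and excess E ∝ e^(−kt), the
product E·f is time-free). The tests exploit this limit. When production
is ongoing the corrected cumulative series is convex rather than linear,
so corrected intact-phase slopes carry a modest upward bias of order
k·t̄ — the correction is designed to recover plateaus, not to deconvolve
active-phase kinetics.

[Ar]min is the minimum argon of one syringe's sample set, per series, not
global: each syringe leaks on its own schedule. [Ar]app estimation searches
for the highest candidate (grid over (max Ar, 10× max Ar], bisection
refinement) such that no series' corrected excess ¹⁵N declines, from its
window maximum to the window's last point, by more than a tolerance. The
window defaults to the post-destruction tail. Both joint (one value for a
collection; the default) and per-series estimation are provided. Three
degenerate outcomes are explicit: a flat collection returns a no-correction
sentinel; an infinite tolerance likewise degenerates to the sentinel (any
value compensates); and a ¹⁵N loss that no candidate can compensate — a
loss not correlated with the argon record — raises with diagnostics. The
composite pipeline treats that last case as "correction inapplicable" and
proceeds uncorrected, recording the reason, since forcing an argon
correction onto non-argon-shaped loss would corrupt the series.

Factors below 1 (argon below the run minimum later in the run) are
mathematically possible with an externally supplied minimum; they are
flagged but never clamped, preserving the formula as written.

### Rates and decomposition

The normalization `Δ¹⁵N = ΔC × 1000 × V/P` uses, for each interval, the
volume present during that interval and the protein in the syringe when the
subsample was drawn (equivalently: the later sample's bookkeeping values).
During the intact phase filaments settle before each draw, so biomass and
total protein stay constant while V shrinks by 10.5 ml per subsample from
60 ml. After destruction the suspension is homogenized, so each draw also
removes protein proportionally; normalizing per μg absorbs that loss.
Because published protein values are concentrations (μg L⁻¹) while the
formula wants micrograms, both conventions are supported via
`protein_mode` ∈ {total, concentration_times_volume}; neither is asserted
as canonical.

Rates are unweighted OLS slopes of cumulative Δ¹⁵N versus time with a free
intercept (the series is anchored at zero but the intercept is not
constrained), uncertainty the standard error of the slope. The first
post-destruction point is excluded from the epibiont fit: it is typically
inflated by carry-over/incomplete mixing, and because OLS slopes are
translation-invariant, the bogus increment across the destruction boundary
only shifts the intercept. The whole-mat fit uses all intact-phase points
including t = 0. The filament rate is the whole-mat slope minus the
epibiont slope, clipped at zero (a negative filament contribution is not
physical) with a `clipped` flag; its SE is the quadrature sum and is not
altered by the clip. Rounding to integer pmol happens only at table
rendering, after subtraction and quadrature.

### Stoichiometry

Oxidation states use the fixed convention O = −2, H = +1; the single
remaining element is solved from the charge (peroxide-like species are
rejected). A couple's electron count is (state change) × (atoms in the
reactant): 5 e⁻ accepted per NO₃⁻ for reduction to N₂, 8 for reduction to
NH₄⁺, 2 donated per HS⁻ oxidized to S⁰, 8 to SO₄²⁻. Balancing normalizes
to 1 mol donor, scales the acceptor to conserve electrons, then closes O
with H₂O and H with H⁺; charge closure is then automatic and is
re-verified, along with every element, in exact `fractions.Fraction`
arithmetic (floats appear only when rendering). Closure species appearing
on both sides (possible when the acceptor product is itself H₂O) are
net-cancelled so H₂O and H⁺ each occur on at most one side.

One sign convention needs care: for the HS⁻ → S⁰ couples, both DNRA and
denitrification *consume* protons (1.5 H⁺ per 0.25 NO₃⁻, i.e. magnitude 6;
and 1.4 per 0.4, magnitude 3.5), which is why sulfide-fuelled nitrate
reduction drives a pH maximum deep in a mat. Discussions of these couples
sometimes phrase the same magnitudes as protons "produced";
`protons_per_nitrate` therefore returns both the signed value (positive =
consumed on the reactant side) and the magnitude, and comparisons should
use the magnitude. Note also that closing the aerobic couple
S⁰ + 1.5 O₂ + H₂O → SO₄²⁻ + 2 H⁺ yields 2 H⁺ — the only coefficient set
consistent with H and charge conservation.

## The simulator: what it emulates and what it does not

Defaults encode one concrete experimental design: 60 ml initial volume,
10.5 ml subsamples at 0, 3, 8 and 19 h (intact) and 21, 23, 28.5 and 32 h
(post-destruction), destruction at 20 h with draw-down to 5 ml and refill
to 60 ml with fresh N₂-purged seawater (which dilutes dissolved gases and
resets argon toward the fill value), apparent argon saturation 9.4 μM with
the N₂-purged fill starting at 8.8 μM, and a leak constant of 0.01 h⁻¹ —
chosen so argon rises steadily by a few tenths of a μM over a run and the
late-run correction factors sit in the ~1.2–1.5 range, the regime the
correction formula is meant for. The ¹⁵N label fraction of the reducible
pool defaults to 0.5 (pre-loading mixes labeled nitrate with unlabeled
stores; the value only controls the 29/30 split, not totals). Measurement
noise defaults (0.03 μM on argon, 0.004 μM on excess ¹⁵N) put fitted slope
SEs in the tens-of-pmol range for realistic protein loads of 1.2–23
μg L⁻¹, i.e. typically ~5–40 % relative — the order observed in practice.
Hypobromite conversion efficiency (default 0.98) scales the NH₄⁺ channel;
simulated truths for that channel are quoted post-conversion so recovery
comparisons are like-for-like.

Simulated rates are rates of ¹⁵N *product* formation per μg protein — the
quantity the measurement chain can actually recover. Converting these to
gross denitrification/DNRA rates would require the isotope-pairing
treatment of the intracellular label fraction, which is deliberately out
of scope (storage dynamics during pre-loading are collapsed into a
constant label fraction). Also not emulated: O₂ dynamics and any
dose–response to HS⁻/acetate amendments (treatments only label scenarios
and shift rate draws), anammox scenarios beyond a null template,
carry-over contamination of the first post-destruction sample (the
pipeline excludes that point regardless), and reaction–diffusion structure
within the mat. Passing recovery tests therefore demonstrates the
correctness of the bookkeeping and statistics, not the realism of mat
biogeochemistry.

Campaign templates draw six scenarios (two sites × SW / +HS⁻ / +DOC
treatments): "white" mats run both pathways with denitrification dominant
in every syringe; "orange" mats have zero filament denitrification (any N₂
production is epibiont) and filament DNRA only. Ranges bracket the
observed spread of published mat-piece rates (~10–1000 pmol μg⁻¹ h⁻¹).

## Statistical limitations worth knowing

With four subsamples per phase, the whole-mat OLS fit has 2 residual
degrees of freedom and the epibiont fit (after the exclusion rule) has 1.
Slope errors scaled by the *fitted* SE are therefore t₂- and
t₁-distributed: a ±3 SE interval covers only ~90 % (t₂) or ~80 % (t₁),
not the Gaussian 99.7 %, and the quadrature FLSB interval inherits ~89–90 %
coverage. This is a property of the experimental design (the number of
time points), not of the estimator; consumers wanting calibrated intervals
should multiply the fitted SE by the appropriate t quantile rather than
treat it as a normal σ. Relatedly, for a mat type whose filament
denitrification is truly zero, the whole-mat and epibiont truths coincide
and the sign of their fitted difference is a fair coin: individual
replicates clip to zero roughly half the time, so "how often the filament
rate clips" is not a stable summary statistic at small n.

The leak correction is exact for plateaus (production stopped) and biased
upward of order k·t̄ for active-phase slopes; with the default leak this
is a few percent and small compared with typical SEs, but it is the reason
"correct then fit" and "fit then correct" do not commute.

## Numerical and interface choices

Exact rationals for all stoichiometric coefficients; decimal only at
output. Grid resolution 200 points and bisection tolerance 10⁻⁶ μM for the
[Ar]app search; the estimation upper bound is 10× the maximum observed
argon. The no-correction sentinel is an explicit result object rather than
a magic value. CSV for time series, JSON for config and diagnostics
(schema-validated, unknown keys rejected), TSV for the report table; all
randomness flows from a single integer seed through
`numpy.random.default_rng`, so equal configs give byte-identical outputs.
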