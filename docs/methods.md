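# Methods

`rhizocomp` simulates the competition of two virtual plant species for soil
water on a lattice of 1 m x 1 m x 1 m soil patches: a deep, **tap-rooted**
species whose roots exude mucilage that renders the topsoil (0--50 cm)
hydrophobic upon drying, and a shallow, **fibrous-rooted** species restricted
to the topsoil.  The package contains four coupled pieces: rasterized
root-system sketches, a resistor-network hydraulics solver that turns those
sketches into resistance--saturation curves, fitted *vitality* functions that
compress the curves into the population model's uptake term, and the daily
individual-based model (IBM) itself, plus a precipitation scenario engine
and spatial point-pattern statistics.

## Root-system sketches

Root systems are drawn as one-cell-wide skeletons on a 60 cm x 100 cm
cross-section at 1 mm resolution.  The fibrous system is a symmetric fan of
adventitious branches from the shoot axis (7 at the intermediate stage, 13
fully developed), confined to the topsoil; the tap system is a vertical root
reaching 100 cm at both stages plus lateral pairs (1 pair near the surface
at the intermediate stage; 7 pairs, five of them in the topsoil, when
developed).  Per-branch cell quotas are balanced so that the total skeleton
cell count times the cell size equals the stage totals (129.7 cm and
391.9 cm) exactly, and therefore agrees between architectures by
construction — the published sketches constrain only totals, branch counts
and depth distribution, so the exact angles and spacings here are a
parametric layout (fan half-angle 40 degrees, lateral dip 10 degrees below
horizontal; both chosen so the canonical quotas fit the profile).  No sketch
exists for the germination stage (first week), during which no transpiration
is assumed.  A one-cell cortex sheath is derived by 8-neighbourhood dilation
of the skeleton; the 8-neighbourhood closes the sheath around diagonal
skeleton steps.

## Resistor-network hydraulics

Each raster cell is a hydraulic resistor: soil cells carry the reciprocal of
the Van Genuchten relative conductivity `Kr(theta) = sqrt(theta) * (1 - (1 -
theta^m)^m)^2` with `n = 2` (`m = 1/2`); cortex resistivity declines
linearly with depth from 10 to 1 (relative units) and stele resistivity
rises from 0.1 to 1; the soil surface is an impermeable cap crossed only by
the stele's exit cell.  Adjacent cells are joined by the mean of their two
resistivities (two half-cells in series, 4-neighbourhood), a single virtual
source node connects to every soil cell of the bottom row and the two
lateral boundary columns through that cell's own resistivity (water arriving
from the surrounding bulk soil; an all-soil-cells source is available as an
option), and the two-point effective resistance between source and exit is
computed from the grounded sparse graph Laplacian (SuperLU with minimum-
degree ordering).  `Kr` is floored at 1e-9 (resistivity ceiling 1e9) so the
linear system stays finite at zero saturation.  Because resistor networks
are homogeneous of degree one in resistivities, the unknown absolute tissue
resistivities only rescale the curves and cancel in the vitality
normalization; the gradient endpoints are therefore conventional, only
their directions matter.

## Vitality

Vitality is the normalized inverse of the total effective resistance,
clipped to [0, 1]; the normalization reference is the second-highest
resistance at zero saturation across the curve family.  Two fitted forms
are used in the simulator:

* uniform saturation (no hydrophobicity):
  `V(theta) = (1 - exp(-k*theta)) / (1 - exp(-k))`, with published constants
  k = 98.79 (intermediate root stage) and k = 63.88 (developed);
* split saturation (hydrophobic topsoil):
  `V(t, s) = (1 - exp(a*t + b)) / (1 + exp(c*s + d))` with published
  per-architecture, per-stage parameters.

The split form's grouping deserves a note: read as `1 - exp(a*t+b) *
sigmoid`, the surface would *decrease* with subsoil saturation for the
published parameters, which is physically backwards; the product grouping
used here increases monotonically in both saturations and reproduces the
published spot value (fibrous, developed stage, bone-dry topsoil over
saturated subsoil: V = 0.25).  The simulator consumes the published
parameters by default — the unpublished absolute resistivities preclude an
exact re-derivation — but `fit_vitality_total` / `fit_vitality_split`
(damped least squares; the split form with 10 seeded multi-starts, bounds
a, c in [-200, 0], b, d in [-20, 20]) allow refitting from the hydraulics
module.  The split form has flat directions when the subsoil sigmoid
saturates, so the testable contract of a fit is pointwise surface
equivalence, not parameter equality.

## The individual-based model

One step is one day.  Order within a step: precipitation; per-patch water
bookkeeping; per-plant vitality; growth and transpiration; mortality;
reproduction; ageing.

**Water.**  A patch stores `phi * z = 500 mm` of water equivalent
(porosity 0.5 over 1 m), 250 mm per layer when split.  Precipitation events
arrive every `f` days (`f` in {1, 7, 14}), each delivering `S * f / 365` mm
of the annual sum `S` (event on day numbers divisible by `f`).  Saturation
above 1 percolates below the profile and is lost.  A patch splits into
topsoil/subsoil compartments exactly while the exudation trait is active
and at least one tap plant is present (activation copies the profile
saturation into both layers; deactivation merges them by their mean, the
layers being equally deep).  Incoming water is partitioned by the
hydrophobicity factor `omega = min(1, 0.5*B_tap * pi*r_rhizo^2 / (2*pi*
r_root^2 * rho_root * V_topsoil))` (r_rhizo = 0.4 cm, r_root = 0.02 cm,
rho_root = 0.01 g/cm3, V_topsoil = 5e5 cm3): the topsoil receives the
volume share `(1-omega)/(2-omega)` and the subsoil `1/(2-omega)`; the
shares sum to one for every omega.

**Vitality and growth.**  Plants younger than a week take up no water and
are exempt from vitality-driven mortality; ages 7--30 use the intermediate-
stage parameters, older plants the developed-stage ones.  On unsplit
patches both species use the uniform-saturation form; on split patches each
species uses its own split-saturation surface.  The gross daily increment
is logistic, `G = (V/50) * B * (1 - B/max_biomass)`, and sets a
transpiration demand of 800 g water per g of assimilate.  The *realized*
increment is throttled by the water actually obtainable: demands are pooled
per patch and layer, each layer supplies at most its standing water
(proportional rationing), and dual-layer tap roots shift unmet demand from
one layer to the other's slack — so a tap plant over a bone-dry topsoil
still grows on subsoil water (consistent with its fitted vitality of ~0.95
there) while a fibrous plant, whose only layer is empty, cannot grow at
all.  Growth without water would otherwise be a free lunch that neutralizes
the hydrophobicity trait entirely.  Tap plants divert 20% of assimilates
into mucilage whenever the trait is active; transpiration is charged on the
gross increment (exudates are photoassimilates and cost water to fix).  On
split patches tap plants draw equal shares from both layers and fibrous
plants from the topsoil only.

**Mortality and reproduction.**  A plant dies when its vitality falls below
0.2 (after the germination week) or its age reaches its life expectancy
(drawn once, normal with mean 600 d and s.d. 100 d).  Each plant older than
30 d attempts reproduction daily with probability `min(1, B^3 * V / 1000)`;
a uniform angle and a Gaussian distance (s.d. 2 patch units, toroidal wrap;
reflecting boundaries available) pick the target patch, and a seedling
(biomass 1 g, fresh life expectancy) establishes only if the target patch's
standing biomass is below 10 g, costing the parent 1 g.  Failed
establishment costs nothing.  When several events target one patch the same
day, a random priority fills the remaining room.

**Initialization.**  One plant of a uniformly random species per patch
(about 5100 per species on the 101 x 101 grid), ages uniform on 1--400 d,
biomass `age/life_expectancy * max_biomass`, patch saturations normal
(0.5 +/- 0.2) clipped to [0, 1].  A run is a pure function of (parameters,
seed).

**The biomass ceiling.**  `max_biomass` is not constrained by the published
description; the default here is 200 g.  The choice matters: the annual
water budget of a patch supports at most `S/800` grams of assimilate per
year (437 g at 350 mm), so a ceiling of O(10^2) g — a typical peak standing
crop for a perennial monopolizing 1 m^2 — keeps mature plants transpiring
and growth water-limited under the dry scenarios, which is the premise of
the whole competition.  A small ceiling (tens of grams) instead parks every
adult at zero net growth and transpiration within a year, makes even the
driest scenario water-surplus, and turns the reproduction rule
deterministic (B^3 far above the 1000 threshold for every adult), leaving
the 20% mucilage tax as the only active force.  With the 200 g default a
tap plant already renders its patch fully hydrophobic (omega = 1) at a
quarter of its ceiling.

## Scenario engine and metrics

The published protocol is a 3 x 3 grid of annual sums {350, 700, 1400} mm
and intervals {1, 7, 14} d, each cell run with the trait on and off for
3650 steps (10 years) and 100 replicates (replicate i uses seed
base_seed + i).  The package's desk-scale profile — used by the test suite —
is a 51 x 51 lattice, 1825 steps (5 years) and 10 replicates per cell,
which keeps the full grid of qualitative checks within minutes on one CPU.
Population metrics are per-step, per-species abundance and total biomass,
reduced to the normalized difference `(tap - fibrous)/(tap + fibrous)`
(0/0 -> 0); "late-run" statistics average the final 1000 steps.  Series
smoothing uses a cubic smoothing spline (GCV-chosen penalty), which
reproduces constant and linear series exactly.

At the desk scale the dry-scenario trait benefit is strong (late normalized
differences near +0.8), the trait-off grid coexists near parity, and the
benefit shrinks sharply at 1400 mm.  The contrast between precipitation
intervals at 350 mm (7 d and 14 d exceeding 1 d) reproduces only weakly —
the ordering holds but by a margin comparable to its replicate noise —
because on mature tap patches omega is pinned at 1, so the topsoil receives
no water at *any* event frequency, and because the dry-scenario effect
saturates well before the evaluation window.  This fragility is recorded as
a known limitation rather than tuned away.

## Spatial statistics

Plant locations (one point per individual, patch center plus a seeded
uniform sub-cell jitter to break grid ties; centers available via a flag)
are analysed with univariate and cross pair correlation functions: annulus
pair counts (bin width 1 patch unit, r up to 25) with translation edge
correction on the rectangular window, normalized by the unbiased intensity
product (`n(n-1)/|W|^2` ordered pairs in the univariate case).  Envelopes
are the pointwise min/max of 199 Monte Carlo simulations of complete
spatial randomness with the observed point counts; an observation above
(below) the envelope at a distance is classified as attraction
(inhibition).  Per-bin outcome frequencies can be aggregated across
replicates at chosen evaluation steps (default 500, 1000, 1500, 3500).

## Numerical and design notes

* All randomness flows through `numpy.random.Generator(PCG64)` seeded
  explicitly; replicate seeds are `base_seed + i`.
* Within-step transpiration uses patch-level proportional rationing rather
  than sequential per-plant draws; the two coincide except at the dry
  limit, where proportional sharing replaces draw-order priority.
* The establishment sweep processes same-day events in random priority
  order, which reproduces sequential establishment semantics for unit-mass
  seedlings.
* The resistor solver restricts the Laplacian to the connected component
  containing source and exit and reports disconnection as "no hydraulic
  path".
* Degenerate inputs: empty lattices step their water bookkeeping only;
  empty point patterns and empty curve families are rejected with errors;
  a raster with no skeleton has zero root length and no cortex.

## What the synthetic conditions do and do not show

All inputs are generated internally (there are no observational data): the
root sketches are parametric stand-ins constrained by published summary
statistics, tissue resistivities are relative, and the scenario engine
emulates only the precipitation regimes of the study design — no
evaporation, run-off, lateral soil-water flow, nutrient or light
competition, or mucilage rewetting dynamics (hydrophobicity persists while
tap plants are present).  Passing tests therefore demonstrate internal
consistency of the model chain and reproduction of the published functional
relationships and qualitative population outcomes at desk scale, not
validation against field data.
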