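"""Individual-based model of two plant species competing for soil water.

A square lattice of soil patches (1 m x 1 m x 1 m each) carries individuals
of two species: a deep, tap-rooted species that can exude mucilage and turn
the topsoil hydrophobic, and a shallow, fibrous-rooted species.  One time
step is one day.  Each step runs, in order:

1. precipitation (an event every ``interval`` days delivering the annual
   sum's proportional share);
2. per-patch water bookkeeping -- patches occupied by a tap plant with the
   exudation trait active split their saturation into topsoil and subsoil
   compartments, and incoming water is partitioned by the hydrophobicity
   factor omega (proportional to tap root biomass on the patch);
3. per-plant vitality from the stage- and species-specific fitted vitality
   functions;
4. logistic growth and the matching transpiration draw on soil water
   (800 g water per g of assimilate; tap plants divert 20% of assimilates
   into mucilage, and draw water equally from both layers where the split is
   active, while fibrous plants draw from the topsoil only);
5. mortality (vitality below 0.2 after establishment, or age reaching the
   individual's life expectancy);
6. stochastic reproduction with a Gaussian dispersal kernel, gated by the
   target patch's standing biomass.

Evaporation, run-off and lateral soil-water flow are deliberately absent;
water leaves a patch only through transpiration or by percolating below 1 m
when saturation would exceed 1.

The module exposes both scalar, single-entity operations (used in unit
tests and for didactic purposes) and a vectorized :func:`step` that advances
the whole lattice; both paths share the same pure formula helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .vitality import K_BY_STAGE, SPLIT_PARAMS, eval_vitality_split, eval_vitality_total

__all__ = [
    "TAP",
    "FIBROUS",
    "SPECIES_NAMES",
    "SpeciesParams",
    "ModelParams",
    "Patch",
    "Plant",
    "ModelState",
    "initialize",
    "compute_omega",
    "precipitation_shares",
    "growth_increment",
    "update_patch_water",
    "plant_vitality",
    "grow_and_transpire",
    "apply_mortality",
    "reproduce",
    "step",
]

TAP, FIBROUS = 0, 1
SPECIES_NAMES = ("tap", "fibrous")


@dataclass(frozen=True)
class SpeciesParams:
    """Fixed traits of one species."""

    name: str
    root_architecture: str
    exudes_mucilage: bool
    mucilage_fraction: float = 0.2
    uptake_layers: str = "both"  # "both" or "top_only"

    def __post_init__(self) -> None:
        if not 0 <= self.mucilage_fraction <= 1:
            raise ValueError("mucilage fraction must lie in [0, 1]")
        if self.uptake_layers not in ("both", "top_only"):
            raise ValueError("uptake_layers must be 'both' or 'top_only'")


DEFAULT_SPECIES = (
    SpeciesParams("tap", "tap", exudes_mucilage=True, uptake_layers="both"),
    SpeciesParams("fibrous", "fibrous", exudes_mucilage=False,
                  mucilage_fraction=0.0, uptake_layers="top_only"),
)


@dataclass(frozen=True)
class ModelParams:
    """All tunable parameters of the lattice model.

    Water-equivalent depths: porosity 0.5 over a 1000 mm profile gives
    500 mm of storable water per patch (250 mm per layer when split), so a
    precipitation sum P (mm) raises the profile saturation by P/500.
    """

    grid_shape: tuple[int, int] = (101, 101)
    max_biomass: float = 200.0  # g; logistic ceiling of standing biomass per plant
    rep_threshold: float = 1000.0
    seed_dispersal_sd: float = 2.0  # patch units
    mortality_threshold: float = 0.2
    transpiration_coeff: float = 800.0  # g water per g assimilate
    establishment_biomass_cap: float = 10.0  # g standing biomass on target patch
    seedling_biomass: float = 1.0
    life_expectancy_mean: float = 600.0  # days
    life_expectancy_sd: float = 100.0
    initial_age_range: tuple[int, int] = (1, 400)
    initial_theta_mean: float = 0.5
    initial_theta_sd: float = 0.2
    porosity: float = 0.5
    profile_depth_mm: float = 1000.0
    topsoil_depth_mm: float = 500.0
    r_rhizo_cm: float = 0.4
    r_root_cm: float = 0.02
    root_density_g_cm3: float = 0.01
    v_topsoil_cm3: float = 5.0e5
    belowground_share: float = 0.5
    stage1_end_day: int = 6
    stage2_end_day: int = 30
    annual_precip_mm: float = 700.0
    precip_interval_days: int = 7
    exudation_active: bool = True
    boundary: str = "torus"  # or "reflect"
    species: tuple[SpeciesParams, SpeciesParams] = DEFAULT_SPECIES

    def __post_init__(self) -> None:
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid must have at least one patch")
        if not 0 < self.stage1_end_day < self.stage2_end_day:
            raise ValueError("stage boundaries must be ordered")
        if self.precip_interval_days < 1:
            raise ValueError("precipitation interval must be >= 1 day")
        if self.boundary not in ("torus", "reflect"):
            raise ValueError("boundary must be 'torus' or 'reflect'")

    # --- derived water-storage constants -------------------------------
    @property
    def water_capacity_mm(self) -> float:
        """phi * z for the whole profile (mm of storable water)."""
        return self.porosity * self.profile_depth_mm

    @property
    def top_capacity_mm(self) -> float:
        return self.porosity * self.topsoil_depth_mm

    @property
    def sub_capacity_mm(self) -> float:
        return self.porosity * (self.profile_depth_mm - self.topsoil_depth_mm)

    def pore_volume_cm3(self, layer: str = "total") -> float:
        """Pore volume of one 1 m2 patch (cm3), by layer."""
        depth_mm = {"total": self.profile_depth_mm,
                    "top": self.topsoil_depth_mm,
                    "sub": self.profile_depth_mm - self.topsoil_depth_mm}[layer]
        return self.porosity * (depth_mm / 10.0) * 1.0e4  # cm depth * 1e4 cm2

    def event_precip_mm(self) -> float:
        """Water delivered per precipitation event."""
        return self.annual_precip_mm * self.precip_interval_days / 365.0


@dataclass
class Patch:
    """Scalar view of one soil patch (used by the per-entity operations)."""

    theta: float = 0.5
    theta_top: float = 0.0
    theta_sub: float = 0.0
    split_active: bool = False


@dataclass
class Plant:
    """Scalar view of one individual."""

    species: int
    age: int
    life_expectancy: float
    biomass: float
    row: int = 0
    col: int = 0
    vitality: float = 1.0


# ---------------------------------------------------------------------------
# pure formula helpers shared by scalar and vectorized paths

def compute_omega(tap_total_biomass, params: ModelParams):
    """Hydrophobicity distribution factor omega in [0, 1].

    omega = (belowground share of tap biomass) * pi * r_rhizo^2
            / (2 pi r_root^2 * rho_root * V_topsoil), clamped at 1.
    It is the fraction of the topsoil volume occupied by (hydrophobic)
    rhizosphere, proportional to tap root biomass on the patch.
    """
    b = np.asarray(tap_total_biomass, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass must be non-negative")
    num = params.belowground_share * b * math.pi * params.r_rhizo_cm**2
    den = (2.0 * math.pi * params.r_root_cm**2
           * params.root_density_g_cm3 * params.v_topsoil_cm3)
    omega = np.minimum(1.0, num / den)
    return omega if omega.ndim else float(omega)


def precipitation_shares(omega):
    """Volume shares of incoming water routed to topsoil and subsoil.

    ((1-omega)/(2-omega), 1/(2-omega)); the two shares sum to one for any
    omega in [0, 1]: no water is created or lost by the partition.
    """
    om = np.asarray(omega, dtype=float)
    top = (1.0 - om) / (2.0 - om)
    sub = 1.0 / (2.0 - om)
    if om.ndim:
        return top, sub
    return float(top), float(sub)


def growth_increment(vitality, biomass, max_biomass):
    """Gross daily assimilate gain: logistic growth scaled by vitality."""
    v = np.asarray(vitality, dtype=float)
    b = np.asarray(biomass, dtype=float)
    g = (v / 50.0) * b * (1.0 - b / max_biomass)
    g = np.maximum(g, 0.0)
    return g if g.ndim else float(g)


def _stage_of_age(age, params: ModelParams):
    """0 = germination (no uptake), 1 = intermediate, 2 = developed."""
    a = np.asarray(age)
    return np.where(a <= params.stage1_end_day, 0,
                    np.where(a <= params.stage2_end_day, 1, 2))


# ---------------------------------------------------------------------------
# scalar per-entity operations

def update_patch_water(patch: Patch, precip_mm: float, omega: float,
                       params: ModelParams) -> Patch:
    """Add one precipitation event to a patch; excess water percolates."""
    if precip_mm < 0:
        raise ValueError("precipitation must be non-negative")
    if not 0 <= omega <= 1:
        raise ValueError("omega must lie in [0, 1]")
    if patch.split_active:
        share_top, share_sub = precipitation_shares(omega)
        patch.theta_top = min(
            1.0, patch.theta_top + precip_mm / params.top_capacity_mm * share_top
        )
        patch.theta_sub = min(
            1.0, patch.theta_sub + precip_mm / params.sub_capacity_mm * share_sub
        )
    else:
        patch.theta = min(1.0, patch.theta + precip_mm / params.water_capacity_mm)
    return patch


def plant_vitality(plant: Plant, patch: Patch, params: ModelParams) -> float:
    """Vitality of one plant given its patch's water state.

    Germinating plants (first week) take up no water; their vitality is
    treated as 1 so that the mortality threshold cannot apply to them.
    """
    stage_idx = int(_stage_of_age(plant.age, params))
    if stage_idx == 0:
        return 1.0
    stage = 2 if stage_idx == 1 else 3
    if patch.split_active:
        arch = params.species[plant.species].root_architecture
        return float(eval_vitality_split(patch.theta_top, patch.theta_sub,
                                         SPLIT_PARAMS[(arch, stage)]))
    return float(eval_vitality_total(patch.theta, K_BY_STAGE[stage]))


def grow_and_transpire(plant: Plant, patch: Patch,
                       params: ModelParams) -> tuple[Plant, Patch]:
    """Apply one day of growth to a plant and its transpiration to the patch.

    The logistic increment determines the transpiration demand (800 g water
    per g assimilate); the realized increment is throttled by the water
    actually available in the layer(s) the root system reaches.  Tap roots
    draw equal shares from both layers where the split is active and shift
    unmet demand to the other layer; fibrous roots only reach the topsoil.
    Growth without water is impossible.
    """
    if plant.age <= params.stage1_end_day:
        return plant, patch
    g = growth_increment(plant.vitality, plant.biomass, params.max_biomass)
    sp = params.species[plant.species]
    exuding = params.exudation_active and sp.exudes_mucilage
    demand = params.transpiration_coeff * g  # grams == cm3
    if demand <= 0.0:
        return plant, patch
    if patch.split_active:
        avail_top = patch.theta_top * params.pore_volume_cm3("top")
        avail_sub = patch.theta_sub * params.pore_volume_cm3("sub")
        if sp.uptake_layers == "both":
            take_top = min(0.5 * demand, avail_top)
            take_sub = min(0.5 * demand, avail_sub)
            # shift unmet demand to whichever layer still has water
            unmet = demand - take_top - take_sub
            extra_sub = min(unmet, avail_sub - take_sub)
            take_sub += extra_sub
            take_top += min(unmet - extra_sub, avail_top - take_top)
            obtained = take_top + take_sub
        else:
            take_top = min(demand, avail_top)
            take_sub = 0.0
            obtained = take_top
        patch.theta_top = max(0.0, patch.theta_top
                              - take_top / params.pore_volume_cm3("top"))
        patch.theta_sub = max(0.0, patch.theta_sub
                              - take_sub / params.pore_volume_cm3("sub"))
    else:
        obtained = min(demand, patch.theta * params.pore_volume_cm3("total"))
        patch.theta = max(0.0, patch.theta
                          - obtained / params.pore_volume_cm3("total"))
    scale = obtained / demand
    plant.biomass += ((1.0 - sp.mucilage_fraction) if exuding else 1.0) * g * scale
    return plant, patch


def apply_mortality(plant: Plant, params: ModelParams, rng=None) -> bool:
    """True if the plant stays alive.

    Death strikes when vitality falls below the threshold (once past the
    germination week) or when age reaches the individual's life expectancy.
    """
    if plant.age >= plant.life_expectancy:
        return False
    if plant.age > params.stage1_end_day and plant.vitality < params.mortality_threshold:
        return False
    return True


def _fold_index(idx, n, boundary):
    """Map a possibly out-of-range lattice index back into [0, n)."""
    i = np.asarray(idx, dtype=np.int64)
    if boundary == "torus":
        out = np.mod(i, n)
    else:  # reflect
        m = np.mod(i, 2 * n)
        out = np.where(m < n, m, 2 * n - 1 - m)
    return out if out.ndim else int(out)


def reproduce(plant: Plant, state: "ModelState", rng: np.random.Generator):
    """One reproduction attempt; returns the established seedling or None.

    With probability min(1, biomass^3 * vitality / rep_threshold) a
    dispersal event occurs: a uniform angle and a Gaussian distance pick the
    target patch (toroidal wrap by default).  Establishment succeeds only if
    the target patch's standing biomass is below the establishment cap; a
    successful seedling costs the parent its own starting biomass.
    """
    p = state.params
    if plant.age <= p.stage2_end_day:
        return None
    if rng.uniform(0.0, p.rep_threshold) >= plant.biomass**3 * plant.vitality:
        return None
    angle = rng.uniform(0.0, 2.0 * math.pi)
    dist = rng.normal(0.0, p.seed_dispersal_sd)
    tr = _fold_index(plant.row + round(dist * math.sin(angle)),
                     p.grid_shape[0], p.boundary)
    tc = _fold_index(plant.col + round(dist * math.cos(angle)),
                     p.grid_shape[1], p.boundary)
    if state.patch_biomass()[tr, tc] >= p.establishment_biomass_cap:
        return None
    life = max(2.0, rng.normal(p.life_expectancy_mean, p.life_expectancy_sd))
    seedling = Plant(species=plant.species, age=1, life_expectancy=life,
                     biomass=p.seedling_biomass, row=tr, col=tc)
    plant.biomass = max(0.0, plant.biomass - p.seedling_biomass)
    state.append_plants(
        species=np.array([seedling.species]),
        age=np.array([1]),
        life_expectancy=np.array([life]),
        biomass=np.array([p.seedling_biomass]),
        row=np.array([tr]),
        col=np.array([tc]),
    )
    return seedling


# ---------------------------------------------------------------------------
# whole-lattice state and the vectorized step

class ModelState:
    """Lattice water state plus struct-of-arrays plant registry."""

    def __init__(self, params: ModelParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.step_count = 0
        h, w = params.grid_shape
        self.theta = np.zeros((h, w))
        self.theta_top = np.zeros((h, w))
        self.theta_sub = np.zeros((h, w))
        self.split_active = np.zeros((h, w), dtype=bool)
        # plant registry (compact arrays, one entry per living individual)
        self.species = np.empty(0, dtype=np.int8)
        self.age = np.empty(0, dtype=np.int32)
        self.life_expectancy = np.empty(0)
        self.biomass = np.empty(0)
        self.row = np.empty(0, dtype=np.int32)
        self.col = np.empty(0, dtype=np.int32)
        self.vitality = np.empty(0)

    # -- registry helpers ------------------------------------------------
    @property
    def n_plants(self) -> int:
        return self.species.size

    def patch_index(self) -> np.ndarray:
        return self.row.astype(np.int64) * self.params.grid_shape[1] + self.col

    def patch_biomass(self) -> np.ndarray:
        h, w = self.params.grid_shape
        return np.bincount(self.patch_index(), weights=self.biomass,
                           minlength=h * w).reshape(h, w)

    def tap_biomass(self) -> np.ndarray:
        h, w = self.params.grid_shape
        tap = self.species == TAP
        return np.bincount(self.patch_index()[tap], weights=self.biomass[tap],
                           minlength=h * w).reshape(h, w)

    def tap_present(self) -> np.ndarray:
        h, w = self.params.grid_shape
        tap = self.species == TAP
        counts = np.bincount(self.patch_index()[tap], minlength=h * w)
        return counts.reshape(h, w) > 0

    def species_counts(self) -> np.ndarray:
        return np.bincount(self.species, minlength=2)

    def species_biomass(self) -> np.ndarray:
        return np.bincount(self.species, weights=self.biomass, minlength=2)

    def keep(self, mask: np.ndarray) -> None:
        for name in ("species", "age", "life_expectancy", "biomass",
                     "row", "col", "vitality"):
            setattr(self, name, getattr(self, name)[mask])

    def append_plants(self, species, age, life_expectancy, biomass, row, col) -> None:
        self.species = np.concatenate([self.species, species.astype(np.int8)])
        self.age = np.concatenate([self.age, age.astype(np.int32)])
        self.life_expectancy = np.concatenate([self.life_expectancy,
                                               np.asarray(life_expectancy, float)])
        self.biomass = np.concatenate([self.biomass, np.asarray(biomass, float)])
        self.row = np.concatenate([self.row, row.astype(np.int32)])
        self.col = np.concatenate([self.col, col.astype(np.int32)])
        self.vitality = np.concatenate([self.vitality, np.ones(species.size)])

    def plants(self) -> list[Plant]:
        """Snapshot of the registry as scalar Plant records (for inspection)."""
        return [
            Plant(int(s), int(a), float(le), float(b), int(r), int(c), float(v))
            for s, a, le, b, r, c, v in zip(
                self.species, self.age, self.life_expectancy, self.biomass,
                self.row, self.col, self.vitality)
        ]


def initialize(params: ModelParams, seed: int) -> ModelState:
    """Seeded initial state: one plant of a random species on every patch.

    Ages are uniform on the initial range, life expectancies normal
    (600 +/- 100 d, floored just above the drawn age), initial biomass is
    the age fraction of the life expectancy times the biomass ceiling, and
    patch saturations are normal (0.5 +/- 0.2) truncated to [0, 1].
    """
    rng = np.random.default_rng(seed)
    state = ModelState(params, rng)
    h, w = params.grid_shape
    n = h * w
    species = rng.integers(0, 2, size=n).astype(np.int8)
    lo, hi = params.initial_age_range
    age = rng.integers(lo, hi + 1, size=n).astype(np.int32)
    life = rng.normal(params.life_expectancy_mean, params.life_expectancy_sd, size=n)
    life = np.maximum(life, age + 1.0)
    biomass = age / life * params.max_biomass
    rows, cols = np.divmod(np.arange(n, dtype=np.int32), w)
    state.append_plants(species, age, life, biomass, rows, cols)
    state.theta = np.clip(
        rng.normal(params.initial_theta_mean, params.initial_theta_sd, size=(h, w)),
        0.0, 1.0,
    )
    return state


def _update_split_partitions(state: ModelState) -> None:
    """Activate/deactivate the top/sub split to match tap occupancy."""
    p = state.params
    new_split = state.tap_present() if p.exudation_active else np.zeros_like(state.split_active)
    activate = new_split & ~state.split_active
    deactivate = ~new_split & state.split_active
    state.theta_top[activate] = state.theta[activate]
    state.theta_sub[activate] = state.theta[activate]
    state.theta[deactivate] = 0.5 * (state.theta_top[deactivate]
                                     + state.theta_sub[deactivate])
    state.split_active = new_split


def step(state: ModelState, precipitation_mm: float | None = None) -> ModelState:
    """Advance the lattice by one day (mutates and returns ``state``).

    ``precipitation_mm`` overrides the built-in event schedule (an event of
    ``annual_sum * interval / 365`` mm on every day divisible by the
    interval).
    """
    p = state.params
    rng = state.rng
    h, w = p.grid_shape
    day = state.step_count + 1

    # --- precipitation & split bookkeeping -----------------------------
    if precipitation_mm is None:
        precipitation_mm = (
            p.event_precip_mm() if day % p.precip_interval_days == 0 else 0.0
        )
    if p.exudation_active:
        omega = compute_omega(state.tap_biomass(), p)
        _update_split_partitions(state)
    else:
        omega = None
    if precipitation_mm > 0.0:
        split = state.split_active
        state.theta = np.where(
            split, state.theta,
            np.minimum(1.0, state.theta + precipitation_mm / p.water_capacity_mm),
        )
        if omega is not None and split.any():
            share_top, share_sub = precipitation_shares(omega)
            state.theta_top = np.where(
                split,
                np.minimum(1.0, state.theta_top
                           + precipitation_mm / p.top_capacity_mm * share_top),
                state.theta_top,
            )
            state.theta_sub = np.where(
                split,
                np.minimum(1.0, state.theta_sub
                           + precipitation_mm / p.sub_capacity_mm * share_sub),
                state.theta_sub,
            )

    if state.n_plants:
        pidx = state.patch_index()
        stage = _stage_of_age(state.age, p)

        # --- vitality ---------------------------------------------------
        vit = np.ones(state.n_plants)
        split_here = state.split_active.ravel()[pidx]
        k_arr = np.array([1.0, K_BY_STAGE[2], K_BY_STAGE[3]])
        uns = ~split_here & (stage > 0)
        if uns.any():
            # same formula as eval_vitality_total, with a per-plant k
            vit[uns] = (
                -np.expm1(-k_arr[stage[uns]] * state.theta.ravel()[pidx[uns]])
                / -np.expm1(-k_arr[stage[uns]])
            )
        spl = split_here & (stage > 0)
        if spl.any():
            abcd = _split_param_table(p)
            sel = (state.species[spl].astype(int), stage[spl] - 1)
            a, b = abcd[0][sel], abcd[1][sel]
            c, d = abcd[2][sel], abcd[3][sel]
            tt = state.theta_top.ravel()[pidx[spl]]
            ts = state.theta_sub.ravel()[pidx[spl]]
            vit[spl] = np.clip((1.0 - np.exp(a * tt + b))
                               / (1.0 + np.exp(c * ts + d)), 0.0, 1.0)
        state.vitality = vit

        # --- growth & transpiration -------------------------------------
        # Demanded transpiration water follows from the vitality-scaled
        # logistic increment; the realized increment is throttled by the
        # water actually obtainable from the layers the root system reaches
        # (supply/demand rationing per patch and layer, with dual-layer tap
        # roots shifting unmet demand to the other layer's slack).  Growth
        # without water is impossible.
        grow = stage > 0
        g = growth_increment(vit, state.biomass, p.max_biomass) * grow
        exuding = np.array([
            p.exudation_active and sp.exudes_mucilage for sp in p.species
        ])
        frac = np.array([sp.mucilage_fraction for sp in p.species])
        eff = np.where(exuding[state.species], 1.0 - frac[state.species], 1.0)
        water = p.transpiration_coeff * g  # grams == cm3
        n_patches = h * w
        pore_tot = p.pore_volume_cm3("total")
        any_split = bool(split_here.any())

        if not any_split:
            D_tot = np.bincount(pidx, weights=water, minlength=n_patches)
            A_tot = state.theta.ravel() * pore_tot
            with np.errstate(divide="ignore", invalid="ignore"):
                r_tot = np.where(D_tot > 0, np.minimum(1.0, A_tot / D_tot), 1.0)
            scale = r_tot[pidx]
            state.biomass = state.biomass + eff * g * scale
            state.theta = np.maximum(
                0.0, state.theta
                - np.bincount(pidx, weights=water * scale,
                              minlength=n_patches).reshape(h, w) / pore_tot)
        else:
            top_only = np.array([sp.uptake_layers == "top_only"
                                 for sp in p.species])
            plant_top_only = top_only[state.species]
            pore_top = p.pore_volume_cm3("top")
            pore_sub = p.pore_volume_cm3("sub")

            d_top = np.where(split_here,
                             np.where(plant_top_only, water, 0.5 * water), 0.0)
            d_sub = np.where(split_here & ~plant_top_only, 0.5 * water, 0.0)
            d_tot = np.where(~split_here, water, 0.0)
            D_top = np.bincount(pidx, weights=d_top, minlength=n_patches)
            D_sub = np.bincount(pidx, weights=d_sub, minlength=n_patches)
            D_tot = np.bincount(pidx, weights=d_tot, minlength=n_patches)
            A_top = state.theta_top.ravel() * pore_top
            A_sub = state.theta_sub.ravel() * pore_sub
            A_tot = state.theta.ravel() * pore_tot
            with np.errstate(divide="ignore", invalid="ignore"):
                r_top = np.where(D_top > 0, np.minimum(1.0, A_top / D_top), 1.0)
                r_sub = np.where(D_sub > 0, np.minimum(1.0, A_sub / D_sub), 1.0)
                r_tot = np.where(D_tot > 0, np.minimum(1.0, A_tot / D_tot), 1.0)
            obtained = (d_top * r_top[pidx] + d_sub * r_sub[pidx]
                        + d_tot * r_tot[pidx])
            # dual-layer roots shift unmet demand to the other layer's slack
            dual = split_here & ~plant_top_only
            deficit_top = np.where(dual, d_top * (1.0 - r_top[pidx]), 0.0)
            deficit_sub = np.where(dual, d_sub * (1.0 - r_sub[pidx]), 0.0)
            E_sub = np.bincount(pidx, weights=deficit_top, minlength=n_patches)
            E_top = np.bincount(pidx, weights=deficit_sub, minlength=n_patches)
            slack_top = np.maximum(0.0, A_top - D_top * r_top)
            slack_sub = np.maximum(0.0, A_sub - D_sub * r_sub)
            with np.errstate(divide="ignore", invalid="ignore"):
                re_sub = np.where(E_sub > 0, np.minimum(1.0, slack_sub / E_sub),
                                  0.0)
                re_top = np.where(E_top > 0, np.minimum(1.0, slack_top / E_top),
                                  0.0)
            shift_to_sub = deficit_top * re_sub[pidx]
            shift_to_top = deficit_sub * re_top[pidx]
            obtained += shift_to_sub + shift_to_top
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(water > 0, obtained / water, 1.0)
            state.biomass = state.biomass + eff * g * scale

            take_top = d_top * r_top[pidx] + shift_to_top
            take_sub = d_sub * r_sub[pidx] + shift_to_sub
            take_tot = d_tot * r_tot[pidx]
            state.theta = np.maximum(
                0.0, state.theta
                - np.bincount(pidx, weights=take_tot,
                              minlength=n_patches).reshape(h, w) / pore_tot)
            state.theta_top = np.maximum(
                0.0, state.theta_top
                - np.bincount(pidx, weights=take_top,
                              minlength=n_patches).reshape(h, w) / pore_top)
            state.theta_sub = np.maximum(
                0.0, state.theta_sub
                - np.bincount(pidx, weights=take_sub,
                              minlength=n_patches).reshape(h, w) / pore_sub)

        # --- mortality ---------------------------------------------------
        dead = (state.age >= state.life_expectancy) | (
            (state.vitality < p.mortality_threshold) & (state.age > p.stage1_end_day)
        )
        if dead.any():
            state.keep(~dead)
            if p.exudation_active:
                lost = state.split_active & ~state.tap_present()
                state.theta[lost] = 0.5 * (state.theta_top[lost]
                                           + state.theta_sub[lost])
                state.split_active &= ~lost

        # --- reproduction ------------------------------------------------
        _reproduce_all(state)

    state.age = state.age + 1
    state.step_count += 1
    return state


def _split_param_table(p: ModelParams):
    """(a, b, c, d) lookup tables indexed by [species, stage-2]."""
    shape = (2, 2)
    a = np.empty(shape); b = np.empty(shape); c = np.empty(shape); d = np.empty(shape)
    for s_idx, sp in enumerate(p.species):
        for st_idx, st in enumerate((2, 3)):
            par = SPLIT_PARAMS[(sp.root_architecture, st)]
            a[s_idx, st_idx] = par.a
            b[s_idx, st_idx] = par.b
            c[s_idx, st_idx] = par.c
            d[s_idx, st_idx] = par.d
    return a, b, c, d


def _reproduce_all(state: ModelState) -> None:
    """Vectorized daily reproduction sweep.

    Each individual past the establishment month draws once; dispersal
    events whose target patch is below the biomass cap establish a seedling,
    with a random per-event priority deciding which events fill a patch's
    remaining room when several target it the same day.
    """
    p = state.params
    rng = state.rng
    h, w = p.grid_shape
    elig = np.flatnonzero(state.age > p.stage2_end_day)
    if elig.size == 0:
        return
    draws = rng.uniform(0.0, p.rep_threshold, size=elig.size)
    event = draws < state.biomass[elig] ** 3 * state.vitality[elig]
    parents = elig[event]
    k = parents.size
    if k == 0:
        return
    angles = rng.uniform(0.0, 2.0 * math.pi, size=k)
    dists = rng.normal(0.0, p.seed_dispersal_sd, size=k)
    tr = _fold_index(state.row[parents] + np.rint(dists * np.sin(angles)).astype(np.int64),
                     h, p.boundary)
    tc = _fold_index(state.col[parents] + np.rint(dists * np.cos(angles)).astype(np.int64),
                     w, p.boundary)
    tpatch = tr * w + tc

    patch_b = np.bincount(state.patch_index(), weights=state.biomass,
                          minlength=h * w)
    room = np.ceil((p.establishment_biomass_cap - patch_b) / p.seedling_biomass)
    allowed = np.maximum(0, room).astype(np.int64)

    # most events target full patches; drop them before ranking the rest
    viable = allowed[tpatch] > 0
    if not viable.any():
        return
    v_idx = np.flatnonzero(viable)
    kv = v_idx.size
    v_patch = tpatch[v_idx]
    prio = rng.random(kv)
    order = np.lexsort((prio, v_patch))
    sorted_patch = v_patch[order]
    first = np.searchsorted(sorted_patch, sorted_patch, side="left")
    rank = np.arange(kv) - first
    accepted_sorted = rank < allowed[sorted_patch]
    accepted = np.zeros(k, dtype=bool)
    accepted[v_idx[order]] = accepted_sorted
    if not accepted.any():
        return

    est_parents = parents[accepted]
    n_new = est_parents.size
    life = np.maximum(2.0, rng.normal(p.life_expectancy_mean,
                                      p.life_expectancy_sd, size=n_new))
    state.biomass[est_parents] = np.maximum(
        0.0, state.biomass[est_parents] - p.seedling_biomass)
    state.append_plants(
        species=state.species[est_parents],
        age=np.zeros(n_new, dtype=np.int32),  # ages +1 at end of step -> 1
        life_expectancy=life,
        biomass=np.full(n_new, p.seedling_biomass),
        row=tr[accepted],
        col=tc[accepted],
    )
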