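# rhizocomp

**Is making the soil around your roots water-repellent ever a good idea?**
Mucilage — the gel plant roots exude — turns hydrophobic when it dries,
impeding rewetting of the topsoil near the root.  For a single plant that
looks like self-sabotage; at the community level it can be a weapon: a
deep-rooted species that seals the topsoil cuts its shallow-rooted
competitors off from rain while it drinks from the subsoil.

`rhizocomp` is a Python library for exploring this hypothesis with a
spatially explicit individual-based model of two species competing for soil
water — a tap-rooted mucilage exuder and a fibrous-rooted competitor — on a
lattice of soil patches under configurable precipitation regimes.  It is
aimed at ecohydrologists and ecological modellers who want a transparent,
fully seeded, pure-Python implementation of the whole chain:

* **`rhizocomp.raster`** — parametric 1 mm raster sketches of fibrous and
  tap root systems at two growth stages, with equal total root length per
  stage (129.7 cm and 391.9 cm) for comparability;
* **`rhizocomp.hydraulics`** — the soil–root system as a lattice resistor
  network (Van Genuchten soil conductivity with n = 2, depth-graded cortex
  and stele resistivities, impermeable surface cap) solved via the sparse
  graph Laplacian for the total effective resistance between bulk soil and
  shoot;
* **`rhizocomp.vitality`** — *vitality*, the normalized inverse resistance
  in [0, 1] that drives uptake, growth, mortality and reproduction:
  `V(Θ) = (1 − e^(−kΘ))/(1 − e^(−k))` without hydrophobicity and
  `V(Θ_top, Θ_sub) = (1 − e^(aΘ_top+b)) / (1 + e^(cΘ_sub+d))` with it,
  including the published parameter sets and least-squares refitting;
* **`rhizocomp.ibm`** — the daily lattice model: precipitation partitioning
  between a hydrophobic topsoil and the subsoil via the root-biomass-driven
  factor ω, water-limited logistic growth (800 g water per g assimilate),
  a 20 % assimilate cost of mucilage, vitality/age mortality, and Gaussian
  seed dispersal with biomass-gated establishment;
* **`rhizocomp.scenarios`** — precipitation scenario sweeps (350/700/1400
  mm yr⁻¹ × 1/7/14-day intervals × trait on/off) with replicate seeding and
  normalized tap–fibrous difference metrics;
* **`rhizocomp.spatial`** — pair and cross-pair correlation functions with
  translation edge correction and 199-fold Monte Carlo envelopes under
  complete spatial randomness.

## A worked example

```bash
python examples/05_scenario_contrast.py
```

runs a miniature scenario pair (31 × 31 lattice, two simulated years, three
replicates) under the dry regime (350 mm yr⁻¹, one event per week) and
prints:

```
exudation OFF: late normalized biomass difference -0.000 (replicate spread 0.011)
exudation ON : late normalized biomass difference +0.205 (replicate spread 0.028)
```

The metric is (tap − fibrous)/(tap + fibrous) total biomass, averaged over
the final year.  Without the trait the two species coexist near parity
(−0.000 is well inside the replicate spread); switching the trait on pulls
the tap-rooted population decisively ahead (+0.205) despite its 20 %
mucilage tax, because the hydrophobic topsoil starves fibrous plants and
their recruits on every patch a tap plant occupies.  The other scripts in
`examples/` walk through the root sketches, resistance curves, vitality
surfaces, a single full run, and the spatial analysis; each prints a short
interpretation of its numbers.

A thin CLI mirrors the library for shell use:

```bash
rhizocomp hydraulics --architecture tap --stage 3 --theta-steps 11 --out curve.csv
rhizocomp sweep --config scenarios.yaml --out-dir results/
rhizocomp ppa --points points.csv --window 101 101 --out envelope.csv
```

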