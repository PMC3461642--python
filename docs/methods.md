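# Methods

## Model

`lvrsim` is a static, gravity-resolved compartment model of regional lung
inflation. The lung is a stack of horizontal layers from apex to base; each
layer holds a population of identical alveoli obeying an exponential
pressure–volume law

    V(Ptp) = Vmax − A·exp(−k·Ptp),      A = Vmax − Vmin,

with `Vmax` the volume at infinite distending pressure, `Vmin` the volume at
zero pressure, and `k` (per cm H2O) the curvature. Transpulmonary pressure
falls linearly with depth `z` from the apex,

    Ptp(z) = Ptp(0) − ρ_frac·z,

where lung tissue density is expressed as a fraction `ρ_frac` of water
density (default 0.25), so ρ·g collapses to `ρ_frac` cm H2O per cm and no
explicit gravitational constant is carried. Two boundary pressures define
the static volume extremes: the apical Ptp at full inflation (TLC) and at
full deflation (RV).

On the deflation limb an airway closes where `Ptp(z)` falls to the closing
pressure `Ptm′` (a single scalar for the whole lung, the homogeneous-disease
assumption); alveoli at or below the closure depth keep the gas trapped at
closure, `V(Ptm′)`, independent of depth. The inflation limb is required to
keep every airway open — a scenario whose TLC-limb Ptp reaches `Ptm′` raises
an error rather than silently trapping gas at full inflation.

Whole-lung TLC and RV are population-weighted sums of the per-alveolus
volumes (µL → L); RV/TLC is their ratio, the gas-trapping index.

### Assumptions

* Static end-inspiratory/end-expiratory states only: no airway resistance,
  no dynamic breathing, no time dependence.
* Constitutive parameters are uniform over the lung (homogeneous disease);
  the types would admit per-layer parameters but no shipped scenario uses
  that freedom.
* Uniform alveolar number density over height; no intra-layer pressure
  variation (midpoint evaluation).
* Equilibrium volumes are fully determined by the supplied apical
  pressures. The chest wall is **not** modeled as an independent compliance
  constraint; see "Known limitations".

## Parameters and defaults

| parameter | units | healthy | emphysema | meaning |
|---|---|---|---|---|
| n | – | 300×10⁶ | 150×10⁶ | alveolar count |
| Vmax | µL | 20 | 40 (nominal, see below) | volume at infinite pressure |
| Vmin/Vmax | – | 0.2 | 0.5 | trapping ratio |
| k | /cm H2O | 0.2 | 0.3 | P–V curvature (iso-volume recoil loss) |
| Ptm′ | cm H2O | 0 | 1 | airway closing pressure |
| height | cm | 35 | 35 | apex-to-base distance |
| Ptp(0) at TLC | cm H2O | 30 | 12.5 | apical recoil at full inflation |
| ρ_frac | – | 0.25 | 0.25 | tissue density / water density |

Depth is measured from the apex (where the pressure law is anchored); every
per-layer output also carries distance-from-base, the axis conventionally
plotted.

### Calibration of the two free degrees of freedom

The physiology above leaves two quantities undetermined:

1. **Deflation-limb apical pressure** (`p_rv_apex`). For the emphysema
   scenario it is found by deterministic Brent root-finding so that
   whole-lung RV/TLC equals the 0.68 baseline anchor (bracket
   `[Ptm′−2, Ptp_TLC(0)−0.5]`, convergence 1e−6; RV/TLC is strictly
   monotone in the deflation pressure over the bracket, verified from the
   endpoint values, and an anchor outside the attainable interval raises an
   error reporting that interval). The calibrated value is ≈2.44 cm H2O.
   For the healthy preset, where no whole-lung anchor exists, the deflation
   pressure is set in closed form so that airway closure sits exactly at
   the lung base (`p_rv_apex = Ptm′ + ρ_frac·height = 8.75`).
2. **Absolute volume scale.** Whole-lung RV is exactly proportional to a
   common scale on (Vmax, Vmin) while RV/TLC is exactly invariant to it, so
   the scale is the closed form `5.8 L / RV(scale=1)` — no iteration. The
   5.8 L anchor implies an effective Vmax ≈ 0.060 µL per alveolus; printed
   per-alveolus "microliter" volumes are dimensionally inconsistent with
   liter-scale whole-lung volumes by a factor ~10³, so the preset's Vmax=40
   µL is nominal and only the calibrated scale is physical. All ratios are
   unaffected.

Exactly two anchors (baseline RV/TLC and RV) are consumed; everything
downstream of the treatment transform is an emergent prediction, which is
what makes the treatment outputs falsifiable.

## Treatment transform

Volume reduction therapy is simulated as four simultaneous changes, with
the constitutive parameters of surviving alveoli untouched:

1. remove `n_removed` alveoli from a target depth interval, spread
   proportionally over the layer populations inside it (diffuse
   subsegmental treatment, and it keeps the post-treatment lung
   well-formed);
2. shorten the lung by a uniform affine rescale of the layer grid
   (35 → 33 cm in the published scenario);
3. raise transpulmonary pressure across the volume range: the apical TLC
   pressure rises (12.5 → 14 cm H2O) and, by default, the deflation-limb
   apical pressure rises by the **same increment**. This is a design
   choice the static model forces: the recoil gain of volume reduction
   applies to the Ptp field as a whole, and if the deflation limb were held
   fixed the apical RV/TLC could only fall after treatment (numerator
   fixed, denominator raised), contradicting the distension mechanism the
   model exists to capture. `p_rv_apex_post` is exposed for users who want
   a different deflation boundary condition;
4. lower the closing pressure (1 → 0.5 cm H2O, restored airway tethering).

"Upper lobes" are the apical half of lung height and "lower lobes" the
basal half by default (the lobar boundary is anatomically fuzzy; the
removal count, 22×10⁶ in the published scenario, is the authoritative
quantity and the fractions are descriptive). The ULT/LLT comparison
requires both arms to share the removal count and all pressure/height
shifts, so outcome differences are attributable to treatment site alone.

The three regional mechanisms the transform produces (labels follow the
figure convention): **A** — alveoli that were open at baseline are further
distended at RV, so their RV/TLC rises; **B** — basal alveoli deflate
further, because trapped volume falls to `V(Ptm′_post)` and TLC volume
rises, so RV/TLC falls in every layer that remains closed and in the basal
portion of the band of layers that reopen; **C** — the closure point moves
caudally. A and B are jointly possible only because the deflation limb
shifts (mechanism 3 above); in the band of reopened layers just below the
old closure point, distension (A) dominates and RV/TLC rises, so B is
asserted where it genuinely holds: the still-closed region and the deepest
reopened layers.

## Numerics

* Discretization: 350 equal layers (1 mm slabs over 35 cm) by default;
  counts apportioned by largest remainder so they sum exactly. Layer
  volumes are evaluated at midpoints (second-order accurate); a layer whose
  midpoint lies at/below the closure depth is treated as fully closed.
* A closed-form integral of the law over height — split at the closure
  depth, with the `ρ_frac → 0` limit handled analytically — is the oracle
  for the discrete sums: agreement is required within 0.1% relative at 200
  layers and 0.01% at 1000, and the default 350-layer grid sits below
  0.02% error at negligible runtime.
* Calibration root-finding is Brent's method at `xtol=1e-12`; there is no
  randomness anywhere in the model (sweeps are deterministic grids), so
  repeated runs are byte-identical.
* Degenerate inputs: `ρ_frac = 0` (gravity off) makes all layers
  identical and is handled throughout, including the closed-form oracle;
  an empty lung (n=0) is representable but raises on summary division;
  negative deflation-limb Ptp evaluates the exponential as written (closure
  normally intervenes first).

## Sensitivity analysis

`run_sweep` varies (n, k, Vmin/Vmax, Ptm′) by a relative span (default
±25%) around a scenario, one-at-a-time or as a joint factorial grid —
both envelopes are produced because "varied as a group" is ambiguous
between them. Pressures are held at the scenario's values. Grid points
that violate an invariant (e.g. Vmin/Vmax reaching 1) become error rows,
never silent drops. Varying n alone leaves RV/TLC unchanged (exact for the
continuous model; integer apportionment perturbs it below 10⁻⁶ relative),
a useful null check.

`dominance_scan` applies matched ULT/LLT treatment arms at every point of
a joint grid (default 3⁴ at ±25% around the emphysema scenario, calibrated
pressures held fixed) and reports the fraction of points where ULT reduces
RV/TLC at least as much as LLT; ties count as dominance since the claim of
interest is "never less effective". An optional mode re-anchors the
deflation pressure per grid point to the base scenario's RV/TLC; about
half the ±25% grid cannot attain the 0.68 anchor (raising Vmin/Vmax lifts
the trapped-gas floor above it), which is why fixed pressures are the
default grid semantics.

## What the scenarios do and do not emulate

The presets are idealized whole-population archetypes: uniform disease,
uniform alveolar density, a single closing pressure, and exactly linear
hydrostatic pressure. Real emphysema is regionally heterogeneous, airway
closure is distributed rather than a sharp front, and supine imaging
shifts the gravitational axis. Passing tests therefore demonstrate the
internal mechanics of the gravitational argument — where trapping
concentrates, how the closure front moves, why upper-lobe removal lowers
the population-mean RV/TLC while lower-lobe removal raises it — not a
patient-level prediction of spirometry or clinical response.

## Known limitations

* **No chest-wall compliance constraint.** Lung volumes follow from the
  prescribed apical pressures alone. In a coupled lung–chest-wall system,
  removing tissue re-equilibrates the respiratory system and can keep
  absolute volumes substantially higher than the fixed-pressure model
  predicts: with parameters near their asymptote, per-alveolus TLC here
  can grow only ~1% when apical recoil rises 12.5 → 14 cm H2O, so
  post-treatment absolute RV and TLC are systematically lower than
  chest-wall-coupled expectations (post-LLT RV computes to ≈5.0 L).
  Ratio-based outputs (RV/TLC and its percent changes) are much less
  affected and are the model's primary endpoints.
* Percent-change magnitudes depend on the lobar boundary choice and on the
  deflation boundary condition; the defaults above are fixed before any
  treatment simulation and shared by both arms.
* FEV1/FVC and airflow are outside the model: it predicts volumes, ratios
  and recoil only.
* Heterogeneous-disease simulation is a type-level extension point
  (per-layer parameters) but no validated scenario exercises it.
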