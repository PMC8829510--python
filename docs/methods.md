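# Methods

## Model overview

`vesselabm` simulates remodeling of one arterial cross-section as a
discrete-time, rule-based lattice model. The domain is a 100 × 100 grid
of square sites, 76.75 µm each, centred at (50, 50). The wall is the
annulus of site-centre radii `20 ≤ r < 26` (864 sites by exact lattice
count; the continuum area π(26² − 20²) ≈ 867), giving a 1.535 mm lumen
radius and a 460.5 µm wall — dimensions of a proximal left anterior
descending coronary segment. Each wall site holds exactly one agent,
VSMC or ECM, drawn independently with probability ½ at initialization;
initial ages are uniform integers on `[0, cycle)`.

The simulation advances in 1 h ticks for 800 ticks. The model makes the
following structural assumptions:

* **Rigid geometry, frozen hemodynamics.** The WSS profile is computed
  (or imported) once; it is not re-solved as the wall deforms. The
  feedback "remodeling raises shear again" is represented a priori by an
  exponential decay of the damage index rather than by re-running a flow
  solver.
* **Damage as the only mechanotransduction channel.** WSS below 1 Pa
  injures the wall in proportion to the shortfall; shear at or above
  1 Pa has no effect whatsoever (all event probabilities are exactly
  zero, so an undamaged wall is rigorously stationary).
* **Coarse-grained agents.** One site (76.75 µm) is far larger than a
  single cell; an agent is a tissue parcel whose behavior follows
  single-cell kinetics. Migration, VSMC phenotype switching, lipid and
  inflammatory pathways, and mechanical stress of the wall are out of
  scope.
* **Virtual endothelium.** Endothelial cells are not lattice agents; each
  angular sector hosts one virtual EC whose factor production modifies
  event probabilities.

## Hemodynamic input

`hemodynamics` supplies the angular WSS profile `τ(θ)` in Pa:

* `poiseuille_wss` — the closed form `τ = 4µQ/(πR³)`; with the reference
  tube (R = 1.535 mm, µ = 3.5 mPa·s, Q = 50 ml/min) this gives 1.027 Pa,
  a uniform, just-above-threshold baseline. Cross-checked in the tests
  against the Hagen–Poiseuille pressure-drop route `τ = (R/2)·ΔP/L`.
* `make_sector_profile` — plateau `τ_base` with a raised-cosine dip to
  `τ_min` over a sector of given width: the parametric stand-in for the
  focal low-shear region that disturbed flow produces.
* `load_wss_profile` — CSV import (`angle_deg,wss_pa`), for profiles
  computed by an external flow solver.

Profiles are sampled by periodic linear interpolation (no overshoot;
values provably bounded by the sample extrema).

## Damage field

`damage_index` maps shear to `D = (τ₀ − τ)/τ₀` below the threshold
`τ₀ = 1 Pa` and 0 at or above it (continuous at the threshold). At
hemodynamic initialization each innermost (layer-0) agent takes `D` from
the WSS at its angle; every deeper agent takes the damage of the
angularly nearest innermost agent attenuated by `κ^layer` with
`layer = floor(r − 20)`. Per-layer geometric attenuation was chosen over
continuous-in-distance attenuation because one lattice unit corresponds
to one cell layer on this grid; the alternative would only rescale κ.

Each tick every agent's stored damage is multiplied by `e^(−λ)`. Because
daughters copy their mother's current damage and the decay is uniform,
every agent's damage is exactly `D₀·e^(−λt)` where `D₀` is its ancestral
initial value — the damage field never mixes across lineages.

| parameter | meaning | unit | default |
|---|---|---|---|
| `wss0` | damage threshold | Pa | 1.0 |
| `recovery_rate` (λ) | per-hour damage decay exponent | 1/h | 0.0075 |
| `attenuation` (κ) | per-layer damage attenuation | — | 0.9 |

With λ = 0.0075 the damage has decayed to `e^(−5.25) ≈ 0.5%` of its
initial value by t = 700, which is what makes the trajectories plateau
over the final hundred ticks. κ is not constrained by data; 0.9 keeps
the outermost of six layers at ≈59% of the innermost damage, a gradual
inner-to-outer decrease.

## Biochemical factors

Per-EC hourly synthesis rates (pg/cell/h) as functions of local shear:

* endothelin: `C_ET = M(δ + α(1 − e^(−kτⁿ)))`, M = 8·10⁻⁴, δ = 0.6,
  α = 0.4, k = 3.63, n = 1.68 — rises saturating with shear;
* nitric oxide: quartic `aτ⁴ + bτ³ + cτ² + dτ + e` with
  a = 4.365·10⁻⁷, b = −9.399·10⁻⁷, c = 6.348·10⁻⁷, d = −9.939·10⁻⁸,
  e = 9.333·10⁻⁹, clamped below at zero (the fitted polynomial can go
  negative outside its range; negative synthesis is unphysical);
* MMP-9: affine `βτ + γ`, β = 4.939·10⁻⁸, γ = 2.218·10⁻⁷.

A sector's per-tick content is `C = rate · n_EC · dt` (instantaneous
production, no accumulation; `n_EC = 1` per innermost site). Content
converts to a probability modifier through the saturating map

    p = s · C / (C + K),    s = 0.005, K = 8·10⁴ pg.

The conversion constants printed in the source literature
(16.67, 1.45·10⁻⁹, 8·10⁴) do not compose into a probability in [0, 1]
under any reading; the saturating form is the design choice here —
monotone increasing is the only direction consistent with the stated
biology (ET promotes division, NO inhibits it, MMP-9 promotes matrix
degradation), K reuses the printed 8·10⁴, and the printed constants are
retained verbatim in the configuration for traceability. With per-tick
contents of order 10⁻³ pg against K = 8·10⁴ pg the modifiers are of
order 10⁻¹¹: they are structurally present and unit-tested (including
direction-of-effect), but numerically negligible in the shipped
reproduction runs. Modifiers apply only where `D > 0`, so baseline
factor production never remodels an undamaged wall.

## Event scheduling

Each tick: all agents age by 1 h; agents whose age is a multiple of
their cycle (VSMC 12 h, ECM 4 h) are visited in an order shuffled by the
run's generator. Each eligible agent draws its creation event first
(division / generation, probability `P_div` or `P_gen`) and, only if
that failed, its destruction event (apoptosis / degradation) — at most
one event per agent per tick. On creation the mother's age resets to 1
and the daughter starts at age 1 with the mother's damage.

This create-first exclusive scheme carries a small structural growth
bias: per check `E[ΔN] = p − (1−p)q`, which is `+pq` when `p = q`. The
suite tests this exact expectation rather than a naive zero-drift
assumption.

One `numpy` PCG64 generator drives everything (initial pattern, ages,
update order, event draws); the consumption contract (one shuffle per
tick, one uniform per creation draw, one more only after a failed
creation) is frozen by an event-tally oracle test, and equal seeds give
bit-identical runs.

## Tissue displacement

* **Daughter placement.** The shortest 4-connected chain of cells from
  the mother to the nearest admissible empty site shifts one step into
  it and the daughter takes the vacated site next to the mother.
  Admissible means exterior while the growth direction is outward,
  lumen while inward; inward placement therefore shrinks the lumen by
  exactly one site. For a locally thin wall this reduces to a radial
  single-site shift; in a thick wall it lets crowded columns spill
  sideways, producing the characteristic crescent of localized
  thickening. A strict radial-only shift was rejected: the calibrated
  endpoint growth concentrates enough tissue at the sector centre that
  single rays would overrun the grid. Tie-breaks among equal-length
  paths are deterministic (fixed neighbour order).
* **Removal.** The vacancy is filled by shifting the chain toward the
  nearest outer-boundary cell that passes a local simple-point test
  (its occupied neighbours stay 4-connected without it, as in thinning
  algorithms), so the wall retracts from its outer boundary, never
  fragments, and the lumen never re-expands — in both remodeling
  phases. In the degenerate case with no safely removable boundary cell
  the removal is skipped (not counted as a death).
* **Remodeling switch.** Growth is outward while
  `PB = (A_wall − A_wall(0))/(A_wall + A_lumen) < 0.40` and inward at or
  above (the boundary value goes inward, "less than 40%" being the
  strict clause). PB is evaluated before every placement, so the switch
  can occur mid-tick. The formula gives PB(0) = 0 and is consistent with
  the reference endpoint arithmetic: 864 initial wall sites and ≈2600
  final agents yield a final burden near 49%. If growth should ever
  exhaust the lumen entirely (total occlusion — far outside the
  calibrated regime), inward placement spills outward instead of
  aborting the run.

## Calibration and the reference study conditions

The four probability coefficients are not published; they are free
parameters frozen by calibration (`calibrate_defaults`: explicit
candidate search minimizing the summed squared relative distance of
replicate-mean stabilized endpoints to the targets 1282 VSMC and 1313
ECM agents, endpoints averaged over ticks 700–800). VSMC and ECM count
dynamics are mutually independent, so the two coefficient pairs can be
explored in the same runs.

The reference WSS profile is calibrated jointly with the coefficients,
as the cross-section profile behind the published endpoints is not
tabulated. Within the sector family the dip depth and width trade off
against the coefficients: a deep narrow dip (e.g. to 0.1 Pa over 120°)
concentrates growth in a handful of high-damage founder lineages, which
inflates replicate-to-replicate dispersion (final-count CV ≈ 17%) far
beyond the tight mean-trend behavior being reproduced, and puts single
runs within reach of total lumen occlusion. The frozen reference profile
is therefore the shallower, wider dip — plateau 1.2 Pa, minimum 0.5 Pa,
width 300° (the arc with τ < 1 Pa spans ≈192°, leaving a 168° normal
region whose thickness provably never changes) — which spreads growth
over more founders (final-count CV ≈ 6%) while preserving the defining
feature: thickening confined to the low-shear region.

Destruction coefficients are fixed at one eighth of their paired
creation coefficients — both channels stay active, but the destruction
rate (which adds branching variance without net growth) stays small.
Calibration used replicate batches (up to n = 60) on seed blocks
disjoint from the seeds used anywhere in the tests. Frozen defaults:

| coefficient | value |
|---|---|
| `alpha_div` | 0.5705 |
| `alpha_apop` | 0.0713 |
| `alpha_gen` | 0.1949 |
| `alpha_deg` | 0.0244 |

Achieved endpoints at freeze (n = 60, independent seeds): 1274 VSMC,
1325 ECM, plaque burden 50.0%.

## What the generated conditions do and do not emulate

The sector profile emulates the one reproducible feature of the
reference hemodynamics — a smooth focal low-shear region on an otherwise
physiological perimeter. It does not emulate secondary-flow structure,
shear oscillation, axial variation, or any patient geometry; and the
damage-decay recovery only mimics the trend of shear normalization, not
a re-solved flow field. Consequently, passing the reproduction tests
shows that the cellular kinetics, scheduling and remodeling rules
regenerate the reference endpoint statistics under a compatible
hemodynamic forcing — not that the model predicts remodeling for a real
measured vessel.

Replicate dispersion deserves emphasis: growth is a branching process
seeded by a fixed damage field, so single-run final burdens spread with
sd ≈ 4–5 percentage points even under the frozen defaults. Ten-replicate
means are stable to ≈1–2 points; individual runs are not precise
estimates.

## Numerical choices and degenerate inputs

* Probabilities are clamped into [0, 1]; the NO-dominated division
  modifier can clamp at zero.
* `plaque_burden` may be slightly negative transiently if early deaths
  shrink the wall below baseline; the direction rule treats any value
  below threshold as outward.
* WSS profiles require ≥ 4 samples, non-negative shear, strictly
  ascending angles in [0, 360); CSV import collapses duplicate angles by
  mean and normalizes out-of-range angles modulo 360 with a warning.
* A zero-width sector degenerates to a constant profile; `width = 360`
  leaves no plateau.
* Unknown configuration keys are rejected at load time; every nested
  parameter block revalidates its invariants on construction.

## Problem sizes used by the tests and the acceptance script

The full study condition (100 × 100 grid, 800 ticks) runs in about one
second, so the suite uses it directly: the invariant battery monitors a
complete seed-1 run every tick, and the reproduction tests and the
acceptance script run the full 10-replicate batch (~15 s). Cheap
integration tests shorten the horizon to 240 ticks; the Monte-Carlo
convergence check compares 5- against 20-replicate means at that
horizon.

## Known limitations

* No WSS re-solution as geometry evolves (partially coupled model); the
  recovery exponential is a stand-in.
* No cell migration, phenotype switching, lipid/inflammation pathways,
  or wall mechanics; no factor transport (production acts locally and
  instantaneously).
* The biochemical modifiers, with the literature conversion constant
  K = 8·10⁴ pg, are too small to influence the shipped runs; they matter
  only if `half_content` is reconfigured toward realistic per-tick
  contents.
* Endpoint reproduction is calibrated, not predictive: the coefficients
  and profile were chosen to match the published stabilized statistics,
  and the published cross-section WSS itself is unavailable.
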