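# vesselabm

Lattice agent-based simulation of wall-shear-stress-driven vascular
remodeling in an arterial cross-section.

## The problem

Chronically low wall shear stress (WSS, the tangential frictional force
blood exerts on the endothelium; "low" conventionally means < 1 Pa) is a
key driver of vascular remodeling: vascular smooth muscle cells (VSMC)
proliferate, extracellular matrix (ECM) turns over, the wall thickens
where shear is low, and the lumen eventually narrows. `vesselabm` couples
a hemodynamic input — an angular WSS profile around the lumen perimeter
of one vessel cross-section — to a stochastic cellular model of the wall,
for people who want a desk-scale, fully reproducible model of this
mechanobiological feedback (e.g. to explore how the shape and depth of a
low-shear region steers wall growth).

## The model

The cross-section is a 100 × 100 lattice; one site is 76.75 µm. The wall
starts as an annulus between radii 20 and 26 sites (lumen radius
1.535 mm, wall thickness 460.5 µm — a proximal coronary segment), packed
with one agent per site, VSMC or ECM with equal probability. One tick is
one hour; a VSMC may act every 12 h, an ECM agent every 4 h.

WSS couples to the cells through a damage index: for shear `τ` below the
threshold `τ₀ = 1 Pa`,

    D = (τ₀ − τ) / τ₀        (D = 0 for τ ≥ τ₀)

Innermost agents take `D` from the WSS at their angle; each deeper layer
attenuates it by `κ = 0.9`. Every hour all damage decays by `e^(−λ)`
(`λ = 0.0075`), standing in for the gradual recovery of shear as the
vessel adapts; daughters inherit their mother's damage.

When an agent's age is a multiple of its cycle, events are drawn as
Bernoulli trials (creation first; at most one event per agent per tick):

    P_div  = clamp(α_div·D + p_ET − p_NO)      VSMC division
    P_apop = α_apop·D                          VSMC apoptosis
    P_gen  = α_gen·D                           ECM generation
    P_deg  = clamp(α_deg·D + p_MMP9)           ECM degradation

`p_ET`, `p_NO`, `p_MMP9` are small modifiers derived from the hourly
production of endothelin (promotes proliferation), nitric oxide (inhibits
it) and MMP-9 (degrades matrix) by virtual endothelial cells, each an
empirical function of local WSS, converted to probabilities by a
saturating map and applied only where `D > 0`.

New tissue displaces the wall. While the plaque burden
`PB = (A_wall − A_wall(0)) / (A_wall + A_lumen)` is below 40% the wall
grows outward at constant lumen (positive remodeling); above 40% it grows
inward and the lumen narrows (negative remodeling). Daughters push the
least-displacement chain of cells toward the nearest admissible empty
site; removals compact the wall from its outer boundary.

The four α coefficients are free parameters; the shipped defaults were
frozen by `vesselabm.calibrate.calibrate_defaults` against the reference
stabilized endpoints (≈1282 VSMC, ≈1313 ECM agents after 800 h) together
with the reference low-WSS sector profile (1.2 Pa plateau dipping to
0.5 Pa over a 300° raised-cosine sector). See `docs/methods.md`.

## Worked example

```python
from vesselabm import RemodelingModel

model = RemodelingModel()        # shipped calibrated defaults
res = model.run(seed=1)
print(res.summary())
```

```
Vessel-wall remodeling simulation
=================================================
seed                     1
config hash              2aa2189fe478
ticks simulated          800 (1 h each)
initial wall area        864 sites
final VSMC count         1293
final ECM count          1328
final VSMC/ECM ratio     0.9736
final plaque burden      50.53 %
final lumen area         856 sites
final mean damage        0.0006836
```

The wall roughly triples its area over 800 simulated hours, thickening in
the low-shear sector; growth slows as the damage index decays (final mean
damage ≈ 7·10⁻⁴), and the cross-section reaches homeostasis with slightly
more ECM than VSMC. The lumen lost ~390 of its 1245 sites after the model
switched to inward growth at 40% burden. Ten replicates give the
stabilized means (ticks 700–800):

```python
reps = model.run_replicates(n=10, base_seed=1)
print(reps.summary())
```

```
Replicate summary over 10 runs (seeds 1..10)
==========================================================
window for stabilized means: ticks 700-800
mean VSMC count          1296.7
mean ECM count           1341.3
mean VSMC/ECM ratio      0.9773
mean plaque burden       51.24 %
mean lumen area          826.2 sites
```

`res.plot_snapshot(800)` renders the cross-section (lumen white, VSMC
red, ECM blue); `res.plot_timeseries()` shows counts and burden over
time. The same runs are available from the shell:

```sh
vesselabm wss poiseuille --radius-mm 1.535 --viscosity 0.0035 --flow-ml-min 50
# -> 1.02677   (uniform laminar WSS of the straight reference tube, Pa)
vesselabm simulate --seed 1 --out run1/
vesselabm replicates --n 10 --base-seed 1 --out reps/
```

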