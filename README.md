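# quadgait

Why do walking quadrupeds time their feet the way they do? Most
medium-to-large mammals walk with evenly spaced footfalls (limb phase
near 25 %), while slow or cold-blooded walkers — crocodiles, tortoises,
hippos — use high duty factors and phases of 40–50 %, and sloths
walking upside-down reverse the relationship. `quadgait` implements a
mechanical-work account of this variation: four limbs press on the
center of mass with sinusoidal force profiles, and the positive
mechanical work the limbs must perform over a stride is computed as a
function of duty factor `DF` and Hildebrand limb phase `P`.

The core quantities:

- vertical half-sine per limb, amplitude `Az = pi g / (8 DF)` (exact
  weight support at any duty factor);
- fore-aft full sine `Ax = 0.2 Az` (decelerate–accelerate for upright
  walking, reversed for suspended progression), optional hind-forward /
  fore-backward half-sine bias `0.1 Az` and medial half-sine `0.05 Az`;
- CoM velocities by periodic integration of the summed forces;
- stride cost `W = sum_limbs ∫ max(F_limb · V_CoM, 0) dt` — negative
  work by one limb cannot pay for positive work by another.

Sweeping `(DF, P)` yields cost surfaces whose minima switch from
{25, 75} % below a critical duty factor near 0.75 to {0, 50} % above
it, reverse for suspended (sloth-like) walking, and shift below 25 %
when fore-aft bias and medial forces are added.

The package also carries the observational side: Hildebrand duty
factor and limb phase estimated from footfall event logs, a packaged
table of 52 species medians, two-group K-means classification, the
phase-on-duty-factor regression, and a synthetic generator for event
logs and species ensembles.

For whom: biomechanics and comparative-locomotion researchers who want
a tested, scriptable implementation of the limb-work model and the
Hildebrand gait-space analyses. See `docs/methods.md` for assumptions,
units and numerical choices.

## Worked example

Library:

```python
>>> import quadgait as qg
>>> for phase in (0, 25, 50, 75):
...     c = qg.stride_work_cost(qg.GaitConfig(duty_factor=0.65, phase_pct=phase))
...     print(f"phase {phase:>2}%: cost {c:.6f}")
phase  0%: cost 0.105390
phase 25%: cost 0.100082
phase 50%: cost 0.105390
phase 75%: cost 0.100082
```

At duty factor 0.65 the evenly spaced phases 25/75 are cheapest (costs
are mass-specific work per stride in model units, g = Tstride = 1);
pace and trot timing cost ~5 % more, and the planar model makes P and
P + 50 exactly equivalent. The underlying mechanism is visible in the
CoM motion: at trot timing the vertical velocity in early hind stance
points down at low duty factor and up at high duty factor,

```python
>>> qg.early_stance_vertical_velocity_sign(qg.GaitConfig(0.65, 50.0))
-1
>>> qg.early_stance_vertical_velocity_sign(qg.GaitConfig(0.80, 50.0))
1
```

which is why synchronous timing becomes favorable once duty factor is
high. The switch point, by bisection:

```sh
$ quadgait critical-df --variant base
0.76640625
```

And the observational regression across the packaged 52-species table:

```sh
$ quadgait regress
slope 128.592093
intercept -64.6055931
```

i.e. median phase ≈ 129·DF − 65 across species, with the two K-means
groups (`quadgait classify`) separating the high-duty-factor,
phase-40–50 % walkers from the 'normal mammalian' grouping.

Other subcommands: `surface` (cost-surface CSV, optional heat-map PNG),
`minima`, `diagnose` (per-limb power and force–velocity angles),
`measure` (duty factor and phase from an events CSV),
`simulate-events`, `simulate-ensemble`. Each file-producing invocation
writes a `.manifest.json` with the resolved parameters and seed.

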