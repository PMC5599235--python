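# Methods

## The model

`quadgait` asks a narrow question: given that a quadruped walks with a
duty factor `DF` (fraction of the stride each foot is on the ground,
`0.5 < DF < 1` for walking) and a Hildebrand limb phase `P` (percent of
the stride by which the ipsilateral fore contact follows the hind
contact), how much mechanical limb work does the stride demand? Work is
taken as the quantity the animal economizes; the model then predicts
which phases should be selected at each duty factor.

Each limb presses on the center of mass (CoM) with prescribed,
mass-specific force waveforms while in stance (local stance time
`tau` in `[0, Tstance)`, `Tstance = DF * Tstride`):

- vertical: `Fz = Az sin(pi tau / Tstance)` with
  `Az = pi g / (8 DF)`. A half-sine averages `2/pi` of its amplitude, and
  each limb is loaded for a fraction `DF` of the stride, so four limbs
  supply a stride-averaged force `8 DF Az / pi`; the amplitude above
  makes that exactly `g` at every duty factor.
- fore-aft: `Fx = s Ax sin(2 pi tau / Tstance) + b Ab sin(pi tau / Tstance)`
  with `Ax = 0.2 Az` by default. The full sine has `s = -1` for upright
  walking (each limb decelerates then accelerates the body, as a strut
  in compression does) and `s = +1` for suspended, below-branch
  progression, where the limb acts in tension and the pattern reverses.
  The optional half-sine bias (`Ab = 0.1 Az` in the biased variants) has
  `b = +1` for hind limbs and `b = -1` for fore limbs: a net forward
  impulse from the hindquarters balanced by an equal net backward
  impulse from the forequarters.
- lateral: `Fy = m Ay sin(pi tau / Tstance)` (`Ay = 0.05 Az` in the full
  variant), directed toward the body midline by every limb.

Contacts follow the symmetrical-gait schedule: LH at stride fraction 0,
LF at `P/100`, RH at 0.5, RF at `0.5 + P/100` (mod 1).

CoM velocity fluctuations are the cumulative integral of the summed
limb forces (minus gravity, vertically) over the periodic stride, with
each component's stride mean removed; a mean forward speed `V0` is then
added to the fore-aft component. The power demanded from one limb is
`P_limb = F_limb . V_CoM`, with components cancelling *within* the limb
before any rectification. The stride cost is

    W = sum over limbs of integral of max(P_limb, 0) dt.

Negative work by one limb cannot power simultaneous positive work by
another, and there is no elastic storage: all positive work is paid
for. A pure vault — force perpendicular to velocity — is free.

Model variants: `base` (vertical + fore-aft full sine), `sloth`
(fore-aft sign reversed), `bias` (adds the hind/fore half-sine bias),
`full` (bias plus medial forces).

## Units and parameters

Dimensionless model units: body mass 1, `g = 1`, `Tstride = 1`. Forces
are in body weights, velocities in units of `g Tstride`, work per
stride in units of `m g^2 Tstride^2`. Costs are compared within a duty
factor, and surfaces are min-max normalized per duty-factor row for
presentation, so the unit choice cancels.

| parameter | default | meaning |
|---|---|---|
| `duty_factor` | — | stance fraction of the stride, in (0.5, 1) |
| `phase_pct` | — | Hildebrand limb phase, [0, 100) |
| `fore_aft_ratio` | 0.2 | `Ax/Az`; ~30 degrees of stance sweep |
| `bias_ratio` | 0 (0.1 biased) | `Ab/Az`, hind-forward/fore-backward |
| `medial_ratio` | 0 (0.05 full) | `Ay/Az`, inward from every limb |
| `orientation` | upright | `suspended` flips the fore-aft full sine |
| `mean_forward_speed` | resolved | see below |
| `samples_per_stride` | 2048 | circular time grid size |

**Mean forward speed.** The cost ordering over phases is insensitive to
`V0` provided the instantaneous fore-aft velocity stays positive — but
only if `V0` does not vary across the compared configurations. The
rectified cost contains a term that grows with `V0` (for large `V0`,
roughly `V0` times the positive fore-aft force lobe per limb, the same
for every phase), so a `V0` recomputed per configuration from that
configuration's own velocity fluctuation would tilt cost rows by a
phase-dependent amount and corrupt the minima. The default therefore
resolves to `max(g * Tstride, 1.5 * p2p)` with `p2p` the peak-to-peak
fore-aft fluctuation: constant (= 1 model unit) across every standard
sweep, yet guaranteed above the fluctuation for extreme amplitude
ratios. Any explicit `mean_forward_speed` overrides it.

**Stance angle.** The fore-aft ratio maps to a stance sweep angle by
evaluating the force resultant a quarter of the way through stance,
where the full sine peaks and the half-sine is at `sin(pi/4)`:
`Phi = 2 atan(sqrt(2) * Ax / Az)`; ratio 0.2 gives 31.6 degrees. Bias
and medial terms are excluded from this estimate (base-model quantities
only). A single ratio is used throughout — no variation of stance angle
or stance length with speed or duty factor is modeled.

## Numerical choices

- Uniform circular grid of 2048 samples per stride. Forces are exact
  sinusoid evaluations; stride integrals are sample means times the
  period (identical to the trapezoidal rule with wrap-around on a
  uniform periodic grid).
- Before integration the discrete mean of the net force is subtracted.
  Its analytic mean is zero by construction; the discrete mean carries
  O(1e-7) trapezoid error from the stance-edge kinks, and removing it
  makes the integrated velocity exactly periodic on the grid.
- Positive-work integrals clip the power series at zero and integrate;
  the kinks at the zero crossings leave O(1e-6) relative error at the
  default grid, and the cost at (DF 0.7, phase 25) moves by less than
  0.1 % when the grid doubles to 4096.
- Minima are detected on raw rows (normalization is monotone per row),
  circularly, with plateau runs reporting their central phase. Costs
  equal within 1e-9 relative are reported as a tie set — the planar
  (medial-free) variants produce exact `{P, P+50}` ties by construction.
- The critical duty factor bisects the indicator "global row minimum
  circularly nearer {0, 50} than {25, 75}" on a 0.5 % phase grid,
  default tolerance 0.002 in DF.
- Degenerate inputs are rejected (`DF <= 0.5`, `DF >= 1`, phase outside
  [0, 100)); phase is treated circularly everywhere.

Sign conventions: +x forward, +z up, +y to the animal's left; medial
force from a left limb pushes the CoM toward -y. Flipping the medial
convention is exactly a left/right relabelling, i.e. a half-stride time
shift, so every cost is invariant to it (tested).

## Model behavior worth knowing

With the default amplitudes the base model minimizes work at phases
{25, 75} below a critical duty factor near 0.75 (0.766 by bisection at
ratio 0.2, rising with larger fore-aft amplitude) and at {0, 50} above
it; the suspended variant reverses the relationship. The fore-aft bias
drags all minima toward lower phases; the medial term breaks the
50 %-shift symmetry, making the lower-phase trough the global minimum
and high phases costly.

Two fine points of the full (bias + medial) model surface, both
grid-converged and intrinsic to the stated amplitudes:

- in a narrow transition band (DF roughly 0.77–0.79) the two trough
  families merge into a valley flat to ~1e-4 relative, and the global
  minimum briefly sits just *above* trot timing (phases 50.5–55) before
  settling below 50 again;
- `cost(95) > cost(5)` holds for duty factors below the family switch
  (where phase 95 lies on a ridge), but reverses above it, where phase
  95 sits adjacent to the secondary trough just below 100 % and the
  medial tipping (~1e-3 of total cost at amplitude 0.05) is too small
  to overcome the proximity advantage.

## Observational side

Hildebrand metrics from footfall event logs: duty factor is the
contact duration over the stride period of a reference (default left
hind) limb, averaged over complete strides; limb phase is the lag from
each fore contact to its preceding ipsilateral hind contact, modulo the
mean stride period, averaged circularly when per-stride values straddle
the 0/100 wrap. Zero-noise event logs round-trip their generating
parameters exactly.

The packaged species table (52 species medians of duty factor and limb
phase, with group labels and observation counts) supports two analyses:
K-means with k = 2 on z-scored (duty factor, phase) — standardization is
a recorded choice, since raw phase in percent would dominate the
Euclidean metric — with the higher-duty-factor cluster labeled group 1;
and unweighted OLS of median phase on median duty factor across the 52
rows (slope 128.6, intercept −64.6). Species medians are used as fitted
points because they are the data printed; weighting by per-species
observation counts is deliberately not applied.

## Synthetic data

The event generator emulates video-derived footfall logs: contacts on
the symmetrical schedule scaled by the stride period, lifts one stance
duration later, and independent Gaussian jitter (truncated at 3 SD) on
every event time, standing in for frame-timing measurement error.
Orderings that still invert after truncation raise an error rather than
being silently repaired. The ensemble generator draws species
(duty factor, phase) pairs from per-group Gaussians truncated by
resampling (not clipping, to avoid boundary atoms) to
(0.5, 0.999) x [0, 100); defaults mirror the observed two-group
structure (0.80, 44 %) vs (0.68, 21 %) with 17 and 35 species.

What the generator does *not* emulate: correlated timing errors within
a stride (a digitizer mislabeling one frame shifts contact and lift
together), speed and body-size covariation, within-species variance
structure, asymmetric gaits, or missing limbs in view. Passing
recovery tests therefore show the estimators are correct and robust to
independent timing noise at realistic magnitudes, not that they are
robust to every failure mode of video digitization.

## Known limitations

- The model takes duty factor as given; it makes no attempt to explain
  duty-factor selection, and no attempt to model trot-like mechanics
  approaching DF = 0.5.
- Force profiles are fixed sinusoids, independent of phasing; there is
  no interplay between phasing and force timing, no elastic recovery,
  no muscle activation or peak-power cost, no lateral bending or
  belly/tail contact, and no stability modeling.
- Bias (0.1) and medial (0.05) amplitudes are illustrative magnitudes,
  not fitted quantities; the package exposes them as parameters but the
  defaults are not calibrated to any species.
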