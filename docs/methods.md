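# Methods

## Model

Cells are self-propelled soft disks at constant unit speed (chamber
units).  The orientation `n_i` is a unit vector relaxing toward the signal
vector `p = g + xi + F` with time constant `T`, where `g` is the *unit*
vector along the local chemoattractant gradient (chemotaxis responds to
gradient direction, not signal level), `xi` is white noise and `F` the
soft-disk contact repulsion.  Because `n` lives on the unit circle, the
relaxation acts through the tangential projector `(I − n nᵀ)` followed by
renormalization; the equivalent angle dynamics is

    dθ = −(|g + F| sin Δ / T) dt + (σ/T) dW ,

with Δ the angle between `n` and the deterministic drive.  The discrete
noise realization is `xi = (σ/√dt)·η`, `η` a standard-normal 2-vector, so
trajectory statistics are independent of `dt` for `dt ≪ T`.

The chemoattractant field obeys a diffusion equation with spatially varying
degradation `k(y)` and one point source per cell, on Dirichlet walls
(`c = 0` at the cell-entry wall, `c = 1` at the reservoir) with a periodic
lateral direction.  The degradation profile is the steady solution of the
secreted-degrading-enzyme transport problem: parabolic,
`k(y) = 4 k_max y (1−y)`, vanishing at both reservoirs and peaking at
mid-chamber; a uniform profile with equal total enzyme, `k = (2/3) k_max`,
is available for comparison, and `zero` models non-degrading mutants.

### Analytic limit

With secretion, repulsion and degradation off, the angle SDE reduces to
`dθ = −(sin θ/T) dt + (σ/T) dW`, whose stationary Fokker–Planck solution is
the von Mises density `p(θ) ∝ exp(κ cos θ)` with `κ = 2T/σ²`.  Its mean
resultant `I₁(κ)/I₀(κ)` is the mean progression of non-interacting cells
and its small-angle variance is `σ²/(2T)`; both serve as oracles for the
simulator (the form was re-derived and verified against an independent
scalar-angle Euler–Maruyama simulation in the test suite) and as the basis
of `calibrate_noise`, which inverts a measured angle variance for `σ`.
The `κ` ↔ `(σ, T)` relation is specific to this package's noise contract;
an implementation normalizing the noise differently would shift `κ` by a
constant factor.

## Numerics

* **Field.** Forward-time centred-space (FTCS) explicit steps on a square
  grid, 5-point Laplacian, periodic in `x`, Dirichlet rows re-pinned after
  every step.  Stability requires `dt ≤ h²/(4D)` and, with degradation,
  `dt·k_max ≤ 1`; the engine refuses to start otherwise.  Round-off
  negatives are clipped to zero (warned above 1e−12).
* **Sources.** Each cell deposits `β·dt/h²` on the grid node nearest its
  centre (Kronecker-delta discretization of the 2-D Dirac delta); total
  deposited mass is exactly `n_cells·β·dt` per step.
* **Gradient sampling.** Nodal central differences (one-sided at the `y`
  walls), interpolated bilinearly to the cell position: a continuous,
  O(h²)-accurate gradient.  The gradient is normalized to a unit cue with
  tolerance 1e−12; below it the cue is zero (no directional information).
* **One shared `dt`** advances field and agents; the field bound is the
  binding one at the default parameters.  Operator order within a step:
  deposit, field step, gradient/repulsion, orientation, position,
  boundaries, injection.  The ordering difference is O(dt).
* **Boundaries.** `x` wraps modulo `W`; cells reaching `y ≥ 1` are removed
  (absorbed by the reservoir); cells dipping below `y = 0` are reflected
  with the upward orientation component — removal there is not physical
  (the entry reservoir keeps supplying cells) and re-injection would
  complicate bookkeeping.
* **Injection.** Poisson counts with mean `J·W·dt` per step (deterministic
  rounding would alias with `dt`), uniform in `x`, oriented along `+y`
  (optionally spread uniformly within a configurable half-width).
* **Repulsion.** Exhaustive pairwise sum with the minimum image in `x`,
  evaluated from a contact pair list in fixed row-major order so runs are
  bit-reproducible; coincident centres push along a random direction drawn
  per pair from the run's generator.
* **RNG.** One `numpy` Generator per run; sweeps spawn one child
  `SeedSequence` per realization in a fixed order (β outer, k inner, then
  repetition).

## Metrics

Motion angles are displacement directions relative to `+y` over a
configurable frame lag, with a slow-cell filter (default: displacements
under 10% of the model distance per lag are dropped and counted — the same
filtering applied to experimental tracks, where sub-speed objects are
debris or tracking noise).

The autocorrelation `C(τ)` averages over cells and start times, by default
restricted to the exit-side half of the chamber (`y ∈ [0.5, 1]`) to remove
the orientation bias imprinted at entry.  Two observables are available:

* `quantity="vector"` (default): `C(τ) = ⟨û(t)·û(t+τ)⟩ = ⟨cos(θ(t)−θ(t+τ))⟩`,
  the autocorrelation of the displacement direction.  Its fitted decay time
  estimates the response time `T` directly (verified on synthetic walkers:
  recovery within a few percent at κ ≥ 10).
* `quantity="cos_theta"`: `⟨cos θ(t)·cos θ(t+τ)⟩`.  This observable is even
  in the angles, so its fluctuations relax at roughly twice the rate
  (`T_fit ≈ T/2` at large κ); it is shipped for comparison with analyses
  that correlate the gradient-direction cosine itself.

The exponential fit `A·exp(−τ/T) + B` runs in two modes: `plateau`
(default, `B` free — drift toward the gradient keeps `C` from decaying to
zero, plateauing near `⟨cos θ⟩²`) and `paper` (`B = 0`, the bare exponential
form conventionally reported for experimental tracks).  Non-decaying
inputs report the sentinel `T = ∞`.

Mean progression `u = ⟨v_y⟩/v0` uses per-frame displacement components.
`u_final` averages the trailing quarter of the run (the settled regime)
over cells in `y ∈ [0.25, 1]` by default: freshly injected cells are still
aligned with their `+y` initialization, and including the entry strip
biases `u` upward regardless of the collective state (the same argument
that motivates the exit-side restriction of the autocorrelation).  The
density profile is normalized to chamber mean 1; `rho_max` is taken over
the full chamber by default because aggregates form low in the chamber
when degradation is fast but just below the exit wall when it is slow.

Regime classification uses two threshold boxes in the `(u_final, rho_max)`
plane: clumping at `u ≤ 0.2` and `rho_max ≥ 4`, uncorrelated at `u ≥ 0.6`
and `rho_max ≤ 2`, streaming in between.  The thresholds are configuration
(validated on the canned presets, not on absolute literature values).

## Default parameters and what they emulate

All defaults live in `src/streamrelay/data/example.toml`; they are
repository choices sized to a linear-gradient chemotaxis chamber
(~10²–10³ µm, cell speed ~10 µm/min, cAMP diffusivity ~10⁴ µm²/min), not
measured constants:

| parameter | default | rationale |
|---|---|---|
| `D` | 2.0 | cAMP diffusivity / (v0·L) for the geometry above |
| `T` | 0.02 | orientation response ≈ 1 min at a ~10 min chamber transit |
| `sigma` | 0.1 | κ = 4: stationary angle s.d. ≈ 0.5 rad, matching the breadth of observed motion-angle distributions |
| `f0` | 3.0 | contact repulsion able to locally exceed the unit gradient cue; at `f0 ≤ 1` jammed pairs never unjam and streams freeze into artificial stalls |
| `J` | 60.0 | ~40–90 cells in the chamber at steady state; sparse enough that chains, not a continuous carpet, form |
| `W` | 0.5 | several stream widths per chamber |
| `R` | 0.0125 | ~10 µm cell in a ~10³ µm chamber |
| `beta`, `k_max` | 0.07, 40 | the streaming preset; regime presets at the same `k_max` are β = 0.02 (uncorrelated), 0.07 (streaming), 0.3 (clumping) |
| `h`, `dt` | 0.025, 7.5e-5 | `dt` at 96% of the FTCS bound; grid comparable to the cell diameter |
| `t_end` | 3.0 | ≈ 3 chamber transits; long enough for slow-degradation runs to reveal the collapse of transient streams into clumps |

The phase-diagram protocol used by the acceptance script sweeps
β ∈ {0.02, 0.055, 0.07, 0.085, 0.15} at `k_max = 40` (fast degradation,
comparable to the screening of the imposed gradient) and `k_max = 0.2`
(decay time ≫ run length, i.e. effectively non-degrading), three seeds per
point, classifying each grid point on the across-seed mean.  At these
conditions fast degradation yields a monotone decline of ⟨u⟩ with a
multi-point streaming window, while near-zero degradation collapses from
uncorrelated motion directly into clumps — the relay-plus-degradation
requirement for robust streaming.

## What the synthetic data does and does not emulate

The track generator (`fixtures.make_fixture_ou_tracks`) produces
non-interacting constant-speed walkers with the exact orientation SDE under
a uniform gradient — the idealized counterpart of non-relaying mutant cells
in a linear gradient.  It omits everything that makes real tracks hard:
variable speed, cell–cell contacts, entry/exit censoring, tracking noise
and misassignment, drift of the imposed gradient.  Tests passing on it
validate the metrics pipeline's estimators (autocorrelation time, angle
variance, progression), not robustness of those estimators to experimental
artifacts.

## Known limitations

* The nearest-node source discretization makes a cell's self-field slightly
  grid-anchored; at the default `h ≈ 2R` this regularizes the (physically
  divergent) self-gradient at about the cell scale, but results at much
  finer grids would need a spread-source scheme.
* Streaming is an intermediate, fluctuation-dominated regime: near the
  window edges individual runs can classify to either neighbouring regime,
  which is why classification averages several seeds.
* The degradation profile is static (steady-enzyme assumption); transient
  enzyme transport is out of scope.
* 2-D chamber only; no adhesion, no cell division or death, no
  receptor-level adaptation, no variable speed.
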