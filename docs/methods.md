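# Methods

## The model

`chainpotts` simulates collective neuronal migration — the chain migration
of new neurons such as those moving along the rostral migratory stream —
as a two-dimensional cellular Potts model (CPM).  The simulation domain is
an `L_x x L_y` square lattice (default 35 x 192).  Each site carries an
integer label `m(r, t)`: 0 for extracellular matrix (ECM), `1..N` for the
`N` cells (default 48), and `N + 1` for obstacles.  The two edge columns
`x = 0` and `x = L_x - 1` are obstacle walls, so the domain is a channel;
the y-direction is periodic so cells can migrate over distances much longer
than the cell size (8 lattice units).  Cell number is conserved: there is
no division or death, and any copy that would erase a cell's last site is
rejected.

Beside the label field, each cell carries two slow variables: a unit
polarity vector `p_m` (the leading-process direction) and a continuous
center `R_m` (the centroid of its sites, tracked in unwrapped y so motion
across the periodic seam accumulates).

### Energy

Configurations are weighted by a Hamiltonian with five terms, each summing
over unordered neighboring site pairs (nearest + next-nearest, i.e. the
8-neighborhood) or over cells:

* **Surface tension** — `gamma_E` (3.0) per cell–ECM pair and `gamma_C`
  (8.0) per pair of sites of two different cells.  Because
  `2 gamma_E < gamma_C`, ECM invades the gap between two cells that are
  not otherwise held together, so cell–cell contact persists only when the
  explicit adhesion term (below) pays for it.  Violating this inequality
  in a configuration file produces a loud warning, not an error.
* **Volume and shape** — `kappa_0 V_0 (1 - V_m / V_0)^2` per cell
  (`kappa_0 = V_0 = 64`) plus an elongation penalty
  `kappa_2 [1 - xi_m(r)^2]` (`kappa_2 = 5`) summed over every site of the
  cell, where `xi_m(r)` is the direction cosine of site `r` seen from the
  cell center along the polarity.  The per-site penalty vanishes on the
  polarity axis, so cells prefer to elongate along `p_m` — a leading
  process.  `xi` is defined as 0 at a site coinciding with the center,
  where the unit vector is undefined (this matters only for one-site
  cells).
* **Motility** — `-gamma_P [xi_m(r) + xi_m'(r')]` (`gamma_P = 1`) over
  cell–cell contact pairs.  Motion is contact-dependent: an isolated cell
  gains nothing by advancing, which encodes the scaffold-dependence of
  chain migration.
* **Cell–cell adhesion** —
  `-Gamma_R [1 + lam xi_m(r)][1 + lam xi_m'(r')]` over the same contact
  pairs.  `Gamma_R` is the control parameter of the study; `lam = 0.3`
  biases adhesion toward each cell's front, reflecting that the cell body
  adheres more than the thin growth cone.
* **Walls** — `gamma_W` (13.0) per cell–obstacle pair, with
  `gamma_W >> gamma_E` so cells do not squeeze through the channel walls.

### Dynamics

One Monte Carlo step (MCS) makes `16 L_x L_y` copy attempts: draw a random
site and a random one of its 8 neighbors, propose to copy the source label
onto the neighbor, and accept with the Metropolis probability
`min[1, exp(-beta dH)]` at `beta = 0.2`.  The energy change `dH` is
evaluated incrementally from the 8 neighbors of the target site; centers
and polarities are frozen within the step (they are slow variables), while
volumes update copy-by-copy.  A compiled (numba) inner loop makes the
full problem size tractable on one core; its exact agreement with a
plain full-recomputation reference is a tested invariant (tolerance 1e-9
per proposal).

After the copy attempts of each step:

1. centers are recomputed from the label field (minimal-image in y
   relative to the previous center, exact while a cell spans less than
   half the channel);
2. each polarity performs a leap-frog persistent-random-walk update: with
   half-step displacement `d`, the orthogonal component
   `dp = [d - (p.d) p] / (a tau)` rotates `p` in-plane by `|dp|` toward
   the side given by `sign(p x dp)`.  The rotation form keeps `|p| = 1`
   exactly (no norm drift; tested to 1e-9 over 10^4 updates).  `tau` is 5
   saltatory cycles = 500 MCS; `a = 1` is the lattice spacing.  The update
   runs every MCS, matching the per-unit-time discretization;
3. the saltatory phase clocks advance (below).

### Saltatory phases

Each cell alternates strictly between a *resting* and a *migrating* phase.
Every copy attempt in which either participating cell is resting is
rejected, pinning resting cell bodies (the stricter either-side reading of
the resting rule; it best matches an immobile cell body).  Phase durations
are drawn from Normal(50, 50) MCS, rounded to the nearest integer, and
resampled until >= 1.  Initial phases are equiprobable per cell.

The >= 1 resampling is a deliberate choice over clamping: it keeps the
shape of the stated normal on its admissible range.  It has a quantifiable
consequence: truncating Normal(50, 50) at 0.5 removes ~16% of the mass, so
the realized mean is ~64.6 MCS (not 50) and the realized standard
deviation ~39.6 MCS (not 50).  The package reports the moments its sampler
actually produces; tests compare them against the truncated-normal law
rather than the nominal 50/50.

### Randomness and determinism

A run consumes exactly one integer seed.  A `SeedSequence` spawns one
stream for placement and phase scheduling (numpy `Generator`) and one for
the compiled copy loop (the kernel RNG), so either half is reproducible in
isolation.  Identical (config, seed) runs produce byte-identical outputs;
this is an acceptance-tested contract.

## Initial configuration

No particular initial configuration is prescribed by the model definition.  Cells start as
`side x side` squares (side = sqrt(V_0) = 8) dropped on randomly chosen
non-overlapping slots of an aligned grid inside the channel, with uniform
random polarities.  At the default packing (48 x 64 sites in a 33 x 192
interior, fraction 0.49) unconstrained random sequential placement of 8x8
squares stalls near its jamming limit, so the slot grid is used instead;
the warm-up (default 1000 cycles) erases the initial arrangement long
before measurements start.

## Observables

* **Ordering indicator** `P = | <p_m(t)>_{m,t} |`, with polarity snapshots
  taken once per cycle over the `T`-cycle measurement period (default
  5000).  `P = 1` for perfect alignment; for uniformly random directions
  `P` is O(1/sqrt(N T)).
* **Mean velocity** `v = | <d_m(w)>_{m,w} |`, where `d_m(w)` is cell m's
  displacement over one window of `disp_window_cycles` cycles (default 5,
  the midpoint of the sensible 2–10 range; a single fixed window makes
  the statistic deterministic).  Displacements use unwrapped y, so
  periodic crossings count as real motion.  Units are lattice units per
  window; the velocity scale is internal, so only
  relative comparisons across `Gamma_R` are meaningful.

Both statistics cancel under incoherent motion, so they detect *collective*
transport, not activity.

## The adhesion sweep

The central experiment holds every parameter at its default and scans
`Gamma_R` over 0–16 (default grid 0, 1, 2, 3, 4, 6, 10, 16: zero adhesion
up to twice the cell–cell tension, denser at the low end where contact
formation turns on).  The mechanistic expectation: with
`2 gamma_E < gamma_C`, ECM separates cells unless `Gamma_R` closes the
gap, so the effective contact energy is roughly
`gamma_C - Gamma_R (1 + O(lam))` per pair and cells begin to stick for
`Gamma_R` beyond ~2.  Too little adhesion leaves cells migrating singly in
incoherent directions (low `v`); too much makes contacts effectively
unbreakable, jamming the population; chain migration — contact-driven
collective transport — lives between.

## Problem sizes used by the tests and the acceptance script

Simulation-based checks run on a reduced channel chosen to preserve the
physics while staying desk-sized: 24 x 64 lattice, 12 cells (interior
packing fraction 0.55, close to the full channel's 0.49), identical energetic
parameters.  The steady-state volume check uses 200 warm-up + 300 measured
cycles; the sweep check uses the full default `Gamma_R` grid with two
seeds per point and 20 warm-up + 40 measured cycles per run; cell-number
conservation is additionally checked on the full 35 x 192 / 48-cell
channel over 50 cycles.  Statistical checks (phase-duration moments,
Metropolis rate, ordering-indicator limits) run at full default sizes
(10^5 draws; 10^4 trials; 48 cells x 5000 snapshots).

## Numerical choices and edge cases

* Pair sums count each unordered neighboring pair once; the symmetric
  brackets of the printed tension/wall terms then contribute exactly one
  term per mixed pair.  Any consistent alternative only rescales tensions.
* The conventional "16 L^2" attempts per step is realized as `16 L_x L_y` for the
  non-square lattice (preserves attempts per site).
* Proposals are decoded from a single uniform draw over the
  `8 L_x L_y` (site, neighbor) combinations; the Metropolis variate is
  drawn only when an uphill move reaches the acceptance test.
* Neighbor queries wrap in y and clip in x; the clipped columns are
  obstacle walls in every scenario, so clipping never affects dynamics.
* The elongation sum runs over all sites of a cell, as the per-site
  Kronecker delta in the printed term dictates (not only boundary sites).
* An optional connectivity rule (`connectivity=True`) rejects any copy in
  which the losing cell's sites among the target's 8 neighbors form more
  than one cyclic arc (the target bridges separate parts of the cell); it
  is the usual O(1) local approximation, and rare global splits it misses
  heal quickly.  It is off by default — see "Known behaviors" below for
  the trade-off it controls.  Volume-annihilating copies are always
  forbidden, which is what conserves N.
* Phase durations: strictly alternating phases; negative/zero draws
  resampled, not clamped.
* In rendering, ECM is white and obstacles black, with cells colored from
  a qualitative map — ECM and obstacles are distinct reserved colors even
  though both are "background".

## What the reduced-scale tests do and do not show

The reduced channel preserves the packing fraction, the energetics, and
the saltatory timescales, so volume regulation, conservation laws, the
acceptance law, and the qualitative adhesion dependence carry over.  It
does not reproduce the full channel's absolute `P` and `v` values:
with 12 cells and a few hundred cycles the ordering indicator has a large
floor for incoherent states (`~1/sqrt(12)` per snapshot, and polarities
decorrelate slowly), and a narrow channel can sustain counter-migrating
chains whose polarities partly cancel.  Comparisons across `Gamma_R` at
matched seeds remain meaningful, which is what the sweep test asserts.

## Known behaviors of the default parameterization

Three properties of the model as defined deserve explicit mention, because
they shape what the sweep can and cannot show:

* **Counter-migrating lanes.**  From random initial polarities, the
  periodic channel admits long-lived states in which part of the
  population migrates +y and part -y.  Front-biased adhesion makes head-on
  contacts the most strongly bound configuration, smoothly sliding
  antiparallel neighbors exert no aligning torque on each other, and the
  polarity update cannot flip a polarity that is exactly antiparallel to
  its displacement — so nothing drives the two lanes to merge.  In such
  states `P` measures lane imbalance rather than global order, and `v`
  measures net lane flux.
* **Frozen polarities without contact.**  Polarity rotation is driven by
  displacement, and motility requires cell–cell contact; a cell moving
  little keeps its polarity almost indefinitely.  At zero adhesion the
  population therefore retains a finite `P` of order `1/sqrt(N)` from its
  random initial directions rather than decaying to zero.
* **Fragmentation at strong adhesion.**  Once `Gamma_R` times the maximal
  front weight exceeds `gamma_C`, the effective cell–cell interface
  tension is negative and cell domains fray and fragment unless the
  optional `connectivity` rule is enabled.  Velocities measured in that
  regime reflect streaming of label fragments, not migration of intact
  cells.  The `connectivity` rule keeps cells whole but also suppresses
  the treadmilling motion itself, which is why it is off by default.

## Known limitations

* Two-dimensional only; no 3-D kernels or neighborhoods.
* No spatial correlation functions or explicit chain-topology metrics;
  the ordering indicator and mean velocity are the readouts.
* There is no canonical `Gamma_R` grid; the
  default grid is a reasoned choice (configurable, not
  hard-coded), so curves are comparable in shape but not point-for-point.
* The velocity unit (lattice units per window) is internal; absolute
  magnitudes are not calibrated to biological micrometers per hour.
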