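# chainpotts

A cellular Potts model of collective neuronal **chain migration** — the
mode in which newborn neurons (for example those traveling the rostral
migratory stream, or those re-routed toward an injury) migrate at high
speed by using each other as scaffolds.  The package exists to answer one
mechanistic question *in silico*: **how does the strength of cell–cell
adhesion control whether chains form and move?**  Its central experiment
sweeps the adhesion strength and shows that efficient, ordered chain
migration requires an *intermediate* adhesion level: too little and cells
wander individually, too much and the population clumps and stalls.

It is written for computational biophysicists who want a small, fully
seeded, tested CPM engine with saltatory (stop-and-go) cell dynamics and
persistent-random-walk polarities.

## Model in brief

Cells are domains of shared integer labels on a 35 × 192 lattice channel
(obstacle walls in x, periodic in y).  Configurations evolve by
Metropolis-accepted single-site label copies, `16 L_x L_y` per Monte Carlo
step, under the Hamiltonian

```
H = H_st + H_v + H_m + H_cca + H_w
```

with surface tension (γ_E = 3 cell–ECM, γ_C = 8 cell–cell), a volume +
elongation-shape constriction (κ₀ = V₀ = 64, κ₂ = 5), contact-dependent
motility (γ_P = 1), front-biased cell–cell adhesion of swept strength Γ_R
(imbalance λ = 0.3), and wall repulsion (γ_W = 13), at inverse fluctuation
scale β = 0.2.  Each cell alternates resting/migrating phases with
Normal(50, 50)-MCS durations (resting cells are frozen), and its polarity
**p**_m follows a leap-frog persistent-random-walk update with persistence
time τ = 5 cycles.  Two observables summarize a run:

* ordering indicator `P = |⟨p_m(t)⟩_{m,t}|` ∈ [0, 1] — alignment of
  leading-process directions;
* mean velocity `v = |⟨d_m(w)⟩_{m,w}|` — net collective transport per
  5-cycle displacement window.

See `docs/methods.md` for the full term-by-term account, parameter table,
and numerical choices.

## Worked example

A reduced-scale run (24 × 64 channel, 12 cells — same physics, desk-sized)
at intermediate adhesion:

```
$ python analysis/01_single_run.py
Gamma_R = 4.0  seed = 1
ordering indicator P = 0.0016
mean velocity v      = 1.7376 lattice units / 5-cycle window
mean cell volume     = 61.94 sites (target V_0 = 64)
cell labels present  = 12
-> results/single_run_trajectory.tsv
```

The mean volume sits a few percent below the target V₀ = 64 (the surface
terms compress cells slightly); all 12 cells survive, as they must — the
dynamics forbids label annihilation.  The velocity is finite: adhesion at
Γ_R = 4 holds cells in contact, and the contact-dependent motility then
conveys them along the channel.  In this narrow channel opposite-moving
chains can coexist, which is why `P` can stay low even while `v` is
finite; across the sweep the *relative* pattern is what matters.

The sweep itself (tens of minutes) and its summary figure:

```
$ python analysis/02_adhesion_sweep.py     # writes results/sweep.tsv
$ python analysis/03_order_velocity_curves.py
```

The same machinery is scriptable:

```python
from chainpotts import ModelParams, run_simulation, ordering_indicator, mean_velocity

params = ModelParams(Gamma_R=4.0)        # full 35 x 192, 48 cells
traj = run_simulation(params, seed=1)    # 1000 warm-up + 5000 measured cycles
print(ordering_indicator(traj), mean_velocity(traj))
```

and a CLI mirrors it (`chainpotts run / sweep / analyze / render /
fixtures`; every run directory receives the fully resolved config).

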