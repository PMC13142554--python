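# ksnet

Toolkit for a bistable Keller–Segel-type model of in vitro microvascular
network formation. A cell density `u` and a chemoattractant `v` evolve on a
rectangular zero-flux grid:

    du/dt = f(u) - b div(u grad v) + du lap(u)
    dv/dt = c u - e v + dv lap(v)

with the cubic reaction `f(u) = a u (1-u)(u-gamma)` (stable rest states 0
and 1, unstable threshold `gamma`). The package provides:

- **kinetics** — the reaction term, the space-free (u, v) ODE, its three
  equilibria, stability and basins of attraction.
- **grid_ops** — Laplacian, gradient dot product, and the conservative
  chemotaxis divergence `div(u grad v)` with zero-flux (mirrored ghost)
  boundaries; centered or positivity-preserving upwind face fluxes.
- **pde_sim** — RK4 forward simulation from the nine-squares initial
  condition, per-step diagnostics, and classification of the long-time
  regime (homogeneous / traveling invasion / network / degenerate network)
  as `gamma` varies.
- **phase_traces** — time series of `u`, `lap u`, `grad u . grad v`, `v`,
  `lap v` at fixed grid positions, and a two-breakpoint piecewise-linear
  segmentation of `v(t)` into three temporal phases.
- **inverse_chemo** — reconstruction of the chemoattractant field from two
  consecutive density frames by a gauge-fixed (mean-zero) GMRES solve of
  the associated elliptic equation.
- **ode4** — a reduced two-compartment 4D ODE analogue: equilibrium
  enumeration through the scalar fixed-point map `u1 = phi(phi(u1))`
  (cross-checked by brute-force 4D Newton), stability, a bifurcation scan
  in the chemotactic sensitivity `b`, and heteroclinic orbits off the
  symmetric saddle.
- **cli_io** — YAML/JSON configuration, HDF5/PNG/CSV readers and writers,
  synthetic frame-pair fixtures, and the command-line interface.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes a few long pattern-formation runs (t = 180 on a
100x100 grid) shared across tests via session fixtures; the full run takes
several minutes.

## CLI

One entry point with subcommands:

```sh
ksnet simulate --gamma 0.25 --seed 7 --out run.h5         # forward model
ksnet phases --run run.h5 --pos 50,50 --out trace.csv      # phase traces
ksnet invert --frames f1.png --frames f2.png --out v.h5    # inverse solve
ksnet ode4 scan --b 10 25 --steps 16 --out scan.csv        # bifurcation scan
ksnet fixtures --kind gaussian-bumps --seed 0 --out fix    # synthetic frames
```

All commands accept `--config cfg.yaml`; an empty config gives the
standard parameter set `a=7, b=10, c=3, e=2, du=1, dv=10, gamma=0.25, h=1`.

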