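# bmcperm

Analysis toolkit for quantifying **small-molecule permeability, diffusion,
crowding and shell stability** in simulations of bacterial microcompartments
(BMCs) — polyhedral protein shells, built from hexamer and trimer tiles with
central pores, that encapsulate enzymes and their metabolites.

The package is aimed at molecular-simulation practitioners who have (or want
to emulate) trajectories of metabolites crossing a protein shell, and need
defensible numbers for how fast those metabolites get through.

## What it computes

Two independent routes to a shell permeability coefficient *P* (cm/s):

1. **Transition counting** (equilibrium trajectories). For *x* crossings of
   the shell observed over time *t* across surface area *A* at aqueous
   solute concentration *c*,

   *P* = *x* / (2 *c A t*),

   with crossings detected by a two-state hysteresis automaton on each
   solute's radial position (a crossing requires full passage between
   R_mid − δ and R_mid + δ, suppressing pore-mouth recrossing noise).

2. **Inhomogeneous solubility-diffusion model (ISDM)** (umbrella-sampling
   windows). Biased windows along the pore axis are unbiased with iterative
   WHAM into a free-energy profile G(ξ); per-window diffusivities
   D = var(ξ)/τ_ξ (τ_ξ from an exponential fit to the position
   autocorrelation) give D(ξ); then

   *P* = [ ∫ exp(β G(ξ)) / D(ξ) dξ ]⁻¹.

   For pores sampled under a cylindrical confinement of radius *r* on a tile
   of area *A*, the tile-level effective permeability combining three
   hexamer pores and one trimer pore is
   *P*_eff = (3 *P*_H + *P*_T)·π*r*²/*A*.

Supporting analyses: lag-time Einstein diffusion D(Δt) = MSD(Δt)/(6Δt) with
inside/outside partitioning and radial profiles; the
Stokes–Einstein–Sutherland fit D = a·MW^(−1/3) + b that converts
complex-size-vs-diffusion data into an effective viscosity; differentiable
coordination-number contact scores C = Σ 1/(1+e^{5(d_ij−4 Å)});
complex-level contact graphs (GEXF/GraphML export) and nearest-neighbor
statistics; interior-water counting, ingress rates, voxel flood-fill
interior volumes, and interior-water replication for osmotic rebalancing.

A synthetic Brownian-dynamics module generates all of these inputs with
analytically known ground truth (overdamped Langevin with position-dependent
diffusivity and the ∇D drift correction), so every estimator is validated
end-to-end without an MD engine.

## Worked example

Generate a shell-permeation Brownian-dynamics run (500 solutes, a 30 Å
shell with four 3 Å pores through a 3 kcal/mol barrier, 200 ns), count the
crossings, and compare with the exact quadrature on the generating
profiles:

```python
from bmcperm import (ShellBDParams, gen_shell_bd, tetrahedral_axes,
                     analytic_pore_permeability)
from bmcperm.models import CountingPermeability

params = ShellBDParams(shell_radius=30.0, pore_axes=tetrahedral_axes(),
                       pore_radius=3.0, barrier_height=3.0, n_solutes=500,
                       box_edge=100.0, dt=0.002, n_steps=100_000, seed=7)
traj, shell = gen_shell_bd(params)
results = CountingPermeability(traj, shell).fit()
print(results.summary())
print(f"Analytic (generating-profile) P: "
      f"{analytic_pore_permeability(params):.4g} cm/s")
```

Output:

```
Counting Permeability Results
==========================================
Method                transition counting (hysteresis)
Crossings (in / out)  344 / 370
Sampled time          200 ns
Surface area A        11309.7 Å²
Concentration c       0.00057792 molecules/Å³
Permeability P        2.731 ± 0.1 cm/s

Analytic (generating-profile) P: 2.442 cm/s
```

The in/out tallies agree within Poisson noise (equilibrium detailed
balance), and the counted permeability lands within ~12% of the exact
answer for the generating model — the level of agreement to expect from
~700 stochastic crossing events.

The same Model/Results pattern drives the other pipelines:
`UmbrellaPermeability(windows, bounds=(-30, 30)).fit()` returns WHAM and
diffusivity profiles plus the ISDM permeability;
`StokesEinsteinModel(mw_kda, D_obs).fit()` returns the viscosity fit.

A command-line interface mirrors the library:

```bash
bmcperm simulate shell --config cfg.toml --seed 7 --out run/
bmcperm count --traj run/shell_bd.traj --out report.json
bmcperm reus --windows windows/ --bounds -30 30 --out profiles.csv
bmcperm network --traj cargo.traj --cutoff 10 --out graph.gexf
```

## Layout

| Module | Contents |
| --- | --- |
| `bmcperm.trajectory` | ParticleSet/Trajectory/ShellGeometry, PDB/DCD/columnar-text I/O, shell fitting |
| `bmcperm.synthetic` | shell-permeation BD, umbrella-window and cargo generators + analytic oracle |
| `bmcperm.counting` | radial series, hysteresis transition detection, counting permeability |
| `bmcperm.reus` | WHAM, window diffusivity, spline fits, ISDM integral, Boltzmann inversion, 2D PMF |
| `bmcperm.diffusion` | lag-time MSD, radial diffusion/density profiles, Stokes–Einstein fit |
| `bmcperm.network` | contact scores, interaction graphs, nearest neighbors, graph export |
| `bmcperm.stability` | interior waters, ingress rates, flood-fill volume, water replication |
| `bmcperm.models` | CountingPermeability / UmbrellaPermeability / StokesEinsteinModel |

See `docs/methods.md` for the models, defaults, and known limitations.
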