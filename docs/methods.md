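# Methods

This note records the models implemented in `bmcperm`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices a user should know before trusting a number.

## Units and constants

Internal units are Å, ns and kcal/mol everywhere; conversions happen once,
in `bmcperm.constants`:

* permeability: 1 Å/ns = 10 cm/s;
* concentration: 1 M = 6.022140857×10⁻⁴ molecules/Å³;
* k_B = 1.987204×10⁻³ kcal/mol/K, so k_BT = 0.5922 kcal/mol at the default
  T = 298 K;
* water-count → volume conversions use the pure-water molarity 55.345 M;
* the Stokes–Einstein prefactor is evaluated in cgs and reported in
  10⁻⁸ cm²/s.

## Counting permeability

**Model.** At equilibrium the bidirectional crossing rate of a closed
surface measures its permeability: P = x/(2cAt) for x crossings (both
directions) in time t, area A, aqueous concentration c. The factor 2
credits equilibrium bidirectionality.

**Crossing detection.** A two-state hysteresis automaton per particle:
state flips to "inside" only below R_in = R_mid − δ and to "outside" only
above R_out = R_mid + δ; each flip emits one event at the first frame past
the threshold (no sub-frame interpolation). Events for one particle
therefore alternate in direction by construction. Default δ = 10 Å — large
against the ~5 Å pore scale, so single-frame recrossing noise at the pore
mouth cannot masquerade as transport. The counting rate with this scheme
equals the steady-state flux between absorbing boundaries at R_in and
R_out, which is what the ISDM integral over [R_mid − δ, R_mid + δ]
predicts; the two estimators are therefore compared over the same band.

**Concentration convention.** c is the solute concentration *in the aqueous
compartments*: solutes outside the [R_in, R_out] band divided by the box
volume minus the geometric band volume, averaged over frames
(`counting.bulk_concentration`). The band is partially excluded volume (the
shell itself), so the naive count-over-box-volume underestimates the
aqueous concentration — by ~15% under the default synthetic conditions —
and correspondingly overestimates P. With zero events, P = 0 is reported
together with a one-sided 95% upper bound 3/(2cAt) (rule of three);
otherwise the standard error propagates the Poisson √x uncertainty.

## Umbrella-sampling analysis (WHAM → D(ξ) → ISDM)

**WHAM.** Standard binned iterative WHAM: self-consistent iteration on the
window free energies to relative tolerance 10⁻⁷ (cap 10⁵ iterations),
histogram bin width 0.5 Å by default to match ~0.5 Å window spacing.
Uncertainties by Bayesian bootstrap: 200 seeded replicates with Dirichlet
weights over each window's samples, profiles re-anchored per replicate.
Windows may carry an equilibration period to discard (20 ns is the
convention for production replica-exchange data; the synthetic windows use
their own shorter burn-in).

Two pragmatic guards matter in practice and are on by default:

* *Occupancy threshold* — bins holding fewer than max(10, 1% of the
  best-sampled bin) samples are dropped. Tail bins visited a handful of
  correlated times otherwise acquire spuriously deep free energies and,
  because profiles are anchored min-is-zero, shift the whole profile.
* *Trim to window span* — the grid is clipped to the span of the window
  centers. Beyond the outermost umbrella the bias weight varies steeply
  within a bin, and the bin-midpoint approximation systematically deflates
  those bins.

Disjoint windows (no shared occupied bins between neighbors) raise an error
naming the gap.

**Window diffusivity.** D = var(ξ)/τ_ξ per window, with τ_ξ from an
exponential fit to the normalized position autocorrelation restricted to
lags below 2 ps — the effective replica-exchange attempt interval, beyond
which exchanges artificially decorrelate a window's series. Requires ≥1000
samples; a non-decaying ACF or zero variance raises an error rather than
returning a junk diffusivity. The D(ξ) profile is these per-window values
at the window centers, spline-smoothed downstream.

**ISDM integral.** P = [∫ exp(βG)/D dξ]⁻¹ by adaptive Gauss–Kronrod
quadrature (relative tolerance 10⁻⁸) on cubic smoothing splines of the two
profiles, with GCV-selected smoothing and evaluations clamped to the data
range. Integration bounds are per system (e.g. ±30 Å for a hexamer pore,
±60 Å for the taller trimer). The error bar resamples G within its per-bin
standard errors (200 seeded draws). Profiles are anchored min-is-zero; the
anchor is part of the convention, and re-anchoring plus matched bounds
leaves P invariant.

**Tile correction.** Permeabilities sampled inside a confining cylinder
overstate the open-surface value, since molecules outside the pore cylinder
cannot cross at all. Assuming full impermeability outside the pores,
P_eff = (n_H·P_H + P_T)·πr²/A_tile with r = 15 Å and A_tile = 16166 Å²
(cylinder-area fraction 0.0437) for a tile carrying three hexamer pores and
one trimer pore. This is exact arithmetic on its inputs.

**Equilibrium PMFs.** For comparison with biased profiles,
`boltzmann_inversion` builds G(z) = −k_BT ln p(z) from species densities in
a pore-axis cylinder (default radius 15 Å), and `pmf_2d` builds a radially
reweighted G(z, r), dividing counts by the cylindrical-shell volume 2πrΔrΔz
so a uniform density is flat; unvisited bins are NaN ("unreachable"), never
zero.

## Diffusion and crowding

`msd_lag` implements D(Δt) = MSD(Δt)/(6Δt) averaged over particles and
overlapping time origins (origin stride = lag/2 — variance reduction
without full correlation bookkeeping). It refuses wrapped trajectories
outright: silent unwrapping heuristics corrupt diffusion estimates, so
unwrapping must happen upstream and be declared in the trajectory metadata.
The 2 ns lag is the conventional headline value; sweeping 0.5–10 ns exposes
confinement (sublinear MSD inside a closed shell). Inside/outside
partitioning assigns particles per time origin by radius against R_mid and
discards windows that straddle a crossing. Radial profiles bin particles by
radius at window start; per-bin errors use a block bootstrap over
contiguous time blocks — a stand-in for independent replicas when only one
trajectory exists, which underestimates errors if the trajectory is shorter
than a few correlation times. Radial densities are per-area
(counts / 4πr²Δr), with an optional interior free-volume correction
(default 20% of the interior occupied by protein → interior bins divided
by 0.8). No periodic-box finite-size correction and no TIP3P-style
viscosity rescaling are applied; the numbers are as-measured.

The Stokes–Einstein–Sutherland fit models a complex as a sphere of density
ρ = 1.35 g/cm³: D = k_BT/(6πη)·(4πρ/3MW)^{1/3}. Fitting observed (MW, D)
pairs to D = a·MW^(−1/3) + b recovers η from the slope; the constant offset
b absorbs the non-Stokes floor seen for large assemblies in crowded
interiors. At least three distinct masses are required.

## Contact networks

The contact score is a logistic coordination number,
C = Σ 1/(1+e^{5(d_ij−4 Å)}), summed over heavy-atom cross pairs; pairs
beyond 12 Å (contribution < 4×10⁻¹⁸) are skipped via a KD-tree query, and
the minimum-image convention applies when a box is present. Complex-level
graphs use the alpha-carbon criterion (any Cα–Cα cross distance below
10 Å in a frame) and carry both the contact-frame fraction and the mean
minimum distance as edge attributes — consumers pick whichever weighting
they need. Nearest-neighbor statistics use the minimum over any atom pair
between distinct complexes; because "the average of the first k neighbors"
is ambiguous, both per-rank means and the pooled mean over the k are
returned, labeled. Graphs export to GEXF 1.2 and GraphML; layout is left to
external tools.

## Shell stability

Interior waters are counted by a geometric criterion on the water site
(oxygen-site convention): radius < R_mid in spherical mode, or membership
in the flood-fill interior mask in grid mode — both modes are exposed since
the "right" enclosure criterion is itself a modeling choice. The interior
volume voxelises space (default 1 Å spacing), marks voxels within 2.4 Å of
any shell atom occupied, flood-fills 6-connected exterior from all eight
box corners (robust to the shell touching one face), and reports remaining
unoccupied voxels × spacing³. A fill that reaches the shell's geometric
center warns of a leaky shell but still reports. Water replication for
osmotic rebalancing duplicates a uniformly sampled fraction (default 20%)
of interior waters at +0.5 Å in a random direction, resampling up to 10
times to keep ≥0.8 Å from non-parent atoms; originals are preserved
verbatim and duplicates get fresh ids. The accept/reject judgement on the
rebalanced structure stays with the user — the guess-and-check loop is
deliberately not automated.

## Synthetic generators (ground truth for every estimator)

**Shell permeation** (`gen_shell_bd`): point solutes under overdamped
Euler–Maruyama Langevin dynamics,
x ← x + [βD F + ∇D]dt + √(2D dt)·N(0,1), where the ∇D term is the spurious
drift required for the correct Boltzmann stationary distribution under
position-dependent diffusivity. The shell is a radial Gaussian barrier of
height H centered at the shell radius, gated to zero inside pore cones by a
cosine switch over 2 Å of transverse distance (differentiable forces);
diffusivity interpolates radially between D_free and D_shell with the same
Gaussian envelope. Solutes reflect at the box faces (reflecting, not
periodic — keeps inside/outside bookkeeping unambiguous) and carry an
initial inside/outside label. A timestep whose rms displacement exceeds
half the pore radius is rejected as unstable.

Defaults are the desk-scale study conditions: 30 Å shell, four tetrahedral
pores of radius 3 Å (the realistic BMC pore scale, keeping the pore-area
fraction ~1% so the lateral-decoupling assumption of the 1D oracle holds),
H = 3 kcal/mol, width 3 Å, D = 100 Å²/ns, 500 solutes in a 100 Å box,
2 ps steps for 200 ns.

**The analytic oracle** (`analytic_pore_permeability`) integrates the
generating profiles exactly: local per-area permeability
P_loc(s) = [∫ exp(β·s·G(ξ))/D(ξ) dξ]⁻¹ at pore-switch value s, area-weighted
over the open pore disks, the cosine-switch annuli and the fully gated rest
of the sphere (quadrature tolerance 10⁻⁸). The trans-barrier term matters:
at a 3 kcal/mol barrier the leakage through the 99% of the surface outside
the pores carries more flux than the pores themselves, and an oracle
keeping only the pore term would be wrong by several fold. Integration runs
over [R_mid − δ, R_mid + δ] to match the hysteresis counting band.

**Umbrella windows** (`gen_umbrella_windows`): 1D biased BD on
U(ξ) = G(ξ) + ½k(ξ−ξ₀)² with the same drift-corrected integrator,
substepped so the Euler bias on the window variance stays below ~2%
(dt ≤ 0.02/(βkD)); samples are recorded at a fixed interval after a
burn-in. Windows are independent — no replica-exchange swap dynamics — so
synthetic window series lack the swap-induced decorrelation of real
replica-exchange data; the 2 ps ACF truncation in the diffusivity estimator
is still exercised, but its motivation is only realized on real data.

**Cargo** (`gen_cargo_frames`): rigid clusters of pseudo-Cα sites whose
centers follow overdamped BD with an exponential pairwise attraction
(range ~confinement_radius/3), a soft-core repulsion at contact, and
reflection at a confining sphere. With positive attraction strength later
frames are measurably more clustered — the designed signal for the
network/nearest-neighbor analyses. Orientations are frozen (translation
only).

**What the generators do not emulate:** explicit solvent, electrostatics,
protein flexibility, molecular shape/orientation of solutes, concentration-
dependent crowding, and replica-exchange swaps. Passing tests therefore
demonstrate that the *estimators* are correct on data obeying their model
assumptions, not that those assumptions hold in any particular all-atom
system.

## Validation conditions and observed recoveries

All stochastic checks run at fixed seeds. The bundled suite verifies, among
others: free-diffusion MSD within 5% at 1000 particles; counting vs oracle
within 25% at the default shell conditions (≥50 events; observed ratios
1.00–1.12 across seeds); WHAM reconstruction of a double-Gaussian well
(~1.8 kcal/mol barrier, 24 windows, 10⁴ samples/window at 2 ps) within
0.2 kcal/mol RMS; OU-window diffusivity within 15%; flat-profile ISDM equal
to D/L to 10⁻⁶; the full windows→WHAM→D(ξ)→ISDM pipeline within 30% of the
generating-profile quadrature; flood-fill volume of a closed 50 Å-cavity
shell within 5%; and the planted-viscosity fit within 15% under 5% noise.

## Known limitations

* Binned WHAM with midpoint bias evaluation — fine at 0.5 Å bins with ≥5
  windows per kcal/mol of gradient, but steep profiles need finer bins or
  stiffer springs; MBAR is deliberately not implemented.
* The counting estimator's hysteresis band must fit inside the simulation
  box; events are not attributed to individual pores.
* Block-bootstrap errors on radial diffusion profiles understate the
  replicate-to-replicate spread of short trajectories.
* The interior-volume flood fill is a voxel approximation: volumes carry
  O(spacing) surface error (≈0.4% at 1 Å spacing for a 50 Å shell).
* `pmf_2d` leaves empty bins NaN; downstream integrations must mask them.
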