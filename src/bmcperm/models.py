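"""Estimator pipelines packaged as Model/Results pairs.

Each Model is built from data, ``fit()`` runs the full pipeline, and the
returned Results object carries the estimates, their uncertainties and a
``summary()`` table. The low-level operations these compose are all public
in their own modules; the models are the convenient front door.

* :class:`CountingPermeability` — equilibrium trajectory → crossing events →
  counting permeability.
* :class:`UmbrellaPermeability` — umbrella windows → WHAM G(ξ) + window
  diffusivities D(ξ) → ISDM permeability.
* :class:`StokesEinsteinModel` — (MW, D) observations → viscosity fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import counting, diffusion, reus
from .constants import ThermoConstants
from .trajectory import ShellGeometry, Trajectory

__all__ = [
    "CountingPermeability",
    "CountingPermeabilityResults",
    "UmbrellaPermeability",
    "UmbrellaPermeabilityResults",
    "StokesEinsteinModel",
]


def _table(title: str, rows: list[tuple[str, str]]) -> str:
    width = max(len(k) for k, _ in rows) + 2
    lines = [title, "=" * max(len(title), width + 20)]
    lines += [f"{k:<{width}}{v}" for k, v in rows]
    return "\n".join(lines)


# ---------------------------------------------------------------------------

class CountingPermeability:
    """Counting permeability estimator for an equilibrium shell trajectory.

    Parameters
    ----------
    traj : Trajectory
        Labeled, preferably unwrapped trajectory containing the solutes.
    shell : ShellGeometry
        Fitted shell with hysteresis radii R_in/R_out and surface area A.
    species : label or sequence, optional
        Solute species to track (default: every non-water, non-shell
        particle selected by the metabolite role).
    concentration : float, optional
        Solute concentration in molecules/Å³; default is the aqueous-
        compartment concentration measured from the trajectory
        (:func:`bmcperm.counting.bulk_concentration`), which excludes the
        partially excluded shell band.
    """

    def __init__(self, traj: Trajectory, shell: ShellGeometry,
                 species=None, concentration: float | None = None):
        self.traj = traj
        self.shell = shell
        self.species = species
        if concentration is None:
            concentration = counting.bulk_concentration(traj, shell, species)
        self.concentration = float(concentration)

    def fit(self) -> "CountingPermeabilityResults":
        series = counting.radial_series(self.traj, self.shell, self.species)
        mask = (self.traj.particles.select(species=self.species)
                if self.species
                else np.ones(self.traj.n_particles, dtype=bool))
        events = counting.detect_transitions(
            series, self.traj.times, self.shell.R_in, self.shell.R_out,
            particle_ids=self.traj.particles.particle_id[mask],
            species=self.traj.particles.species[mask])
        t_total = float(self.traj.times[-1] - self.traj.times[0])
        est = counting.permeability_from_counts(
            events, self.concentration, self.shell.A, t_total)
        return CountingPermeabilityResults(model=self, events=events,
                                           estimate=est)


@dataclass
class CountingPermeabilityResults:
    model: CountingPermeability
    events: list
    estimate: counting.PermeabilityEstimate

    @property
    def P(self) -> float:
        return self.estimate.P

    @property
    def stderr(self) -> float:
        return self.estimate.stderr

    @property
    def tally(self) -> tuple[int, int]:
        return counting.directional_tally(self.events)

    def plot_events(self, ax=None):
        """Cumulative crossing count vs time, split by direction."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for direction, style in (("inbound", "-"), ("outbound", "--")):
            times = sorted(e.crossing_time for e in self.events
                           if e.direction == direction)
            ax.step([0.0] + times, range(len(times) + 1), style,
                    where="post", label=direction)
        ax.set_xlabel("time (ns)")
        ax.set_ylabel("cumulative crossings")
        ax.legend()
        return ax

    def summary(self) -> str:
        n_in, n_out = self.tally
        e = self.estimate
        rows = [
            ("Method", "transition counting (hysteresis)"),
            ("Crossings (in / out)", f"{n_in} / {n_out}"),
            ("Sampled time", f"{e.t:.4g} ns"),
            ("Surface area A", f"{e.A:.6g} Å²"),
            ("Concentration c", f"{e.c:.6g} molecules/Å³"),
            ("Permeability P", f"{e.P:.4g} ± {e.stderr:.2g} cm/s"),
        ]
        if e.n_transitions == 0:
            rows.append(("95% upper bound", f"{e.upper_95:.4g} cm/s"))
        return _table("Counting Permeability Results", rows)


# ---------------------------------------------------------------------------

class UmbrellaPermeability:
    """WHAM + window-diffusivity + ISDM pipeline over umbrella windows.

    Parameters
    ----------
    windows : list of UmbrellaWindow
    bounds : (ξ_l, ξ_u)
        Integration bounds in Å (e.g. ±30 for a hexamer pore, ±60 trimer).
    bin_width : float
        WHAM histogram bin width, Å.
    equil_discard : float, optional
        Equilibration to strip from each window, ns.
    acf_max_lag : float
        Diffusivity ACF fit range, ps.
    """

    def __init__(self, windows, bounds, bin_width: float = 0.5,
                 thermo: ThermoConstants = ThermoConstants(),
                 equil_discard: float | None = None,
                 acf_max_lag: float = 2.0, n_bootstrap: int = 200,
                 seed: int = 0):
        self.windows = list(windows)
        self.bounds = tuple(bounds)
        self.bin_width = bin_width
        self.thermo = thermo
        self.equil_discard = equil_discard
        self.acf_max_lag = acf_max_lag
        self.n_bootstrap = n_bootstrap
        self.seed = seed

    def fit(self) -> "UmbrellaPermeabilityResults":
        G = reus.wham(self.windows, self.bin_width, self.thermo,
                      equil_discard=self.equil_discard,
                      n_bootstrap=self.n_bootstrap, seed=self.seed)
        D = reus.diffusivity_profile(self.windows, self.thermo,
                                     self.acf_max_lag)
        lo = max(self.bounds[0], G.grid[0], D.grid[0])
        hi = min(self.bounds[1], G.grid[-1], D.grid[-1])
        est = reus.isdm_permeability(G, D, lo, hi, self.thermo,
                                     seed=self.seed)
        return UmbrellaPermeabilityResults(model=self, free_energy=G,
                                           diffusivity=D, estimate=est,
                                           bounds=(lo, hi))


@dataclass
class UmbrellaPermeabilityResults:
    model: UmbrellaPermeability
    free_energy: reus.FreeEnergyProfile
    diffusivity: reus.DiffusivityProfile
    estimate: counting.PermeabilityEstimate
    bounds: tuple

    @property
    def P(self) -> float:
        return self.estimate.P

    @property
    def stderr(self) -> float:
        return self.estimate.stderr

    def summary(self) -> str:
        G = self.free_energy
        rows = [
            ("Method", "ISDM on WHAM free energy"),
            ("Windows", str(len(self.model.windows))),
            ("Integration bounds", f"[{self.bounds[0]:.3g}, "
                                   f"{self.bounds[1]:.3g}] Å"),
            ("Barrier max G", f"{G.G.max():.3g} kcal/mol"),
            ("Diffusivity range", f"{self.diffusivity.D.min():.3g} – "
                                  f"{self.diffusivity.D.max():.3g} Å²/ns"),
            ("Permeability P", f"{self.estimate.P:.4g} ± "
                               f"{self.estimate.stderr:.2g} cm/s"),
        ]
        return _table("Umbrella/ISDM Permeability Results", rows)

    def plot_profiles(self, axes=None):
        """Free-energy and diffusivity profiles with error bands."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(2, 1, sharex=True)
        g = self.free_energy
        axes[0].plot(g.grid, g.G, "-")
        if g.stderr is not None:
            axes[0].fill_between(g.grid, g.G - g.stderr, g.G + g.stderr,
                                 alpha=0.3)
        axes[0].set_ylabel("G (kcal/mol)")
        axes[1].plot(self.diffusivity.grid, self.diffusivity.D, "o-")
        axes[1].set_ylabel("D (Å²/ns)")
        axes[1].set_xlabel("ξ (Å)")
        return axes

    def to_dataframe(self):
        """Profiles as a tidy DataFrame (xi, G, G_err, D interpolated)."""
        import pandas as pd

        D_interp = np.interp(self.free_energy.grid, self.diffusivity.grid,
                             self.diffusivity.D)
        return pd.DataFrame({
            "xi": self.free_energy.grid,
            "G": self.free_energy.G,
            "G_err": (self.free_energy.stderr
                      if self.free_energy.stderr is not None
                      else np.full_like(self.free_energy.G, np.nan)),
            "D": D_interp,
        })


# ---------------------------------------------------------------------------

class StokesEinsteinModel:
    """Viscosity estimation from complex-size vs diffusion observations."""

    def __init__(self, mw_kda, D_obs, rho: float = 1.35, T: float = 298.0):
        self.mw_kda = np.asarray(mw_kda, dtype=float)
        self.D_obs = np.asarray(D_obs, dtype=float)
        self.rho = rho
        self.T = T

    def fit(self) -> diffusion.SEFit:
        return diffusion.stokes_einstein_fit(self.mw_kda, self.D_obs,
                                             self.rho, self.T)

    @staticmethod
    def summary_of(fit: diffusion.SEFit) -> str:
        rows = [
            ("Model", "D = a·MW^(-1/3) + b"),
            ("Viscosity η", f"{fit.eta:.4g} cP"),
            ("Offset b", f"{fit.offset:.4g} ×1e-8 cm²/s"),
            ("Density ρ", f"{fit.rho:g} g/cm³"),
            ("Temperature", f"{fit.T:g} K"),
            ("RMS residual", f"{np.sqrt(np.mean(fit.residuals**2)):.4g}"),
        ]
        return _table("Stokes-Einstein-Sutherland Fit", rows)
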