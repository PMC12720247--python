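"""Transition-event counting and the counting permeability estimator.

At equilibrium, the rate at which solutes cross a closed shell measures its
permeability directly: for x crossings (both directions) observed over time
t across a surface of area A bathed in solute concentration c,

    P = x / (2 c A t) ,

where the factor 2 credits the bidirectionality of equilibrium flux.
Crossings are detected with a two-state hysteresis automaton on each
particle's radial distance from the per-frame shell centroid: the state
flips to "inside" only below R_in and to "outside" only above R_out,
suppressing single-frame recrossing noise at the pore mouth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (ANG_PER_NS_TO_CM_PER_S, MOLAR_TO_PER_ANG3,
                        PURE_WATER_MOLARITY)
from .trajectory import ShellGeometry, Trajectory

__all__ = [
    "TransitionEvent",
    "PermeabilityEstimate",
    "FluxBalance",
    "radial_series",
    "detect_transitions",
    "permeability_from_counts",
    "concentration_estimate",
    "steady_state_gradient",
    "directional_tally",
]


@dataclass(frozen=True)
class TransitionEvent:
    """One shell crossing: which particle, when, and which way."""

    particle_id: int
    crossing_time: float          # ns
    direction: str                # "inbound" | "outbound"
    species: str = "pseudo"

    def __post_init__(self) -> None:
        if self.direction not in ("inbound", "outbound"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass
class PermeabilityEstimate:
    """A permeability coefficient with its provenance.

    ``P`` and ``stderr`` are in cm/s; ``method`` records which estimator
    produced it (counting | isdm | isdm_effective). For counting estimates
    ``c`` (molecules/Å³), ``A`` (Å²), ``t`` (ns), ``n_transitions`` and the
    surface-normalised rate ``r`` (transitions per Å² per ns) are filled in.
    ``upper_95`` carries a one-sided bound when no events were seen.
    """

    P: float
    stderr: float
    method: str
    c: float = np.nan
    A: float = np.nan
    t: float = np.nan
    n_transitions: int = 0
    r: float = np.nan
    upper_95: float = np.nan

    def __post_init__(self) -> None:
        if self.P < 0 or self.stderr < 0:
            raise ValueError("permeability and stderr must be non-negative")


@dataclass
class FluxBalance:
    """Steady-state flux bookkeeping: J = P·A·ΔC after unit conversion.

    J in molecules/ns, ΔC in molecules/Å³ (``delta_molar`` reports molar),
    A in Å², P in cm/s.
    """

    J: float
    delta_C: float
    A: float
    P: float

    @property
    def delta_molar(self) -> float:
        return self.delta_C / MOLAR_TO_PER_ANG3

    def residual(self) -> float:
        """|J − P·A·ΔC| in molecules/ns (zero up to roundoff)."""
        p_ang_ns = self.P / ANG_PER_NS_TO_CM_PER_S
        return abs(self.J - p_ang_ns * self.A * self.delta_C)


# ---------------------------------------------------------------------------

def radial_series(traj: Trajectory, shell: ShellGeometry,
                  species=None, refit_center: bool = True) -> np.ndarray:
    """Per-particle radial distance from the shell centroid, per frame.

    Returns an array of shape (n_frames, n_selected) in Å. When
    ``refit_center`` is true the centroid of the shell-role particles is
    recomputed each frame; otherwise the fitted ``shell.center`` is used.
    """
    if species is None:
        mask = np.ones(traj.n_particles, dtype=bool)
    else:
        mask = traj.particles.select(species=species)
    shell_mask = traj.particles.select(role="shell")
    pos = traj.positions[:, mask, :]
    if refit_center and shell_mask.any():
        centers = traj.positions[:, shell_mask, :].mean(axis=1)
    else:
        centers = np.broadcast_to(shell.center, (traj.n_frames, 3))
    return np.linalg.norm(pos - centers[:, None, :], axis=2)


def detect_transitions(series: np.ndarray, times: np.ndarray,
                       R_in: float, R_out: float,
                       particle_ids=None, species=None
                       ) -> list[TransitionEvent]:
    """Hysteresis crossing detection on radius time series.

    ``series`` is (n_frames,) for one particle or (n_frames, n) for many.
    A particle's state becomes "inside" only when its radius drops below
    R_in and "outside" only when it exceeds R_out; each flip emits one
    event timestamped at the first frame past the threshold. The initial
    state is taken from the first frame's side of the band midpoint.
    Events for any one particle therefore alternate in direction.
    """
    if R_in >= R_out:
        raise ValueError("require R_in < R_out")
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if series.shape[0] != len(times):
        raise ValueError("series frame count does not match times")
    n_frames, n = series.shape
    if n_frames < 2:
        return []
    if particle_ids is None:
        particle_ids = np.arange(n)
    if species is None:
        species = np.full(n, "pseudo")
    elif isinstance(species, str):
        species = np.full(n, species)

    r_mid = 0.5 * (R_in + R_out)
    events: list[TransitionEvent] = []
    state = series[0] < r_mid                      # True = inside
    for f in range(1, n_frames):
        r = series[f]
        went_in = (~state) & (r < R_in)
        went_out = state & (r > R_out)
        for j in np.nonzero(went_in)[0]:
            events.append(TransitionEvent(int(particle_ids[j]),
                                          float(times[f]), "inbound",
                                          str(species[j])))
        for j in np.nonzero(went_out)[0]:
            events.append(TransitionEvent(int(particle_ids[j]),
                                          float(times[f]), "outbound",
                                          str(species[j])))
        state = state | went_in
        state = state & ~went_out
    events.sort(key=lambda e: e.crossing_time)
    return events


def permeability_from_counts(events, c: float, A: float, t: float
                             ) -> PermeabilityEstimate:
    """Counting permeability P = x/(2cAt), converted to cm/s.

    Parameters
    ----------
    events : list of TransitionEvent (or an integer count)
    c : solute concentration in molecules/Å³
    A : shell surface area in Å²
    t : total sampled time in ns

    The standard error propagates the Poisson √x counting uncertainty. With
    zero events, P = 0 and a one-sided 95% upper bound (3/(2cAt), from the
    rule of three) is reported in ``upper_95``.
    """
    if c <= 0 or A <= 0 or t <= 0:
        raise ValueError("c, A and t must all be positive")
    x = events if isinstance(events, (int, np.integer)) else len(events)
    denom = 2.0 * c * A * t
    scale = ANG_PER_NS_TO_CM_PER_S
    if x == 0:
        return PermeabilityEstimate(P=0.0, stderr=0.0, method="counting",
                                    c=c, A=A, t=t, n_transitions=0,
                                    r=0.0, upper_95=3.0 / denom * scale)
    P = x / denom * scale
    return PermeabilityEstimate(P=P, stderr=np.sqrt(x) / denom * scale,
                                method="counting", c=c, A=A, t=t,
                                n_transitions=int(x), r=x / (A * t))


def concentration_estimate(n_solutes: int, n_waters: int) -> float:
    """Solute molarity from solute and water counts.

    The aqueous volume is inferred from the water count via the pure-water
    molarity (55.345 M), so 5 solutes among 60,000 waters gives ~4.6 mM.
    """
    if n_waters <= 0:
        raise ValueError("need a positive water count")
    if n_solutes < 0:
        raise ValueError("solute count cannot be negative")
    return n_solutes / n_waters * PURE_WATER_MOLARITY


def concentration_from_trajectory(traj: Trajectory, shell: ShellGeometry,
                                  species, region: str = "all-aqueous",
                                  frame: int = 0) -> float:
    """Molarity of a species in a region (inside | outside | all-aqueous).

    Uses water counts in the same region to fix the aqueous volume.
    """
    if region not in ("inside", "outside", "all-aqueous"):
        raise ValueError(f"unknown region {region!r}")
    p = traj.particles
    sol = p.select(species=species)
    wat = p.select(species="water")
    if region != "all-aqueous":
        r = np.linalg.norm(traj.positions[frame] - shell.center, axis=1)
        inside = r < shell.R_mid
        keep = inside if region == "inside" else ~inside
        sol, wat = sol & keep, wat & keep
    return concentration_estimate(int(sol.sum()), int(wat.sum()))


def bulk_concentration(traj: Trajectory, shell: ShellGeometry,
                       species=None) -> float:
    """Solute concentration in the aqueous compartments, molecules/Å³.

    Counts the selected solutes outside the shell band [R_in, R_out] —
    i.e. in the interior and exterior aqueous compartments — and divides by
    the corresponding geometric volume (box volume minus the band shell),
    averaged over frames. This is the concentration Eq.-5-style counting
    needs: the shell band itself is partially excluded volume, so the naive
    count-over-box-volume underestimates the aqueous concentration.
    """
    if np.any(traj.box_edges <= 0):
        raise ValueError("bulk concentration needs a finite box")
    if species is None:
        mask = np.ones(traj.n_particles, dtype=bool)
    else:
        mask = traj.particles.select(species=species)
    r = np.linalg.norm(traj.positions[:, mask, :] - shell.center, axis=2)
    outside_band = (r < shell.R_in) | (r > shell.R_out)
    v_box = float(np.prod(traj.box_edges))
    v_band = 4 * np.pi / 3 * (shell.R_out**3 - shell.R_in**3)
    if v_band >= v_box:
        raise ValueError("shell band exceeds the box volume")
    return float(outside_band.sum(axis=1).mean()) / (v_box - v_band)


def steady_state_gradient(P: float, A: float, J: float) -> FluxBalance:
    """Concentration difference ΔC = J/(P·A) sustained by a flux J.

    P in cm/s, A in Å², J in molecules/ns. Returns a :class:`FluxBalance`
    whose ``delta_molar`` property reports ΔC in mol/L.
    """
    if P <= 0 or A <= 0:
        raise ValueError("P and A must be positive")
    p_ang_ns = P / ANG_PER_NS_TO_CM_PER_S
    delta_c = J / (p_ang_ns * A)
    return FluxBalance(J=J, delta_C=delta_c, A=A, P=P)


def directional_tally(events) -> tuple[int, int]:
    """(n_inbound, n_outbound) partition of a list of events."""
    n_in = sum(1 for e in events if e.direction == "inbound")
    return n_in, len(events) - n_in


def events_to_dataframe(events):
    """Events as a pandas DataFrame (particle_id, time_ns, direction, species)."""
    import pandas as pd

    return pd.DataFrame(
        [(e.particle_id, e.crossing_time, e.direction, e.species)
         for e in events],
        columns=["particle_id", "time_ns", "direction", "species"])
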