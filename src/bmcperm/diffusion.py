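"""Lag-time diffusion estimates, radial diffusion/density profiles, and the
Stokes–Einstein–Sutherland viscosity fit.

The instantaneous diffusion coefficient at lag Δt is the three-dimensional
Einstein estimator D(Δt) = MSD(Δt)/(6Δt), averaged over particles and
overlapping time origins. Because crowded interiors confine molecules, D(Δt)
is lag-dependent there; sweeping Δt (0.5–10 ns is typical) exposes that.

For protein-complex diffusion, modelling a complex as a sphere of density ρ
gives the Stokes–Einstein–Sutherland prediction

    D = k_B T / (6 π η) · (4 π ρ / (3 MW))^{1/3} ,

so a fit of observed D against MW^{-1/3} (plus a constant offset) recovers
the effective viscosity η of the crowded environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DALTON_G, K_B_CGS
from .trajectory import ShellGeometry, Trajectory

__all__ = [
    "MSDResult",
    "SEFit",
    "msd_lag",
    "partition_by_region",
    "radial_diffusion_profile",
    "radial_density",
    "predict_diffusion",
    "stokes_einstein_fit",
]


@dataclass
class MSDResult:
    """MSD and Einstein diffusion coefficient at one lag time."""

    lag: float            # Δt, ns
    msd: float            # Å²
    D: float              # Å²/ns = MSD/(6Δt)
    subset: str           # "all" | "inside" | "outside" | "rbin-<i>"
    n_pairs: int          # particle×origin pairs averaged

    def __post_init__(self) -> None:
        if self.msd < 0:
            raise ValueError("MSD cannot be negative")


@dataclass
class SEFit:
    """Result of the Stokes–Einstein–Sutherland fit D = a·MW^(-1/3) + b.

    ``eta`` is the recovered viscosity in cP; ``offset`` is the constant
    term b in the same units as the D observations (1e-8 cm²/s);
    ``residuals`` are observation-minus-fit values.
    """

    eta: float
    offset: float
    rho: float
    T: float
    slope: float
    residuals: np.ndarray
    mw_kda: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("fitted viscosity must be positive")

    def predict(self, mw_kda) -> np.ndarray:
        return self.slope * np.asarray(mw_kda, float) ** (-1 / 3) + self.offset

    def plot(self, ax=None):
        """Observations and the fitted D = a·MW^(-1/3) + b curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.mw_kda is not None:
            mw = np.asarray(self.mw_kda, float)
            ax.plot(mw, self.predict(mw) + self.residuals, "o",
                    label="observed")
            grid = np.linspace(mw.min(), mw.max(), 200)
            ax.plot(grid, self.predict(grid), "-",
                    label=f"fit (η = {self.eta:.3g} cP)")
            ax.legend()
        ax.set_xlabel("MW (kDa)")
        ax.set_ylabel("D (1e-8 cm²/s)")
        return ax


def _require_unwrapped(traj: Trajectory) -> None:
    if not traj.unwrapped:
        raise ValueError(
            "MSD analysis requires unwrapped coordinates; this trajectory is "
            "wrapped. Unwrap upstream rather than relying on heuristics.")


def msd_lag(traj: Trajectory, lags, subset: np.ndarray | None = None,
            shell: ShellGeometry | None = None, region: str | None = None,
            stride_fraction: float = 0.5) -> list[MSDResult]:
    """MSD(Δt) and D(Δt) over particles and overlapping time origins.

    Parameters
    ----------
    lags : sequence of float
        Lag times in ns; each is rounded to the nearest whole number of
        frames and must fit inside the trajectory span.
    subset : bool array, optional
        Particle selection (default: all particles).
    shell, region : optional
        With ``region`` = "inside"/"outside", particles are assigned per
        time origin by radius against ``shell.R_mid`` and windows that
        straddle a crossing are discarded (see :func:`partition_by_region`).
    stride_fraction : float
        Origins advance by ``max(1, round(lag_frames*stride_fraction))``
        frames — overlapping origins for variance reduction.
    """
    _require_unwrapped(traj)
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    dt_frame = float(traj.times[1] - traj.times[0])
    if subset is None:
        subset = np.ones(traj.n_particles, dtype=bool)
    pos = traj.positions[:, subset, :]

    labels = None
    if region is not None:
        if shell is None:
            raise ValueError("region selection needs a shell geometry")
        labels = partition_by_region(traj, shell)[:, subset]

    results = []
    span = traj.times[-1] - traj.times[0]
    for lag in lags:
        if lag <= 0 or lag > span + 1e-9:
            raise ValueError(f"lag {lag} ns outside trajectory span {span} ns")
        k = max(int(round(lag / dt_frame)), 1)
        stride = max(int(round(k * stride_fraction)), 1)
        origins = np.arange(0, traj.n_frames - k, stride)
        disp = pos[origins + k] - pos[origins]             # (O, n, 3)
        sq = (disp ** 2).sum(axis=2)
        if labels is not None:
            inside_start = labels[origins]
            inside_end = labels[origins + k]
            keep = inside_start == inside_end              # drop straddlers
            want_inside = region == "inside"
            keep &= inside_start == want_inside
            vals = sq[keep]
        else:
            vals = sq.ravel()
        n_pairs = vals.size
        msd = float(vals.mean()) if n_pairs else np.nan
        actual_lag = k * dt_frame
        results.append(MSDResult(lag=actual_lag, msd=msd,
                                 D=msd / (6 * actual_lag),
                                 subset=region or "all", n_pairs=n_pairs))
    return results


def partition_by_region(traj: Trajectory, shell: ShellGeometry) -> np.ndarray:
    """Boolean (n_frames, n_particles) array: inside (radius < R_mid)?"""
    r = np.linalg.norm(traj.positions - shell.center, axis=2)
    return r < shell.R_mid


def radial_diffusion_profile(traj: Trajectory, shell: ShellGeometry,
                             r_bins, interval: float,
                             subset: np.ndarray | None = None,
                             n_blocks: int = 5):
    """D(r): Einstein diffusion binned by radial position at window start.

    Particles are assigned to radial bins (edges ``r_bins``, Å) by their
    radius at the start of each non-overlapping window of length
    ``interval`` ns; D per bin = mean squared displacement over the window
    / (6·interval). Per-bin errors are block-bootstrap standard deviations
    over ``n_blocks`` contiguous time blocks (a stand-in for independent
    replicas when only one trajectory exists). Returns (bin_centers, D,
    D_err, n per bin); empty bins are NaN.
    """
    _require_unwrapped(traj)
    dt_frame = float(traj.times[1] - traj.times[0])
    if interval < dt_frame - 1e-12:
        raise ValueError("interval must be at least the frame spacing")
    k = max(int(round(interval / dt_frame)), 1)
    if subset is None:
        subset = np.ones(traj.n_particles, dtype=bool)
    pos = traj.positions[:, subset, :]
    r_bins = np.asarray(r_bins, dtype=float)
    nb = len(r_bins) - 1

    origins = np.arange(0, traj.n_frames - k, k)
    radii = np.linalg.norm(pos[origins] - shell.center, axis=2)
    sq = ((pos[origins + k] - pos[origins]) ** 2).sum(axis=2)
    which = np.digitize(radii, r_bins) - 1                 # (O, n)

    centers = 0.5 * (r_bins[:-1] + r_bins[1:])
    D = np.full(nb, np.nan)
    D_err = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    block_of = np.minimum((np.arange(len(origins)) * n_blocks)
                          // max(len(origins), 1), n_blocks - 1)
    for b in range(nb):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b] == 0:
            continue
        D[b] = sq[sel].mean() / (6 * k * dt_frame)
        block_means = []
        for blk in range(n_blocks):
            m = sel & (block_of[:, None] == blk)
            if m.sum() > 0:
                block_means.append(sq[m].mean() / (6 * k * dt_frame))
        if len(block_means) > 1:
            D_err[b] = np.std(block_means, ddof=1) / np.sqrt(len(block_means))
    return centers, D, D_err, counts


def radial_density(traj: Trajectory, shell: ShellGeometry, r_bins,
                   subset: np.ndarray | None = None,
                   free_volume_fraction: float | None = None):
    """Probability-per-area radial profile of the selected particles.

    Counts per spherical bin are normalised by the bin mid-surface area
    4πr²Δr (per-area probability). With ``free_volume_fraction`` f given,
    interior bins (r < R_mid) are additionally divided by (1 − f) to
    correct for volume excluded by packed protein (default correction in
    the field: f = 0.20). Empty bins report 0 density (density, unlike a
    PMF, is well-defined at zero). Returns (centers, density).
    """
    if subset is None:
        subset = np.ones(traj.n_particles, dtype=bool)
    r_bins = np.asarray(r_bins, dtype=float)
    r = np.linalg.norm(traj.positions[:, subset, :] - shell.center,
                       axis=2).ravel()
    counts, _ = np.histogram(r, bins=r_bins)
    centers = 0.5 * (r_bins[:-1] + r_bins[1:])
    dr = np.diff(r_bins)
    area = 4 * np.pi * centers**2 * dr
    dens = counts / counts.sum() / area
    if free_volume_fraction is not None:
        if not 0 <= free_volume_fraction < 1:
            raise ValueError("free_volume_fraction must be in [0, 1)")
        interior = centers < shell.R_mid
        dens = dens.copy()
        dens[interior] /= (1.0 - free_volume_fraction)
    return centers, dens


# ---------------------------------------------------------------------------
# Stokes–Einstein–Sutherland

def _se_prefactor(rho: float, T: float) -> float:
    """a in D = a·MW^{-1/3}, with D in 1e-8 cm²/s and MW in kDa.

    a = k_B T/(6πη₀)·(4πρ/3)^{1/3}·(kDa→g)^{-1/3} evaluated at η₀ = 1 cP,
    in cgs throughout.
    """
    rho_factor = (4 * np.pi * rho / 3.0) ** (1 / 3)
    mw_factor = (1e3 * DALTON_G) ** (-1 / 3)     # kDa -> grams
    eta0 = 1e-2                                   # 1 cP in poise
    return K_B_CGS * T / (6 * np.pi * eta0) * rho_factor * mw_factor / 1e-8


def predict_diffusion(mw_kda, rho: float = 1.35, eta: float = 1.0,
                      T: float = 298.0):
    """Stokes–Einstein–Sutherland D for a sphere of the complex's mass.

    Parameters: MW in kDa, protein density ρ in g/cm³, viscosity η in cP,
    temperature in K. Returns D in units of 1e-8 cm²/s.
    """
    mw = np.asarray(mw_kda, dtype=float)
    if np.any(mw <= 0) or rho <= 0 or eta <= 0 or T <= 0:
        raise ValueError("all Stokes-Einstein inputs must be positive")
    return _se_prefactor(rho, T) / eta * mw ** (-1 / 3)


def stokes_einstein_fit(mw_kda, D_obs, rho: float = 1.35,
                        T: float = 298.0) -> SEFit:
    """Fit D = a·MW^(−1/3) + b and recover the viscosity from the slope.

    ``D_obs`` in 1e-8 cm²/s. Needs at least 3 distinct molecular weights.
    The constant offset b absorbs the non-Stokes behaviour seen for large
    assemblies in crowded interiors.
    """
    mw = np.asarray(mw_kda, dtype=float)
    D = np.asarray(D_obs, dtype=float)
    if len(np.unique(mw)) < 3:
        raise ValueError("need at least 3 distinct molecular weights")
    X = np.column_stack([mw ** (-1 / 3), np.ones_like(mw)])
    coef, *_ = np.linalg.lstsq(X, D, rcond=None)
    a, b = coef
    if a <= 0:
        raise ValueError("fit slope non-positive; data inconsistent with "
                         "Stokes-Einstein scaling")
    eta = _se_prefactor(rho, T) / a
    return SEFit(eta=float(eta), offset=float(b), rho=rho, T=T,
                 slope=float(a), residuals=D - X @ coef, mw_kda=mw)
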