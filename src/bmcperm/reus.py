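"""Umbrella-sampling analysis: WHAM free energies, window diffusivities,
spline fitting, and ISDM permeability integration.

The pipeline mirrors standard membrane-permeation practice: harmonically
biased windows along a 1D reaction coordinate ξ are unbiased with the
weighted histogram analysis method (WHAM) into a free-energy profile G(ξ);
a local diffusivity D(ξ) comes from the variance and position-autocorrelation
time of each window (D = var(ξ)/τ); and the inhomogeneous solubility-
diffusion model turns the two profiles into a permeability,

    P = [ ∫ exp(β G(ξ)) / D(ξ) dξ ]⁻¹ ,

integrated between stated bounds and converted to cm/s. For shells whose
pores were sampled under a cylindrical confinement of radius r, the
effective permeability of a tile of area A carrying three hexamer pores and
one trimer pore is

    P_eff = (3 P_H + P_T) · π r² / A .

Uncertainties: WHAM errors by Bayesian bootstrap (Dirichlet-weighted
resampling of each window's samples); ISDM errors by resampling G within
its standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, interpolate, optimize

from .constants import ANG_PER_NS_TO_CM_PER_S, ThermoConstants

__all__ = [
    "UmbrellaWindow",
    "FreeEnergyProfile",
    "DiffusivityProfile",
    "PoreSet",
    "wham",
    "window_diffusivity",
    "fit_profile_spline",
    "isdm_permeability",
    "effective_permeability",
    "boltzmann_inversion",
    "pmf_2d",
    "read_window_file",
    "write_window_file",
]


@dataclass
class UmbrellaWindow:
    """One harmonically biased window: U_bias(ξ) = ½ k (ξ − ξ₀)²."""

    center: float                 # ξ₀, Å
    k: float                      # kcal/mol/Å²
    samples: np.ndarray           # ξ values, Å, at fixed interval
    sample_interval: float        # ps between samples
    equil_discard: float = 0.0    # ns already removed (bookkeeping)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.k <= 0:
            raise ValueError("bias force constant must be positive")
        if self.samples.size == 0:
            raise ValueError("window has no samples after discard")

    def discard(self, equil_ns: float) -> "UmbrellaWindow":
        """Return a copy with the first ``equil_ns`` ns of samples removed."""
        n_skip = int(round(equil_ns * 1e3 / self.sample_interval))
        if n_skip >= len(self.samples):
            raise ValueError(
                f"window at {self.center}: discarding {equil_ns} ns leaves "
                "no samples")
        return UmbrellaWindow(self.center, self.k, self.samples[n_skip:],
                              self.sample_interval,
                              self.equil_discard + equil_ns)


@dataclass
class FreeEnergyProfile:
    """Gridded free energy G(ξ) in kcal/mol, anchored so min(G) = 0."""

    grid: np.ndarray
    G: np.ndarray
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("profile grid must be strictly increasing")
        self.G = self.G - np.nanmin(self.G)
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)


@dataclass
class DiffusivityProfile:
    """Gridded diffusivity D(ξ) in Å²/ns; strictly positive."""

    grid: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("profile grid must be strictly increasing")
        if np.any(self.D <= 0):
            raise ValueError("diffusivity must be positive everywhere")


@dataclass
class PoreSet:
    """Per-pore permeabilities plus the cylinder-confinement geometry."""

    P_H: float          # hexamer-pore permeability, cm/s
    P_T: float          # trimer-pore permeability, cm/s
    n_H: int = 3        # hexamer pores per tile
    r_cyl: float = 15.0  # confining-cylinder radius, Å
    A_tile: float = 16166.0  # tile surface area, Å²

    def __post_init__(self) -> None:
        if min(self.P_H, self.P_T) < 0 or min(self.r_cyl, self.A_tile) <= 0 \
                or self.n_H < 0:
            raise ValueError("PoreSet values must be positive")

    @property
    def area_fraction(self) -> float:
        """π r² / A — the single-cylinder area fraction."""
        return np.pi * self.r_cyl**2 / self.A_tile


# ---------------------------------------------------------------------------
# WHAM

def wham(windows: list[UmbrellaWindow], bin_width: float = 0.5,
         thermo: ThermoConstants = ThermoConstants(),
         equil_discard: float | None = None,
         tol: float = 1e-7, max_iter: int = 100_000,
         n_bootstrap: int = 200, seed: int = 0,
         min_count: int = 10, rel_min_count: float = 0.01,
         trim_to_centers: bool = True) -> FreeEnergyProfile:
    """Self-consistent iterative WHAM over binned window histograms.

    Parameters
    ----------
    windows : list of UmbrellaWindow
        Biased samples; adjacent windows must share occupied bins.
    bin_width : float
        Histogram bin width in Å (default 0.5 Å, matching the window spacing
        the estimator is designed for).
    equil_discard : float, optional
        Equilibration time in ns to strip from each window before analysis.
    tol : float
        Relative convergence tolerance on the window free energies.
    n_bootstrap : int
        Bayesian-bootstrap replicates for the standard error (0 disables).
    min_count, rel_min_count : int, float
        Bins with fewer total samples than max(min_count,
        rel_min_count × the best-sampled bin) are dropped: tail bins visited
        only a handful of (correlated) times otherwise acquire spuriously
        deep free energies and corrupt the min-is-zero anchor.
    trim_to_centers : bool
        Restrict the reported grid to the span of the window centers. In
        the tail beyond the outermost umbrella the bias weight varies
        steeply within a bin, so the midpoint approximation systematically
        depresses those bins; the profile is only trustworthy where windows
        are centered.

    Returns
    -------
    FreeEnergyProfile with min(G) anchored to zero and per-bin stderr.
    """
    if not windows:
        raise ValueError("no umbrella windows supplied")
    if equil_discard:
        windows = [w.discard(equil_discard) for w in windows]

    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.samples, bins=edges)[0]
                       for w in windows])          # (W, B)
    _check_overlap(windows, counts)
    total = counts.sum(axis=0)
    good = total >= max(min_count, rel_min_count * total.max())
    if trim_to_centers:
        c_lo = min(w.center for w in windows)
        c_hi = max(w.center for w in windows)
        good &= (mid >= c_lo - bin_width / 2) & (mid <= c_hi + bin_width / 2)
    if not np.any(good):
        raise ValueError("no sufficiently occupied bins inside the window span")

    beta = thermo.beta
    bias = np.stack([0.5 * w.k * (mid - w.center) ** 2 for w in windows])
    boltz = np.exp(-beta * bias)                   # (W, B)
    n_w = counts.sum(axis=1).astype(float)         # samples per window

    G = _wham_solve(counts.sum(axis=0).astype(float), n_w, boltz, beta,
                    tol, max_iter)
    G[~good] = np.nan
    G = G - np.nanmin(G)

    stderr = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        draws = np.empty((n_bootstrap, n_bins))
        for b in range(n_bootstrap):
            # Bayesian bootstrap: Dirichlet weights over each window's samples
            c_b = np.empty_like(counts, dtype=float)
            for i, w in enumerate(windows):
                wts = rng.dirichlet(np.ones(len(w.samples))) * len(w.samples)
                c_b[i] = np.histogram(w.samples, bins=edges, weights=wts)[0]
            d = _wham_solve(c_b.sum(axis=0), c_b.sum(axis=1), boltz,
                            beta, tol, max_iter)
            d[~good] = np.nan
            draws[b] = d - np.nanmin(d)
        stderr = np.full(n_bins, np.nan)
        stderr[good] = np.nanstd(draws[:, good], axis=0, ddof=1)

    finite = np.isfinite(G)
    return FreeEnergyProfile(mid[finite], G[finite],
                             stderr[finite] if stderr is not None else None)


def _wham_solve(total_counts: np.ndarray, n_w: np.ndarray,
                boltz: np.ndarray, beta: float,
                tol: float, max_iter: int) -> np.ndarray:
    """Iterate the WHAM equations; returns G per bin (kcal/mol, min 0)."""
    f = np.zeros(len(n_w))                          # window free energies, kT
    for _ in range(max_iter):
        # p_b ∝ N_b / Σ_i n_i exp(f_i) c_ib
        denom = (n_w[:, None] * np.exp(f)[:, None] * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total_counts / denom, 0.0)
        z = boltz @ p                               # (W,)
        f_new = -np.log(np.where(z > 0, z, np.nan))
        f_new -= f_new[0]
        if np.nanmax(np.abs(f_new - f) / (1.0 + np.abs(f_new))) < tol:
            f = f_new
            break
        f = f_new
    denom = (n_w[:, None] * np.exp(f)[:, None] * boltz).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where((denom > 0) & (total_counts > 0),
                     total_counts / denom, np.nan)
        G = -np.log(p) / beta
    return G - np.nanmin(G)   # provisional anchor; caller re-anchors on good bins


def _check_overlap(windows: list[UmbrellaWindow], counts: np.ndarray) -> None:
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            raise ValueError(
                "disjoint umbrella windows: no shared occupied bins between "
                f"centers {windows[a].center:g} and {windows[b].center:g} Å")


# ---------------------------------------------------------------------------
# Diffusivity from window fluctuations

def window_diffusivity(window: UmbrellaWindow,
                       thermo: ThermoConstants = ThermoConstants(),
                       acf_max_lag: float = 2.0) -> float:
    """Local diffusivity D = var(ξ)/τ_ξ from one umbrella window.

    τ_ξ is the time constant of an exponential fit to the normalized
    position autocorrelation function, restricted to lags below
    ``acf_max_lag`` (ps; default 2 ps, the effective replica-exchange
    interval, beyond which exchanges decorrelate the series artificially).

    Returns D in Å²/ns.
    """
    x = window.samples
    if len(x) < 1000:
        raise ValueError("need at least 1000 samples for a diffusivity fit")
    var = np.var(x)
    if var == 0:
        raise ValueError("window samples have zero variance")

    max_lag = max(int(acf_max_lag / window.sample_interval), 2)
    max_lag = min(max_lag, len(x) // 2)
    dx = x - x.mean()
    acf = np.array([np.mean(dx[:len(dx) - l] * dx[l:]) for l in
                    range(max_lag + 1)]) / var
    lags_ps = window.sample_interval * np.arange(max_lag + 1)

    if acf[1] >= 1.0 or np.all(acf[1:] >= acf[0]):
        raise ValueError(
            "non-decaying autocorrelation within the fit range; "
            "sample longer or reduce the sampling interval")

    tau0 = -lags_ps[1] / np.log(max(acf[1], 1e-12))
    try:
        popt, _ = optimize.curve_fit(
            lambda t, tau: np.exp(-t / tau), lags_ps, acf,
            p0=[max(tau0, lags_ps[1])], maxfev=10_000)
        tau_ps = float(popt[0])
    except RuntimeError as exc:
        raise ValueError(f"autocorrelation fit failed: {exc}") from exc
    if tau_ps <= 0 or not np.isfinite(tau_ps):
        raise ValueError("autocorrelation fit returned a non-positive "
                         "time constant; sample longer")
    return var / (tau_ps * 1e-3)   # ps -> ns


def diffusivity_profile(windows: list[UmbrellaWindow],
                        thermo: ThermoConstants = ThermoConstants(),
                        acf_max_lag: float = 2.0) -> DiffusivityProfile:
    """Evaluate :func:`window_diffusivity` per window, on the window centers."""
    centers = np.array([w.center for w in windows])
    order = np.argsort(centers)
    D = np.array([window_diffusivity(windows[i], thermo, acf_max_lag)
                  for i in order])
    return DiffusivityProfile(centers[order], D)


# ---------------------------------------------------------------------------
# Spline fitting and ISDM integration

def fit_profile_spline(x, y, stderr=None):
    """Cubic smoothing spline with GCV-selected smoothing; clamped evaluation.

    Returns a callable whose evaluations outside [min(x), max(x)] are clamped
    to the range endpoints (no extrapolation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points for a smoothing spline")
    order = np.argsort(x)
    x, y = x[order], y[order]
    w = None
    if stderr is not None:
        s = np.asarray(stderr, dtype=float)[order]
        s = np.where(s > 0, s, np.nanmax(s[s > 0]) if np.any(s > 0) else 1.0)
        w = 1.0 / s**2
    if len(x) >= 5:
        spl = interpolate.make_smoothing_spline(x, y, w=w)
    else:
        # GCV smoothing needs ≥ 5 points; 4 points pin an exact cubic
        spl = interpolate.CubicSpline(x, y)
    lo, hi = x[0], x[-1]

    def f(xi):
        return spl(np.clip(xi, lo, hi))

    f.support = (lo, hi)
    return f


def isdm_permeability(G: FreeEnergyProfile, D: DiffusivityProfile,
                      xi_lower: float, xi_upper: float,
                      thermo: ThermoConstants = ThermoConstants(),
                      n_resamples: int = 200, seed: int = 0,
                      smooth: bool = True):
    """Inhomogeneous solubility-diffusion permeability over [ξ_l, ξ_u].

    P = [∫ exp(βG(ξ))/D(ξ) dξ]⁻¹ by adaptive quadrature on spline fits of
    the two profiles, converted to cm/s. The standard error is propagated by
    resampling G within its per-bin stderr (``n_resamples`` draws, seeded).

    Returns a :class:`bmcperm.counting.PermeabilityEstimate` with
    method="isdm".
    """
    from .counting import PermeabilityEstimate

    if xi_lower >= xi_upper:
        raise ValueError("require xi_lower < xi_upper")
    for prof in (G.grid, D.grid):
        if xi_lower < prof.min() - 1e-9 or xi_upper > prof.max() + 1e-9:
            raise ValueError(
                f"profiles cover [{prof.min():g}, {prof.max():g}] Å but "
                f"integration bounds are [{xi_lower:g}, {xi_upper:g}] Å")

    if smooth and len(G.grid) >= 4:
        g_fun = fit_profile_spline(G.grid, G.G, G.stderr)
    else:
        g_fun = _interp1(G.grid, G.G)
    if smooth and len(D.grid) >= 4:
        d_fun = fit_profile_spline(D.grid, D.D)
    else:
        d_fun = _interp1(D.grid, D.D)

    beta = thermo.beta
    P = _invert_integral(g_fun, d_fun, xi_lower, xi_upper, beta)

    stderr = 0.0
    if n_resamples > 0 and G.stderr is not None and np.any(G.stderr > 0):
        rng = np.random.default_rng(seed)
        draws = np.empty(n_resamples)
        for b in range(n_resamples):
            g_b = G.G + rng.standard_normal(len(G.G)) * G.stderr
            g_b = g_b - g_b.min()
            fb = (fit_profile_spline(G.grid, g_b, G.stderr)
                  if smooth and len(G.grid) >= 4 else _interp1(G.grid, g_b))
            draws[b] = _invert_integral(fb, d_fun, xi_lower, xi_upper, beta)
        stderr = float(np.std(draws, ddof=1))

    return PermeabilityEstimate(P=P, stderr=stderr, method="isdm",
                                n_transitions=0, c=np.nan,
                                A=np.nan, t=np.nan, r=np.nan)


def _interp1(x, y):
    fi = interpolate.interp1d(x, y, kind="linear", bounds_error=False,
                              fill_value=(y[0], y[-1]))

    def f(xi):
        return fi(np.clip(xi, x[0], x[-1]))

    return f


def _invert_integral(g_fun, d_fun, lo, hi, beta) -> float:
    def integrand(xi):
        return np.exp(beta * g_fun(xi)) / d_fun(xi)

    val, _ = integrate.quad(integrand, lo, hi, epsrel=1e-8, limit=500)
    return (1.0 / val) * ANG_PER_NS_TO_CM_PER_S   # Å/ns -> cm/s


def effective_permeability(pores: PoreSet):
    """Cylinder-confinement correction for a mixed-pore tile.

    P_eff = (n_H·P_H + P_T) · π r² / A_tile. Exact arithmetic; no sampling
    error beyond what the per-pore permeabilities carry.
    """
    from .counting import PermeabilityEstimate

    P_eff = (pores.n_H * pores.P_H + pores.P_T) * pores.area_fraction
    return PermeabilityEstimate(P=float(P_eff), stderr=0.0,
                                method="isdm_effective", n_transitions=0,
                                c=np.nan, A=pores.A_tile, t=np.nan, r=np.nan)


# ---------------------------------------------------------------------------
# Equilibrium-trajectory PMFs

def boltzmann_inversion(traj, shell, cylinder_radius: float = 15.0,
                        species=("G3P", "DHAP"), bin_width: float = 0.5,
                        thermo: ThermoConstants = ThermoConstants(),
                        pore_index: int = 0) -> FreeEnergyProfile:
    """PMF along a pore axis by Boltzmann inversion of observed densities.

    Collects, over all frames, the axial coordinate z (along the chosen pore
    axis, measured from the shell mid-surface) of the selected species'
    particles lying within ``cylinder_radius`` of the pore axis, then
    G(z) = −k_BT ln p(z), anchored to min 0. Per-bin stderr assumes Poisson
    counts.
    """
    if not shell.pores:
        raise ValueError("shell geometry has no pores to align to")
    axis, _ = shell.pores[pore_index]
    mask = traj.particles.select(species=species)
    if mask.sum() == 0:
        raise ValueError(f"no particles of species {species}")

    pos = traj.positions[:, mask, :] - shell.center      # (F, n, 3)
    z = pos @ axis - shell.R_mid
    perp = pos - np.multiply.outer(pos @ axis, axis)
    t = np.linalg.norm(perp, axis=-1)
    zs = z[t <= cylinder_radius]
    if zs.size == 0:
        raise ValueError("no samples inside the pore cylinder")

    lo, hi = zs.min(), zs.max()
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(zs, bins=edges)
    mid = 0.5 * (edges[:-1] + edges[1:])
    occ = counts > 0
    with np.errstate(divide="ignore"):
        G = -thermo.kBT * np.log(counts / counts.sum() / bin_width)
    stderr = np.full(n_bins, np.nan)
    stderr[occ] = thermo.kBT / np.sqrt(counts[occ])
    return FreeEnergyProfile(mid[occ], G[occ], stderr[occ])


def pmf_2d(traj, shell, species=("G3P", "DHAP"), z_bins: int = 40,
           r_bins: int = 20, z_range=None, r_max: float | None = None,
           thermo: ThermoConstants = ThermoConstants(), pore_index: int = 0):
    """Radially reweighted 2D PMF G(z, r) around a pore axis.

    Counts per (z, r) bin are divided by the cylindrical-shell volume
    2π r Δr Δz before inversion, so a uniform 3D density yields a flat
    surface. Unvisited bins are returned as NaN (unreachable), never zero.

    Returns (z_mid, r_mid, G) with G of shape (z_bins, r_bins).
    """
    if z_bins <= 0 or r_bins <= 0:
        raise ValueError("bin counts must be positive")
    if not shell.pores:
        raise ValueError("shell geometry has no pores to align to")
    axis, _ = shell.pores[pore_index]
    mask = traj.particles.select(species=species)
    pos = traj.positions[:, mask, :] - shell.center
    z = (pos @ axis - shell.R_mid).ravel()
    perp = pos - np.multiply.outer(pos @ axis, axis)
    r = np.linalg.norm(perp, axis=-1).ravel()

    if z_range is None:
        z_range = (z.min(), z.max())
    if r_max is None:
        r_max = r.max()
    counts, z_edges, r_edges = np.histogram2d(
        z, r, bins=[z_bins, r_bins], range=[z_range, (0.0, r_max)])
    dz = z_edges[1] - z_edges[0]
    dr = r_edges[1] - r_edges[0]
    r_mid = 0.5 * (r_edges[:-1] + r_edges[1:])
    z_mid = 0.5 * (z_edges[:-1] + z_edges[1:])
    vol = 2 * np.pi * r_mid * dr * dz                    # (r_bins,)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = counts / vol[None, :]
        G = -thermo.kBT * np.log(dens)
    G[counts == 0] = np.nan
    G = G - np.nanmin(G)
    return z_mid, r_mid, G


# ---------------------------------------------------------------------------
# Window file I/O (columnar text: `# center <ξ₀> k <k>`, rows time_ps,xi_A)

def write_window_file(window: UmbrellaWindow, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# center {window.center:.9g} k {window.k:.9g}\n")
        fh.write("time_ps,xi_A\n")
        t = window.sample_interval * np.arange(len(window.samples))
        for ti, xi in zip(t, window.samples):
            fh.write(f"{ti:.6f},{xi:.6f}\n")


def read_window_file(path) -> UmbrellaWindow:
    import pandas as pd

    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("# center"):
        raise ValueError(f"window file {path} missing '# center ... k ...' header")
    parts = header.split()
    center, k = float(parts[2]), float(parts[4])
    df = pd.read_csv(path, skiprows=1)
    t = df["time_ps"].to_numpy()
    interval = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return UmbrellaWindow(center, k, df["xi_A"].to_numpy(), interval)
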