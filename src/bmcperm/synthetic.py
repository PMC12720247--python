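"""Ground-truth-known synthetic inputs for every analysis stage.

Three generators emulate, at desk scale, the data the analyses were designed
for:

* :func:`gen_shell_bd` — point solutes diffusing across a spherical shell
  pierced by circular pores, evolved by overdamped Euler–Maruyama Langevin
  dynamics on a radial Gaussian barrier with position-dependent diffusivity
  (the spurious-drift term ∇D is included so the stationary distribution is
  the Boltzmann one).
* :func:`gen_umbrella_windows` — harmonically biased 1D window sampling on a
  stated free-energy/diffusivity profile, the input WHAM expects.
* :func:`gen_cargo_frames` — pseudo-protein complexes drifting with pairwise
  attraction inside a confining sphere, which cluster over time and feed the
  contact-network and nearest-neighbor analyses.

Because the generating profiles are known analytically,
:func:`analytic_pore_permeability` provides an exact oracle for what the
downstream counting and ISDM estimators should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .constants import ANG_PER_NS_TO_CM_PER_S, ThermoConstants
from .reus import UmbrellaWindow
from .trajectory import ParticleSet, ShellGeometry, Trajectory

__all__ = [
    "ShellBDParams",
    "UmbrellaSpec",
    "CargoSpec",
    "gen_shell_bd",
    "analytic_pore_permeability",
    "gen_umbrella_windows",
    "gen_cargo_frames",
]

#: Width of the cosine switch gating the barrier off inside pores, Å.
PORE_SWITCH_WIDTH = 2.0


@dataclass(frozen=True)
class ShellBDParams:
    """Parameters of the shell-permeation Brownian-dynamics generator.

    The shell is a radial Gaussian barrier of height ``barrier_height``
    (kcal/mol) and width ``barrier_width`` (Å, Gaussian sigma) centered at
    ``shell_radius``, switched smoothly to zero inside cones around each
    pore axis out to ``pore_radius`` (transverse distance). Diffusivity
    interpolates radially between ``D_free`` (bulk) and ``D_shell`` (inside
    the barrier region) with the same Gaussian envelope.
    """

    shell_radius: float = 30.0          # Å
    pore_axes: tuple = ()               # unit vectors
    pore_radius: float = 3.0            # Å
    barrier_height: float = 3.0         # kcal/mol
    barrier_width: float = 3.0          # Å (Gaussian sigma)
    D_free: float = 100.0               # Å²/ns
    D_shell: float = 100.0              # Å²/ns
    n_solutes: int = 500
    box_edge: float = 100.0             # Å
    dt: float = 0.002                   # ns
    n_steps: int = 100_000
    seed: int = 0
    save_stride: int = 10               # frames saved every this many steps

    def __post_init__(self) -> None:
        if self.pore_radius >= self.shell_radius:
            raise ValueError("pore_radius must be smaller than shell_radius")
        if self.D_free <= 0 or self.D_shell <= 0:
            raise ValueError("diffusivities must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be non-negative")
        if self.n_solutes < 1 or self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("counts must be positive")
        d_max = max(self.D_free, self.D_shell)
        step = np.sqrt(6 * d_max * self.dt)
        if self.pore_radius > 0 and len(self.pore_axes) > 0 \
                and step > self.pore_radius / 2:
            raise ValueError(
                f"dt={self.dt} ns is unstable: rms displacement per step "
                f"{step:.2f} Å exceeds pore_radius/2 = {self.pore_radius / 2:.2f} Å")

    @property
    def axes(self) -> np.ndarray:
        if len(self.pore_axes) == 0:
            return np.zeros((0, 3))
        a = np.asarray(self.pore_axes, dtype=float)
        return a / np.linalg.norm(a, axis=1, keepdims=True)


def tetrahedral_axes() -> tuple:
    """Four symmetric pore axes (vertices of a tetrahedron)."""
    s = 1 / np.sqrt(3)
    return ((s, s, s), (s, -s, -s), (-s, s, -s), (-s, -s, s))


@dataclass(frozen=True)
class UmbrellaSpec:
    """Specification for synthetic harmonically biased window sampling."""

    profile_G: object                  # callable ξ -> kcal/mol
    profile_D: object                  # callable ξ -> Å²/ns
    window_centers: tuple              # Å, strictly increasing
    k_bias: float = 5.0                # kcal/mol/Å²
    n_samples: int = 20_000            # per window
    sample_interval: float = 0.2       # ps
    equil_discard: float = 0.05        # ns
    seed: int = 0
    T: float = 298.0

    def __post_init__(self) -> None:
        centers = np.asarray(self.window_centers, dtype=float)
        if len(centers) == 0 or (len(centers) > 1
                                 and not np.all(np.diff(centers) > 0)):
            raise ValueError("window_centers must be non-empty and "
                             "strictly increasing")
        if self.k_bias <= 0:
            raise ValueError("k_bias must be positive")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass(frozen=True)
class CargoSpec:
    """Specification for the clustering pseudo-protein cargo generator."""

    n_complexes: int = 20
    complex_radii: float = 8.0          # Å
    sites_per_complex: int = 5
    attraction_strength: float = 2.0    # kcal/mol
    confinement_radius: float = 120.0   # Å
    dt: float = 0.5                     # ns
    n_frames: int = 100
    D_cargo: float = 2.0                # Å²/ns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.complex_radii <= 0 or self.confinement_radius <= 0:
            raise ValueError("all radii must be positive")
        if self.n_complexes < 2:
            raise ValueError("need at least 2 complexes")


# ---------------------------------------------------------------------------
# Shell BD generator

def _barrier_envelope(r, params: ShellBDParams):
    """Radial Gaussian envelope exp(-(r-R)²/(2w²)) and its r-derivative."""
    u = (r - params.shell_radius) / params.barrier_width
    env = np.exp(-0.5 * u * u)
    denv = -u / params.barrier_width * env
    return env, denv


def _pore_gates(pos, r, axes, params: ShellBDParams):
    """Per-pore switch s_p(t) in [0,1] (0 = open pore) and gradient pieces.

    Returns (gates (P, n), dgate_dt (P, n), perp_unit (P, n, 3)).
    """
    n = pos.shape[0]
    n_p = len(axes)
    gates = np.ones((n_p, n))
    dgates = np.zeros((n_p, n))
    perp_unit = np.zeros((n_p, n, 3))
    rp, ws = params.pore_radius, PORE_SWITCH_WIDTH
    for p, a in enumerate(axes):
        proj = pos @ a
        perp = pos - np.multiply.outer(proj, a)
        t = np.linalg.norm(perp, axis=1)
        near = proj > 0          # pores are one-sided along +axis
        inside = near & (t <= rp)
        switch = near & (t > rp) & (t < rp + ws)
        gates[p, inside] = 0.0
        arg = np.pi * (t[switch] - rp) / ws
        gates[p, switch] = 0.5 * (1 - np.cos(arg))
        dgates[p, switch] = 0.5 * np.pi / ws * np.sin(arg)
        tt = np.where(t > 1e-12, t, 1.0)
        perp_unit[p] = perp / tt[:, None]
    return gates, dgates, perp_unit


def _forces_and_D(pos, params: ShellBDParams, axes):
    """Potential force -∇U, diffusivity D and its gradient ∇D at positions."""
    n = pos.shape[0]
    r = np.linalg.norm(pos, axis=1)
    r_safe = np.where(r > 1e-12, r, 1.0)
    rhat = pos / r_safe[:, None]

    env, denv = _barrier_envelope(r, params)
    dD = params.D_shell - params.D_free
    D = params.D_free + dD * env
    gradD = (dD * denv)[:, None] * rhat

    F = np.zeros_like(pos)
    H = params.barrier_height
    if H > 0:
        if len(axes) > 0:
            gates, dgates, perp_unit = _pore_gates(pos, r, axes, params)
            gate = np.prod(gates, axis=0)
            # -H * env * ∇gate, with ∇gate by product rule over pores
            for p in range(len(axes)):
                others = np.prod(np.delete(gates, p, axis=0), axis=0) \
                    if len(axes) > 1 else np.ones(n)
                F -= (H * env * others * dgates[p])[:, None] * perp_unit[p]
        else:
            gate = np.ones(n)
        # -H * gate * d(env)/dr * rhat
        F -= (H * gate * denv)[:, None] * rhat
    return F, D, gradD


def gen_shell_bd(params: ShellBDParams,
                 thermo: ThermoConstants = ThermoConstants()
                 ) -> tuple[Trajectory, ShellGeometry]:
    """Brownian-dynamics trajectory of solutes permeating a porous shell.

    Overdamped Euler–Maruyama update with position-dependent diffusivity:

        x += [β D(x) F(x) + ∇D(x)] dt + sqrt(2 D(x) dt) ξ,   ξ ~ N(0, I)

    Solutes start uniformly in the box, are reflected at the box faces
    (keeping inside/outside bookkeeping unambiguous) and carry an
    ``initially_inside`` label. Coordinates are unwrapped by construction.
    """
    rng = np.random.default_rng(params.seed)
    axes = params.axes
    half = params.box_edge / 2.0
    beta = thermo.beta

    pos = rng.uniform(-half, half, size=(params.n_solutes, 3))
    initially_inside = np.linalg.norm(pos, axis=1) < params.shell_radius

    n_saved = params.n_steps // params.save_stride + 1
    saved = np.empty((n_saved, params.n_solutes, 3))
    times = np.empty(n_saved)
    saved[0] = pos
    times[0] = 0.0
    k = 1

    sq2dt = np.sqrt(2 * params.dt)
    for step in range(1, params.n_steps + 1):
        F, D, gradD = _forces_and_D(pos, params, axes)
        noise = rng.standard_normal(pos.shape)
        pos = pos + (beta * D[:, None] * F + gradD) * params.dt \
            + sq2dt * np.sqrt(D)[:, None] * noise
        # reflecting walls at the box faces
        pos = np.where(pos > half, 2 * half - pos, pos)
        pos = np.where(pos < -half, -2 * half - pos, pos)
        if step % params.save_stride == 0:
            saved[k] = pos
            times[k] = step * params.dt
            k += 1

    particles = ParticleSet(
        particle_id=np.arange(params.n_solutes),
        species=np.full(params.n_solutes, "pseudo", dtype=object),
        role=np.full(params.n_solutes, "metabolite", dtype=object),
        complex_id=np.full(params.n_solutes, -1),
        is_calpha=np.zeros(params.n_solutes, dtype=bool),
        coordinates=saved[0],
    )
    particles.initially_inside = initially_inside

    traj = Trajectory(times[:k], saved[:k],
                      np.full(3, params.box_edge), True, particles)
    R = params.shell_radius
    shell = ShellGeometry(
        center=np.zeros(3), R_mid=R, R_in=R - 10.0, R_out=R + 10.0,
        A=4 * np.pi * R**2,
        pores=[(a, params.pore_radius) for a in axes])
    return traj, shell


def analytic_pore_permeability(params: ShellBDParams,
                               thermo: ThermoConstants = ThermoConstants(),
                               integration_halfwidth: float = 10.0,
                               pore_area_fraction: float | None = None
                               ) -> float:
    """Exact permeability of the generating model, in cm/s.

    Applies the solubility-diffusion integral to the generating profiles.
    The shell surface is partitioned by the local pore switch value s: the
    local (per-area) permeability at switch value s is

        P_loc(s) = [ ∫ exp(β·s·G(ξ)) / D(ξ) dξ ]⁻¹

    over ξ ∈ [R − h, R + h] (h = ``integration_halfwidth``, matching the
    hysteresis band the counting estimator uses), and the total permeability
    is the area-weighted sum of the open-pore, switch-annulus and full-barrier
    contributions. With ``pore_area_fraction`` given, the simple two-term
    form f·P_loc(0) + (1−f)·P_loc(1) is used instead of the pore geometry.

    Quadrature relative tolerance 1e-8.
    """
    beta = thermo.beta
    R, H = params.shell_radius, params.barrier_height
    lo, hi = R - integration_halfwidth, R + integration_halfwidth

    def p_loc(s: float) -> float:
        def integrand(xi):
            env = np.exp(-0.5 * ((xi - R) / params.barrier_width) ** 2)
            D = params.D_free + (params.D_shell - params.D_free) * env
            return np.exp(beta * s * H * env) / D

        val, _ = integrate.quad(integrand, lo, hi, epsrel=1e-8, limit=500)
        return 1.0 / val

    if pore_area_fraction is not None:
        f = pore_area_fraction
        P = f * p_loc(0.0) + (1 - f) * p_loc(1.0)
        return P * ANG_PER_NS_TO_CM_PER_S

    A = 4 * np.pi * R**2
    axes = params.axes
    rp, ws = params.pore_radius, PORE_SWITCH_WIDTH
    open_area = len(axes) * np.pi * rp**2

    # switch annulus: integrate P_loc(s(t)) 2πt dt over t in [rp, rp+ws]
    annulus = 0.0
    if len(axes) > 0 and H > 0:
        def ann_integrand(t):
            s = 0.5 * (1 - np.cos(np.pi * (t - rp) / ws))
            return p_loc(s) * 2 * np.pi * t

        annulus, _ = integrate.quad(ann_integrand, rp, rp + ws,
                                    epsrel=1e-6, limit=200)
        annulus *= len(axes)
    elif len(axes) > 0:
        annulus = len(axes) * np.pi * ((rp + ws) ** 2 - rp**2) * p_loc(1.0)

    closed_area = A - len(axes) * np.pi * (rp + ws) ** 2
    P = (open_area * p_loc(0.0) + annulus + closed_area * p_loc(1.0)) / A
    return P * ANG_PER_NS_TO_CM_PER_S


# ---------------------------------------------------------------------------
# Umbrella windows

def _vectorized(fun):
    """Wrap a scalar-or-array profile callable to always return float arrays."""
    def f(x):
        x = np.asarray(x, dtype=float)
        out = fun(x)
        out = np.asarray(out, dtype=float)
        if out.shape != x.shape:
            out = np.array([fun(float(xi)) for xi in np.atleast_1d(x)],
                           dtype=float).reshape(x.shape)
        return out
    return f


def gen_umbrella_windows(spec: UmbrellaSpec) -> list[UmbrellaWindow]:
    """Biased BD sampling of U(ξ) = G(ξ) + ½k(ξ−ξ₀)² per window.

    All windows evolve in parallel (they are independent; no replica
    exchange). The integration substep is chosen well below the harmonic
    relaxation time β·k·D so the Euler discretisation bias on the window
    variance stays below ~2%.
    """
    thermo = ThermoConstants(spec.T)
    beta = thermo.beta
    centers = np.asarray(spec.window_centers, dtype=float)
    n_w = len(centers)
    rng = np.random.default_rng(spec.seed)

    G_fun = _vectorized(spec.profile_G)
    D_fun = _vectorized(spec.profile_D)
    h = 1e-4

    def dG(x):
        return (G_fun(x + h) - G_fun(x - h)) / (2 * h)

    def dD(x):
        return (D_fun(x + h) - D_fun(x - h)) / (2 * h)

    interval_ns = spec.sample_interval * 1e-3
    d_typ = float(np.max(D_fun(centers)))
    dt_max = 0.02 / (beta * spec.k_bias * d_typ)
    n_sub = max(int(np.ceil(interval_ns / dt_max)), 1)
    dt = interval_ns / n_sub

    x = centers.copy()
    n_equil = int(round(spec.equil_discard / interval_ns))
    total = n_equil + spec.n_samples
    samples = np.empty((spec.n_samples, n_w))

    sq2dt = np.sqrt(2 * dt)
    for i in range(total):
        for _ in range(n_sub):
            D = D_fun(x)
            force = -(dG(x) + spec.k_bias * (x - centers))
            x = x + (beta * D * force + dD(x)) * dt \
                + sq2dt * np.sqrt(D) * rng.standard_normal(n_w)
        if i >= n_equil:
            samples[i - n_equil] = x

    return [UmbrellaWindow(center=float(centers[j]), k=spec.k_bias,
                           samples=samples[:, j],
                           sample_interval=spec.sample_interval,
                           equil_discard=spec.equil_discard)
            for j in range(n_w)]


# ---------------------------------------------------------------------------
# Clustering cargo

def gen_cargo_frames(spec: CargoSpec) -> Trajectory:
    """Pseudo-protein complexes drifting with pairwise attraction.

    Each complex is a rigid cluster of ``sites_per_complex`` pseudo-Cα sites
    sharing a complex_id. Complex centers follow overdamped BD with a
    pairwise attraction of well depth ``attraction_strength`` (kcal/mol,
    range ~confinement_radius/3) plus a soft-core repulsion at contact, and
    are reflected at the confining sphere. With positive attraction, later
    frames are measurably more clustered than early ones.
    """
    rng = np.random.default_rng(spec.seed)
    thermo = ThermoConstants()
    beta = thermo.beta
    n_c, m = spec.n_complexes, spec.sites_per_complex
    R_conf = spec.confinement_radius
    contact = 2 * spec.complex_radii
    lam = max(R_conf / 3.0, contact)

    centers = rng.uniform(-R_conf / np.sqrt(3), R_conf / np.sqrt(3),
                          size=(n_c, 3))
    offsets = rng.standard_normal((n_c, m, 3))
    offsets *= spec.complex_radii / np.linalg.norm(offsets, axis=2,
                                                   keepdims=True)

    positions = np.empty((spec.n_frames, n_c * m, 3))
    times = spec.dt * np.arange(spec.n_frames)
    sq2dt = np.sqrt(2 * spec.D_cargo * spec.dt)
    eps = spec.attraction_strength

    for f in range(spec.n_frames):
        positions[f] = (centers[:, None, :] + offsets).reshape(-1, 3)
        if f == spec.n_frames - 1:
            break
        diff = centers[None, :, :] - centers[:, None, :]   # j - i
        d = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(d, 1.0)                           # masked below
        unit = diff / d[..., None]
        gap = d - contact
        # attraction -dV/dr with V = -eps*exp(-(d-contact)/lam): pull toward j
        att = (eps / lam) * np.exp(-np.maximum(gap, 0.0) / lam)
        rep = -0.5 * np.maximum(-gap, 0.0)                 # soft-core push
        fmag = np.where(gap > 0, att, rep)
        np.fill_diagonal(fmag, 0.0)
        F = (fmag[..., None] * unit).sum(axis=1)
        centers = centers + beta * spec.D_cargo * F * spec.dt \
            + sq2dt * rng.standard_normal((n_c, 3))
        rad = np.linalg.norm(centers, axis=1)
        over = rad > R_conf
        if np.any(over):
            centers[over] *= ((2 * R_conf - rad[over]) / rad[over])[:, None]

    particles = ParticleSet(
        particle_id=np.arange(n_c * m),
        species=np.full(n_c * m, "pseudo", dtype=object),
        role=np.full(n_c * m, "cargo", dtype=object),
        complex_id=np.repeat(np.arange(n_c), m),
        is_calpha=np.ones(n_c * m, dtype=bool),
        coordinates=positions[0],
    )
    return Trajectory(times, positions, np.zeros(3), True, particles)
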