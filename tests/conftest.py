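"""Shared fixtures: expensive synthetic runs are session-scoped so the
permeation trajectory and umbrella windows are generated once and reused."""

from __future__ import annotations

import numpy as np
import pytest

from bmcperm import (CargoSpec, ShellBDParams, UmbrellaSpec, gen_cargo_frames,
                     gen_shell_bd, gen_umbrella_windows, tetrahedral_axes)


def double_well(x):
    """Two Gaussian wells at ±3 Å, ~1.8 kcal/mol barrier between them."""
    x = np.asarray(x, dtype=float)
    return -2.0 * (np.exp(-(x + 3) ** 2 / 2.88) + np.exp(-(x - 3) ** 2 / 2.88))


def flat_G(x):
    return 0.0 * np.asarray(x, dtype=float)


def const_D(value=70.0):
    return lambda x: value + 0.0 * np.asarray(x, dtype=float)


WINDOW_CENTERS = tuple(np.linspace(-6.0, 6.0, 24))


@pytest.fixture(scope="session")
def shell_bd_run():
    """Permeation BD run at the standard study conditions (4 pores, 3 kcal/mol
    barrier, 500 solutes, 1e5 steps, seed 7)."""
    params = ShellBDParams(shell_radius=30.0, pore_axes=tetrahedral_axes(),
                           pore_radius=3.0, barrier_height=3.0,
                           barrier_width=3.0, D_free=100.0, D_shell=100.0,
                           n_solutes=500, box_edge=100.0, dt=0.002,
                           n_steps=100_000, seed=7, save_stride=10)
    traj, shell = gen_shell_bd(params)
    return params, traj, shell


@pytest.fixture(scope="session")
def free_bd_run():
    """Barrier-free uniform-diffusivity run for MSD ground-truth checks."""
    params = ShellBDParams(shell_radius=30.0, pore_axes=(), pore_radius=3.0,
                           barrier_height=0.0, D_free=100.0, D_shell=100.0,
                           n_solutes=1000, box_edge=600.0, dt=0.002,
                           n_steps=2000, seed=1, save_stride=5)
    traj, shell = gen_shell_bd(params)
    return params, traj, shell


@pytest.fixture(scope="session")
def double_well_windows():
    """24 umbrella windows sampled on the double-well profile."""
    spec = UmbrellaSpec(profile_G=double_well, profile_D=const_D(70.0),
                        window_centers=WINDOW_CENTERS, k_bias=5.0,
                        n_samples=10_000, sample_interval=2.0,
                        equil_discard=0.05, seed=5)
    return spec, gen_umbrella_windows(spec)


@pytest.fixture(scope="session")
def flat_windows():
    spec = UmbrellaSpec(profile_G=flat_G, profile_D=const_D(70.0),
                        window_centers=WINDOW_CENTERS, k_bias=5.0,
                        n_samples=10_000, sample_interval=2.0,
                        equil_discard=0.05, seed=4)
    return spec, gen_umbrella_windows(spec)


@pytest.fixture(scope="session")
def cargo_runs():
    """Clustering (attraction on) and drifting (attraction off) cargo runs."""
    on = gen_cargo_frames(CargoSpec(n_complexes=20, attraction_strength=2.0,
                                    seed=3))
    off = gen_cargo_frames(CargoSpec(n_complexes=20, attraction_strength=0.0,
                                     seed=3))
    return on, off


def fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Evenly spread points on a sphere (Fibonacci lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z * z)
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
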