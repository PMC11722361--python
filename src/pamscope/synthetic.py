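"""Synthetic-data generators with closed-form ground truth.

Every pipeline stage in this package has a matching generator here whose
statistical structure is known exactly, so estimators can be validated by
plant-and-recover: correlated binary contact series (two-state Markov
chains), multivariate Gaussian atomic ensembles with planted covariance,
probe-site trajectories with scheduled contact episodes, analytic
double-well CV landscapes, and harmonic lambda-state sample sets with
analytic free-energy differences.  All generators are deterministic given
their seed and echo their parameters in the returned ground-truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .alchemy import ReducedPotentialMatrix
from .contacts import ContactSeries, PairEnergySeries
from .metadynamics import ToySystem, Wall, wall_potential
from .structure import StructureModel, TrajectoryEnsemble
from .units import KB


# ---------------------------------------------------------------------------
# Correlated binary series
# ---------------------------------------------------------------------------

def markov_chain_parameters(p: float, tau: float, dt: float) -> tuple[float, float]:
    """Flip probabilities (alpha: 0->1, beta: 1->0) of a two-state chain
    with stationary occupancy p and integrated autocorrelation time tau.

    The chain's autocorrelation is rho(k) = mu^k with second eigenvalue
    mu = 1 - alpha - beta, giving integrated time
    tau = dt * (1/2 + mu/(1 - mu)); inverting, mu = (r - 1/2)/(r + 1/2)
    with r = tau/dt.  tau <= dt/2 maps to mu = 0, i.e. i.i.d. sampling.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("stationary occupancy must lie strictly in (0, 1)")
    if tau < 0:
        raise ValueError("autocorrelation time must be non-negative")
    r = tau / dt
    mu = 0.0 if r <= 0.5 else (r - 0.5) / (r + 0.5)
    alpha = (1.0 - mu) * p
    beta = (1.0 - mu) * (1.0 - p)
    if not (0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0):
        raise ValueError(f"infeasible (p={p}, tau={tau}) combination")
    return alpha, beta


def gen_markov_binary_batch(
    p: float, tau: float, n: int, n_series: int, dt: float = 1.0, seed: int = 0
) -> np.ndarray:
    """(n_series, n) correlated binary series, initialized at stationarity."""
    alpha, beta = markov_chain_parameters(p, tau, dt)
    rng = np.random.default_rng(seed)
    out = np.empty((n_series, n), dtype=np.int8)
    state = (rng.random(n_series) < p).astype(np.int8)
    out[:, 0] = state
    u = rng.random((n_series, n - 1))
    for t in range(1, n):
        flip_up = (state == 0) & (u[:, t - 1] < alpha)
        flip_dn = (state == 1) & (u[:, t - 1] < beta)
        state = np.where(flip_up, 1, np.where(flip_dn, 0, state)).astype(np.int8)
        out[:, t] = state
    return out


def gen_markov_binary(
    p: float, tau: float, n: int, dt: float = 1.0, seed: int = 0,
    pair_id: str = "synthetic-markov",
) -> tuple[ContactSeries, dict]:
    """One correlated binary contact series plus its ground-truth record."""
    series = gen_markov_binary_batch(p, tau, n, 1, dt, seed)[0]
    truth = {
        "generator": "gen_markov_binary", "p": p, "tau": tau, "n": n,
        "dt": dt, "seed": seed,
        "tau_integrated": max(tau, dt / 2.0),
    }
    return ContactSeries(pair_id, series, frame_interval=dt), truth


# ---------------------------------------------------------------------------
# Gaussian atomic ensembles
# ---------------------------------------------------------------------------

def _synthetic_structure(masses: np.ndarray, spacing: float = 1.0) -> StructureModel:
    n = len(masses)
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return StructureModel(
        atom_id=np.arange(1, n + 1),
        atom_name=np.array([f"X{i+1}" for i in range(n)], dtype=object),
        element=np.array(["C"] * n, dtype=object),
        residue_number=np.ones(n, dtype=int),
        residue_name=np.array(["SYN"] * n, dtype=object),
        chain_id=np.array(["A"] * n, dtype=object),
        mass=np.asarray(masses, dtype=float),
        coordinates=coords,
    )


def gen_gaussian_ensemble(
    covariance: np.ndarray,
    masses: Sequence[float],
    n: int,
    seed: int = 0,
    frame_interval: float = 1.0,
) -> tuple[TrajectoryEnsemble, dict]:
    """i.i.d. frames from a multivariate Gaussian around a fixed structure.

    ``covariance`` is the (3N x 3N) coordinate covariance in nm^2 (a 1-D
    array is taken as its diagonal).  The ground truth carries the planted
    mass-weighted covariance eigenvalues (amu*nm^2), from which the
    quasi-harmonic entropy follows in closed form via
    :func:`pamscope.conformation.entropy_from_eigenvalues`.
    """
    masses = np.asarray(masses, dtype=float)
    n_dof = 3 * len(masses)
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim == 1:
        if len(cov) != n_dof:
            raise ValueError("diagonal covariance must have 3N entries")
        cov = np.diag(cov)
    if cov.shape != (n_dof, n_dof):
        raise ValueError("covariance must be 3N x 3N")
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric")
    eigval = np.linalg.eigvalsh(cov)
    if eigval.min() < -1e-12 * max(eigval.max(), 1.0):
        raise ValueError("covariance must be positive semi-definite")

    structure = _synthetic_structure(masses)
    rng = np.random.default_rng(seed)
    mean = structure.coordinates.ravel()
    if np.count_nonzero(cov) == 0:
        frames = np.tile(mean, (n, 1))
    else:
        frames = rng.multivariate_normal(mean, cov, size=n, method="cholesky" if
                                         eigval.min() > 0 else "eigh")
    traj = TrajectoryEnsemble(
        reference=structure,
        frames=frames.reshape(n, len(masses), 3),
        frame_interval=frame_interval,
        source_label="gen_gaussian_ensemble",
    )
    sqrt_m = np.sqrt(np.repeat(masses, 3))
    mw_cov = cov * np.outer(sqrt_m, sqrt_m)
    truth = {
        "generator": "gen_gaussian_ensemble", "n": n, "seed": seed,
        "masses": masses.tolist(),
        "mass_weighted_eigenvalues": np.linalg.eigvalsh(mw_cov)[::-1],
    }
    return traj, truth


# ---------------------------------------------------------------------------
# Probe-site trajectories with planted contact episodes
# ---------------------------------------------------------------------------

@dataclass
class Episode:
    """A planted contact episode: the probe sits at ``category``'s site for
    frames [start, end).  ``strong_energy=False`` plants a near-miss that
    satisfies the distance criterion but not the energy criterion."""

    category: str            # 'base' | 'phosphate' | 'non-PAM'
    start: int
    end: int
    strong_energy: bool = True


_SITE_CENTERS = {"base": 0.0, "phosphate": 2.0, "non-PAM": 4.0}  # x offset, nm
_CONTACT_DISTANCE = {"base": 0.40, "phosphate": 0.35, "non-PAM": 0.40}
_STRONG_ENERGY = {"base": -150.0, "phosphate": -400.0, "non-PAM": -150.0}
_WEAK_ENERGY = -10.0
_NEUTRAL_PROBE = np.array([1.0, 1.5, 0.0])


def gen_probe_trajectory(
    episodes: Sequence[Episode],
    n: int,
    seed: int = 0,
    frame_interval: float = 1.0,
    noise: float = 0.02,
) -> tuple[TrajectoryEnsemble, dict[str, PairEnergySeries], dict]:
    """Probe trajectory alternating among base / phosphate / non-PAM sites.

    During an episode the probe satisfies the dual contact criteria of its
    site category (distance within cutoff, energy beyond threshold); outside
    episodes (and during weak-energy episodes, on the energy side) it
    satisfies neither.  Ground truth records the exact planted per-category
    occupancies.
    """
    episodes = sorted(episodes, key=lambda e: e.start)
    for a, b in zip(episodes, episodes[1:]):
        if a.end > b.start:
            raise ValueError("episode schedule overlaps")
    if episodes and (episodes[0].start < 0 or episodes[-1].end > n):
        raise ValueError("episodes must lie within the frame range")

    rng = np.random.default_rng(seed)
    # probe (1 atom) + three 2-atom sites
    masses = np.array([14.0, 12.0, 12.0, 31.0, 16.0, 12.0, 12.0])
    structure = _synthetic_structure(masses)
    names = np.array(["PRB", "NB1", "NB2", "P", "OP1", "NP1", "NP2"], dtype=object)
    structure.atom_name = names
    base_coords = np.zeros((7, 3))
    base_coords[1] = [_SITE_CENTERS["base"] - 0.05, 0, 0]
    base_coords[2] = [_SITE_CENTERS["base"] + 0.05, 0, 0]
    base_coords[3] = [_SITE_CENTERS["phosphate"] - 0.05, 0, 0]
    base_coords[4] = [_SITE_CENTERS["phosphate"] + 0.05, 0, 0]
    base_coords[5] = [_SITE_CENTERS["non-PAM"] - 0.05, 0, 0]
    base_coords[6] = [_SITE_CENTERS["non-PAM"] + 0.05, 0, 0]
    structure.coordinates = base_coords.copy()

    site_com = {
        "base": base_coords[1:3].mean(axis=0),
        "phosphate": base_coords[3:5].mean(axis=0),
        "non-PAM": base_coords[5:7].mean(axis=0),
    }
    # site COMs are mass-weighted means of equal/unequal masses
    site_com["phosphate"] = (
        base_coords[3] * masses[3] + base_coords[4] * masses[4]
    ) / (masses[3] + masses[4])

    frames = np.tile(base_coords, (n, 1, 1))
    probe_pos = np.tile(_NEUTRAL_PROBE, (n, 1))
    energies = {cat: np.full(n, _WEAK_ENERGY) + rng.uniform(-2, 2, n)
                for cat in _SITE_CENTERS}
    occupancy = {cat: np.zeros(n, dtype=np.int8) for cat in _SITE_CENTERS}

    for ep in episodes:
        if ep.category not in _SITE_CENTERS:
            raise ValueError(f"unknown episode category {ep.category!r}")
        span = slice(ep.start, ep.end)
        m = ep.end - ep.start
        direction = rng.standard_normal((m, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radius = _CONTACT_DISTANCE[ep.category] + rng.uniform(-noise, noise, m)
        probe_pos[span] = site_com[ep.category] + direction * radius[:, None]
        if ep.strong_energy:
            level = _STRONG_ENERGY[ep.category]
            energies[ep.category][span] = level + rng.uniform(-10, 10, m)
            occupancy[ep.category][span] = 1
        else:
            energies[ep.category][span] = _WEAK_ENERGY + rng.uniform(-2, 2, m)
    frames[:, 0, :] = probe_pos

    traj = TrajectoryEnsemble(
        reference=structure, frames=frames,
        frame_interval=frame_interval, source_label="gen_probe_trajectory",
    )
    pair_series = {
        cat: PairEnergySeries(
            pair_id=f"PRB-{cat}",
            category="phosphate" if cat == "phosphate" else "base",
            energies=energies[cat],
            frame_interval=frame_interval,
        )
        for cat in _SITE_CENTERS
    }
    truth = {
        "generator": "gen_probe_trajectory", "n": n, "seed": seed,
        "noise": noise,
        "occupancy": {cat: float(occ.mean()) for cat, occ in occupancy.items()},
        "occupancy_series": occupancy,
        "site_atom_indices": {"probe": [0], "base": [1, 2],
                              "phosphate": [3, 4], "non-PAM": [5, 6]},
    }
    return traj, pair_series, truth


# ---------------------------------------------------------------------------
# Analytic double-well CV landscape
# ---------------------------------------------------------------------------

def analytic_double_well(
    a: float = 2.5,
    dimension: int = 1,
    mass: float = 1.0,
    friction: float = 2.0,
    temperature: float = 300.0,
) -> ToySystem:
    """Separable double well V(x) = a * sum_i (x_i^2 - 1)^2, barrier a.

    Minima at x_i = +/-1 with curvature V'' = 8a; the barrier top at the
    origin has height exactly ``a`` per dimension.
    """
    if a <= 0:
        raise ValueError("well parameter a must be positive")

    def potential(x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return (a * (x**2 - 1.0) ** 2).sum(axis=1)

    def gradient(x: np.ndarray) -> np.ndarray:
        x2 = np.atleast_2d(x)
        g = 4.0 * a * x2 * (x2**2 - 1.0)
        return g if np.ndim(x) > 1 else g[0]

    return ToySystem(
        potential=potential,
        gradient=gradient,
        mass=mass,
        friction=friction,
        temperature=temperature,
        x0=tuple([-1.0] * dimension),
        domain=tuple([(-2.0, 2.0)] * dimension),
    )


def boltzmann_reference_fes(
    system: ToySystem,
    grid: np.ndarray,
    walls: Sequence[Wall] = (),
    temperature: float | None = None,
) -> np.ndarray:
    """Reference 1-D free energy F(x) = -kB*T ln p(x), min shifted to 0.

    p(x) is the Boltzmann density of the system potential plus walls on the
    given grid; for an identity CV this is the exact surface a converged
    metadynamics run should recover.
    """
    t = system.temperature if temperature is None else temperature
    pts = grid[:, None]
    u = system.potential(pts)
    if walls:
        wu, _ = wall_potential(pts, walls)
        u = u + wu
    f = u - u.min()
    return f


def basin_delta_f(
    grid: np.ndarray, fes: np.ndarray, temperature: float, split: float = 0.0
) -> float:
    """Free-energy difference (kJ/mol) between the two basins of a 1-D FES,
    right minus left of ``split``, by Boltzmann integration."""
    kbt = KB * temperature
    w = np.exp(-(fes - fes.min()) / kbt)
    # include the dividing point in both integrals so a symmetric surface on
    # a symmetric grid gives exactly 0
    left = np.trapezoid(w[grid <= split], grid[grid <= split])
    right = np.trapezoid(w[grid >= split], grid[grid >= split])
    return float(-kbt * np.log(right / left))


def fes_barrier(grid: np.ndarray, fes: np.ndarray, split: float = 0.0) -> float:
    """Barrier height (kJ/mol): FES at the dividing point minus the global
    minimum, for a 1-D surface."""
    i_split = int(np.argmin(np.abs(grid - split)))
    return float(fes[i_split] - fes.min())


# ---------------------------------------------------------------------------
# Harmonic lambda-state families
# ---------------------------------------------------------------------------

@dataclass
class HarmonicLambdaFamily:
    """1-D harmonic states U(lambda, x) = k(lambda)/2 (x - x0(lambda))^2.

    Free energies are analytic: dG(i -> j) = (kB*T/2) ln(k_j / k_i); center
    shifts do not change the partition function.
    """

    k_of_lambda: Callable[[float], float]            # kJ/mol/nm^2
    x0_of_lambda: Callable[[float], float] = lambda lam: 0.0
    temperature: float = 300.0

    def energy(self, lam: float, x: np.ndarray) -> np.ndarray:
        k = self.k_of_lambda(lam)
        if k <= 0:
            raise ValueError("force constant must be positive")
        return 0.5 * k * (np.asarray(x, dtype=float) - self.x0_of_lambda(lam)) ** 2

    def sample(self, lam: float, n: int, rng: np.random.Generator) -> np.ndarray:
        k = self.k_of_lambda(lam)
        sigma = np.sqrt(KB * self.temperature / k)
        return self.x0_of_lambda(lam) + sigma * rng.standard_normal(n)

    def analytic_delta_f(self, lam_i: float, lam_j: float) -> float:
        """Reduced free-energy difference f_j - f_i."""
        return 0.5 * np.log(self.k_of_lambda(lam_j) / self.k_of_lambda(lam_i))


def gen_harmonic_lambda_samples(
    family: HarmonicLambdaFamily,
    lambdas: Sequence[float],
    n_per_state: int,
    seed: int = 0,
) -> tuple[ReducedPotentialMatrix, dict]:
    """Exact Gaussian samples from each lambda state, assembled into a
    reduced-potential matrix, with the analytic reduced free energies."""
    rng = np.random.default_rng(seed)
    kbt = KB * family.temperature
    samples = [family.sample(lam, n_per_state, rng) for lam in lambdas]
    x = np.concatenate(samples)
    u_kn = np.stack([family.energy(lam, x) / kbt for lam in lambdas])
    problem = ReducedPotentialMatrix(u_kn, np.full(len(lambdas), n_per_state))
    f_true = np.array([family.analytic_delta_f(lambdas[0], lam) for lam in lambdas])
    truth = {
        "generator": "gen_harmonic_lambda_samples",
        "lambdas": list(lambdas), "n_per_state": n_per_state, "seed": seed,
        "temperature": family.temperature,
        "f_true_reduced": f_true,
        "delta_g_true_kJ": f_true * kbt,
    }
    return problem, truth
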