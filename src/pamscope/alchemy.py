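"""Alchemical free-energy machinery: MBAR, lambda-window scheduling,
Metropolis neighbor swaps, thermodynamic-cycle differences and per-residue
enthalpy decompositions.

The multistate Bennett acceptance ratio (MBAR) estimator solves

    f_i = -ln sum_n exp(-u_i(x_n)) / sum_k N_k exp(f_k - u_k(x_n))

self-consistently for the reduced free energies f_i of K thermodynamic
states given samples from any subset of them, and provides asymptotic
uncertainties from the weight-matrix covariance.  Lambda windows of an
alchemical transformation are spaced so that neighbor-exchange acceptance
stays above a target (10% by default), mirroring Hamiltonian replica
exchange practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from .units import KB, KJ_TO_KCAL


@dataclass
class ReducedPotentialMatrix:
    """u[k, n]: reduced potential of sample n evaluated in state k."""

    u_kn: np.ndarray
    n_k: np.ndarray

    def __post_init__(self) -> None:
        self.u_kn = np.asarray(self.u_kn, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=int)
        if self.u_kn.ndim != 2:
            raise ValueError("u_kn must be 2-D (states x samples)")
        if self.n_k.sum() != self.u_kn.shape[1]:
            raise ValueError("sum of per-state sample counts must equal total samples")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("reduced potentials must be finite")

    @property
    def n_states(self) -> int:
        return self.u_kn.shape[0]


@dataclass
class MBARResult:
    """Per-state reduced free energies (f_0 = 0) with asymptotic covariance."""

    f_k: np.ndarray
    theta: np.ndarray          # covariance of f_k, reduced units squared
    n_iterations: int
    overlap: np.ndarray        # K x K overlap matrix

    def delta_f(self, i: int, j: int) -> tuple[float, float]:
        """f_j - f_i (reduced) with its standard error."""
        var = self.theta[i, i] + self.theta[j, j] - 2.0 * self.theta[i, j]
        return float(self.f_k[j] - self.f_k[i]), float(np.sqrt(max(var, 0.0)))

    def delta_g_kJ(self, i: int, j: int, temperature: float) -> tuple[float, float]:
        df, ddf = self.delta_f(i, j)
        kbt = KB * temperature
        return df * kbt, ddf * kbt


def reduced_potentials(
    samples_per_state: Sequence[np.ndarray],
    energy_functions: Sequence[Callable[[np.ndarray], np.ndarray]],
    temperature: float,
) -> ReducedPotentialMatrix:
    """Assemble u[k, n] = U_k(x_n) / kB*T from per-state sample sets.

    Every sample is evaluated in every state; samples are concatenated in
    state order so column blocks correspond to origin states.
    """
    kbt = KB * temperature
    n_k = np.array([len(s) for s in samples_per_state], dtype=int)
    x = np.concatenate([np.asarray(s, dtype=float) for s in samples_per_state])
    u_kn = np.stack([np.asarray(u(x), dtype=float) / kbt for u in energy_functions])
    return ReducedPotentialMatrix(u_kn, n_k)


def _mbar_weights(u_kn: np.ndarray, n_k: np.ndarray, f_k: np.ndarray) -> np.ndarray:
    """Log-weight matrix log W[n, k] = f_k - u_kn - log D_n."""
    log_nk = np.where(n_k > 0, np.log(np.maximum(n_k, 1)), -np.inf)
    log_denom = logsumexp((log_nk + f_k)[:, None] - u_kn, axis=0)  # (N,)
    return (f_k[:, None] - u_kn - log_denom[None, :]).T            # (N, K)


def mbar_solve(
    problem: ReducedPotentialMatrix,
    tolerance: float = 1e-8,
    max_iterations: int = 10_000,
    overlap_warning: float = 0.03,
) -> MBARResult:
    """Solve the MBAR equations (f_0 anchored at 0) with uncertainties.

    Self-consistent iteration bootstraps the solution; once the update is
    small a Newton-Raphson polish drives it to ``tolerance`` in reduced
    units.  States with no samples are handled naturally (for them the
    estimator reduces to exponential averaging against the sampled states).
    Adjacent-state overlaps below ``overlap_warning`` trigger a warning.
    """
    u_kn, n_k = problem.u_kn, problem.n_k
    K, N = u_kn.shape
    if N == 0:
        raise ValueError("no samples")
    f = np.zeros(K)
    sampled = n_k > 0
    log_nk = np.where(sampled, np.log(np.maximum(n_k, 1)), -np.inf)

    def scf(f):
        log_denom = logsumexp((log_nk + f)[:, None] - u_kn, axis=0)
        return -logsumexp(-u_kn - log_denom[None, :], axis=1)

    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        f_new = scf(f)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < 1e-4:
            break
    # Newton polish on the sampled-state subspace (zero-sample states follow
    # from one final SCF evaluation and do not enter the equations).
    idx = np.nonzero(sampled)[0]
    free = idx[1:] if idx[0] == 0 else idx  # f of first sampled state fixed
    for _ in range(100 if len(free) else 0):
        n_iter += 1
        logw = _mbar_weights(u_kn, n_k, f)
        w = np.exp(logw)                    # (N, K)
        col = w[:, idx] * n_k[idx]
        grad = col.sum(axis=0) - n_k[idx]
        hess = np.diag(col.sum(axis=0)) - col.T @ col
        sel = np.searchsorted(idx, free)
        g = grad[sel]
        h = hess[np.ix_(sel, sel)]
        if np.max(np.abs(g)) < tolerance * max(1, n_k.max()):
            break
        try:
            step = np.linalg.solve(h + 1e-12 * np.eye(len(sel)), g)
        except np.linalg.LinAlgError:
            step = g / np.maximum(np.diag(h), 1e-12)
        if np.max(np.abs(step)) > 2.0:      # damp wild steps
            step *= 2.0 / np.max(np.abs(step))
        f[free] -= step
        f = scf(f)
        f -= f[0]
    else:
        if len(free):
            raise RuntimeError("MBAR did not converge within the iteration cap")
    f = scf(f)
    f -= f[0]

    logw = _mbar_weights(u_kn, n_k, f)
    w = np.exp(logw)                        # (N, K), columns sum to 1
    # Asymptotic covariance: Theta = V S (I - S V' N V S)^+ S V' with W = U S V'
    _, s, vt = np.linalg.svd(w, full_matrices=False)
    ndiag = np.diag(n_k.astype(float))
    inner = np.eye(K) - np.diag(s) @ vt @ ndiag @ vt.T @ np.diag(s)
    theta = vt.T @ np.diag(s) @ np.linalg.pinv(inner, rcond=1e-10) @ np.diag(s) @ vt
    # variances of differences need Theta relative to the f_0 anchor
    overlap = (w.T @ w) * n_k[None, :]
    small = [
        (k, k + 1) for k in range(K - 1)
        if sampled[k] and sampled[k + 1] and overlap[k, k + 1] < overlap_warning
    ]
    if small:
        warnings.warn(f"low adjacent-state overlap (<{overlap_warning}) at pairs {small}")
    return MBARResult(f_k=f, theta=theta, n_iterations=n_iter, overlap=overlap)


def neighbor_swap(
    x_i: np.ndarray,
    x_j: np.ndarray,
    u_i: Callable[[np.ndarray], float],
    u_j: Callable[[np.ndarray], float],
    temperature: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis acceptance of a configuration swap between two states.

    Accepts with probability min(1, exp(-[U_i(x_j) + U_j(x_i) - U_i(x_i)
    - U_j(x_j)] / kB*T)); energies in kJ/mol.
    """
    kbt = KB * temperature
    delta = (u_i(x_j) + u_j(x_i) - u_i(x_i) - u_j(x_j)) / kbt
    if delta <= 0:
        return True
    return bool(rng.random() < np.exp(-delta))


@dataclass
class LambdaSchedule:
    """Ordered lambda values spanning [0, 1] with measured neighbor
    acceptance rates."""

    lambdas: np.ndarray
    acceptance: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if lam[0] != 0.0 or lam[-1] != 1.0:
            raise ValueError("schedule must span lambda = 0 to 1")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("lambda values must be strictly increasing")
        self.lambdas = lam


def estimate_pair_acceptance(
    family,
    lam_a: float,
    lam_b: float,
    n_pilot: int,
    temperature: float,
    rng: np.random.Generator,
) -> float:
    """Mean Metropolis swap acceptance between two lambda states from pilot
    samples; ``family`` provides sample(lam, n, rng) and energy(lam, x)."""
    kbt = KB * temperature
    xa = family.sample(lam_a, n_pilot, rng)
    xb = family.sample(lam_b, n_pilot, rng)
    delta = (
        family.energy(lam_a, xb) + family.energy(lam_b, xa)
        - family.energy(lam_a, xa) - family.energy(lam_b, xb)
    ) / kbt
    return float(np.mean(np.minimum(1.0, np.exp(-np.maximum(delta, -700)))))


def optimize_lambda_schedule(
    family,
    initial_lambdas: Sequence[float],
    target_acceptance: float = 0.10,
    temperature: float = 300.0,
    n_pilot: int = 2000,
    max_iterations: int = 60,
    max_windows: int = 64,
    learning_rate: float = 0.25,
    seed: int = 0,
) -> LambdaSchedule:
    """Space lambda windows so every neighbor pair reaches a target swap
    acceptance.

    Interior lambdas descend the gradient of the summed squared acceptance
    deficits (estimated with common random numbers per iteration); when a
    gap cannot reach the target a window is inserted at its midpoint.  If
    the target is unreachable within the window budget, the best schedule is
    returned flagged as unconverged.
    """
    lam = np.array(sorted(set(float(v) for v in initial_lambdas)))
    if lam[0] != 0.0 or lam[-1] != 1.0:
        raise ValueError("initial schedule must include lambda = 0 and 1")
    rng_master = np.random.default_rng(seed)

    def acceptances(lam_vec, rng_seed):
        return np.array([
            estimate_pair_acceptance(
                family, lam_vec[i], lam_vec[i + 1], n_pilot, temperature,
                np.random.default_rng(rng_seed + i),
            )
            for i in range(len(lam_vec) - 1)
        ])

    while True:
        for _ in range(max_iterations):
            base_seed = int(rng_master.integers(2**31 - 1))
            acc = acceptances(lam, base_seed)
            if acc.min() >= target_acceptance:
                return LambdaSchedule(lam, acc, converged=True)
            deficits = np.maximum(0.0, target_acceptance - acc)
            # finite-difference gradient wrt interior lambdas, common RNs
            grad = np.zeros(len(lam))
            h = 1e-3
            for j in range(1, len(lam) - 1):
                lam_p = lam.copy()
                lam_p[j] = min(lam[j + 1] - 1e-6, lam_p[j] + h)
                acc_p = acceptances(lam_p, base_seed)
                def_p = np.maximum(0.0, target_acceptance - acc_p)
                grad[j] = ((def_p**2).sum() - (deficits**2).sum()) / (lam_p[j] - lam[j])
            step = learning_rate * grad
            if np.max(np.abs(step)) > 0:
                lam_new = lam - step
                # keep ordering with a minimal gap
                for j in range(1, len(lam) - 1):
                    lam_new[j] = np.clip(
                        lam_new[j], lam_new[j - 1] + 1e-4, lam[j + 1] - 1e-4
                    )
                lam = lam_new
        # gradient descent stalled below target: insert a window at the
        # worst gap, if the budget allows
        if len(lam) >= max_windows:
            acc = acceptances(lam, int(rng_master.integers(2**31 - 1)))
            warnings.warn(
                "lambda schedule target acceptance unreachable within the "
                f"window budget (min acceptance {acc.min():.3f})"
            )
            return LambdaSchedule(lam, acc, converged=False)
        acc = acceptances(lam, int(rng_master.integers(2**31 - 1)))
        worst = int(np.argmin(acc))
        lam = np.sort(np.append(lam, 0.5 * (lam[worst] + lam[worst + 1])))


@dataclass
class CycleResult:
    """Thermodynamic-cycle ddG = dG_m2 (DNA-bound) - dG_m1 (apo), kcal/mol."""

    dg_m1: float
    dg_m1_err: float
    dg_m2: float
    dg_m2_err: float

    @property
    def ddg(self) -> float:
        return self.dg_m2 - self.dg_m1

    @property
    def ddg_err(self) -> float:
        return float(np.hypot(self.dg_m1_err, self.dg_m2_err))


def ddg_cycle(
    dg_m1: float, dg_m1_err: float, dg_m2: float, dg_m2_err: float
) -> CycleResult:
    """Combine the two mutation legs of the thermodynamic cycle.

    dG_m1 is the alchemical mutation free energy without DNA, dG_m2 with
    DNA bound; ddG = dG_m2 - dG_m1, errors summed in quadrature.  A
    mutation that stabilizes the DNA-bound leg gives ddG < 0 (favourable
    binding).
    """
    if dg_m1_err < 0 or dg_m2_err < 0:
        raise ValueError("uncertainties must be non-negative")
    return CycleResult(dg_m1, dg_m1_err, dg_m2, dg_m2_err)


@dataclass
class EnthalpyDecomposition:
    residue: str
    mean: float            # kJ/mol
    block_error: float     # kJ/mol, SD of block means / sqrt(n_blocks)
    n_blocks: int
    equilibration_fraction: float
    n_frames_used: int


def per_residue_deltaE(
    energies: np.ndarray,
    residue: str = "",
    equilibration_fraction: float = 0.10,
    n_blocks: int = 5,
) -> EnthalpyDecomposition:
    """Mean residue-DNA interaction energy with a block-average error.

    The first ``equilibration_fraction`` of frames is discarded; the rest
    is split into ``n_blocks`` equal blocks and the error is the standard
    deviation of the block means divided by sqrt(n_blocks).
    """
    e = np.asarray(energies, dtype=float)
    start = int(np.floor(len(e) * equilibration_fraction))
    e = e[start:]
    if len(e) < n_blocks:
        raise ValueError("too few frames after equilibration discard")
    edges = np.linspace(0, len(e), n_blocks + 1).astype(int)
    block_means = np.array([e[edges[b]: edges[b + 1]].mean() for b in range(n_blocks)])
    err = float(block_means.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks > 1 else 0.0
    return EnthalpyDecomposition(
        residue=residue,
        mean=float(e.mean()),
        block_error=err,
        n_blocks=n_blocks,
        equilibration_fraction=equilibration_fraction,
        n_frames_used=len(e),
    )


def to_kcal(value_kJ: float) -> float:
    return value_kJ * KJ_TO_KCAL
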