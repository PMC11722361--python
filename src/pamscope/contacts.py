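"""Arginine-DNA contact classification and occupancy statistics.

A contact between a guanidinium group and a DNA group is declared per frame
by a dual criterion: the centre-of-mass distance must be below a
category-specific cutoff (0.6 nm for nucleobases, 0.5 nm for backbone
phosphates) *and* the pair interaction energy must be attractive with
magnitude at or above a category-specific threshold (100 kJ/mol for bases,
350 kJ/mol for phosphates).  Occupancy means carry standard errors corrected
for temporal correlation through the integrated autocorrelation time of the
pair's interaction-energy series; across replicates, the largest replicate
autocorrelation time is used and replicate means are combined as the
standard deviation of the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import AtomSelection, TrajectoryEnsemble
from .units import COULOMB_CONSTANT

CATEGORY_BASE = "base"
CATEGORY_PHOSPHATE = "phosphate"


@dataclass
class ContactCriteria:
    """Dual distance + energy contact criteria, per pair category."""

    base_distance_cutoff: float = 0.6       # nm
    phosphate_distance_cutoff: float = 0.5  # nm
    base_energy_threshold: float = 100.0    # kJ/mol, magnitude of attraction
    phosphate_energy_threshold: float = 350.0
    min_occupancy_prefilter: float = 0.05

    def __post_init__(self) -> None:
        if self.base_distance_cutoff <= 0 or self.phosphate_distance_cutoff <= 0:
            raise ValueError("distance cutoffs must be positive")
        if self.base_energy_threshold <= 0 or self.phosphate_energy_threshold <= 0:
            raise ValueError("energy thresholds must be positive")
        if not 0.0 <= self.min_occupancy_prefilter <= 1.0:
            raise ValueError("prefilter occupancy must lie in [0, 1]")

    def distance_cutoff(self, category: str) -> float:
        if category == CATEGORY_BASE:
            return self.base_distance_cutoff
        if category == CATEGORY_PHOSPHATE:
            return self.phosphate_distance_cutoff
        raise ValueError(f"unknown contact category {category!r}")

    def energy_threshold(self, category: str) -> float:
        if category == CATEGORY_BASE:
            return self.base_energy_threshold
        if category == CATEGORY_PHOSPHATE:
            return self.phosphate_energy_threshold
        raise ValueError(f"unknown contact category {category!r}")


@dataclass
class PairEnergySeries:
    """Per-frame interaction energy (kJ/mol) of one arginine-DNA pair."""

    pair_id: str
    category: str
    energies: np.ndarray
    frame_interval: float = 1.0  # ps

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)


@dataclass
class ContactSeries:
    """Per-frame binary contact occupancy of one pair."""

    pair_id: str
    occupancy: np.ndarray
    frame_interval: float = 1.0  # ps
    category: str = CATEGORY_BASE

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if not np.isin(occ, (0, 1)).all():
            raise ValueError("occupancy values must be binary")
        self.occupancy = occ.astype(np.int8)


@dataclass
class FrequencyEstimate:
    """Occupancy mean with an autocorrelation-corrected standard error."""

    mean: float
    variance: float
    tau: float        # ps
    n_eff: float
    std_error: float
    replicate_id: int = 0


def com_distance(
    traj: TrajectoryEnsemble, group_a: AtomSelection, group_b: AtomSelection
) -> np.ndarray:
    """Per-frame distance (nm) between the mass-weighted COMs of two groups."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("COM distance requires non-empty selections")
    ma = group_a.masses
    mb = group_b.masses
    ca = traj.frames[:, group_a.indices, :]  # (n_frames, n_a, 3)
    cb = traj.frames[:, group_b.indices, :]
    com_a = np.einsum("fij,i->fj", ca, ma) / ma.sum()
    com_b = np.einsum("fij,i->fj", cb, mb) / mb.sum()
    return np.linalg.norm(com_a - com_b, axis=1)


def pair_interaction_energy(
    traj: TrajectoryEnsemble,
    group_a: AtomSelection,
    group_b: AtomSelection,
    pair_id: str = "",
    category: str = CATEGORY_BASE,
    lj_params: dict[str, tuple[float, float]] | None = None,
    energy_table: np.ndarray | pd.Series | None = None,
) -> PairEnergySeries:
    """Per-frame group-group interaction energy in kJ/mol.

    If ``energy_table`` is given (e.g. force-field energies exported from an
    MD engine) it is passed through unchanged with pair metadata attached.
    Otherwise the energy is the sum of pairwise Coulomb terms from the
    structure's point charges, plus 12-6 Lennard-Jones terms when
    ``lj_params`` maps atom names to (sigma_nm, epsilon_kJ/mol), combined
    with Lorentz-Berthelot rules.
    """
    if energy_table is not None:
        energies = np.asarray(energy_table, dtype=float)
        if len(energies) != traj.n_frames:
            raise ValueError("external energy table length must match frame count")
        return PairEnergySeries(pair_id, category, energies, traj.frame_interval)

    charges = traj.reference.charge
    if charges is None:
        raise ValueError(
            "structure has no charges and no external energy table was given"
        )
    qa = charges[group_a.indices]
    qb = charges[group_b.indices]
    ca = traj.frames[:, group_a.indices, :]
    cb = traj.frames[:, group_b.indices, :]
    # (n_frames, n_a, n_b) pairwise distances
    diff = ca[:, :, None, :] - cb[:, None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    energies = COULOMB_CONSTANT * np.einsum("i,j,fij->f", qa, qb, 1.0 / r)
    if lj_params is not None:
        names_a = traj.reference.atom_name[group_a.indices]
        names_b = traj.reference.atom_name[group_b.indices]
        sig_a = np.array([lj_params[str(n)][0] for n in names_a])
        eps_a = np.array([lj_params[str(n)][1] for n in names_a])
        sig_b = np.array([lj_params[str(n)][0] for n in names_b])
        eps_b = np.array([lj_params[str(n)][1] for n in names_b])
        sig = 0.5 * (sig_a[:, None] + sig_b[None, :])
        eps = np.sqrt(eps_a[:, None] * eps_b[None, :])
        sr6 = (sig[None, :, :] / r) ** 6
        energies = energies + (4.0 * eps[None, :, :] * (sr6**2 - sr6)).sum(axis=(1, 2))
    return PairEnergySeries(pair_id, category, energies, traj.frame_interval)


def prefilter_pairs(
    distance_series: dict[str, tuple[str, list[np.ndarray]]],
    criteria: ContactCriteria,
) -> list[str]:
    """Keep candidate pairs that meet their distance cutoff often enough.

    ``distance_series`` maps pair_id -> (category, list of per-replicate
    distance arrays in nm).  A pair survives iff the fraction of frames,
    pooled over all replicates, with distance strictly below the category
    cutoff is >= the prefilter occupancy (boundary inclusive).
    """
    kept = []
    for pair_id, (category, replicates) in distance_series.items():
        cutoff = criteria.distance_cutoff(category)
        pooled = np.concatenate([np.asarray(d, dtype=float) for d in replicates])
        occupancy = float(np.mean(pooled < cutoff))
        if occupancy >= criteria.min_occupancy_prefilter:
            kept.append(pair_id)
    return kept


def classify_contacts(
    distances: np.ndarray,
    energies: np.ndarray,
    criteria: ContactCriteria,
    category: str,
    pair_id: str = "",
    frame_interval: float = 1.0,
) -> ContactSeries:
    """Binary contact series: distance < cutoff AND energy <= -threshold."""
    distances = np.asarray(distances, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if distances.shape != energies.shape:
        raise ValueError("distance and energy series must be frame-aligned")
    cutoff = criteria.distance_cutoff(category)
    threshold = criteria.energy_threshold(category)
    occupancy = (distances < cutoff) & (energies <= -threshold)
    return ContactSeries(pair_id, occupancy.astype(np.int8), frame_interval, category)


def autocorrelation_function(series: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation rho(k) of a 1-D series, via FFT."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        out = np.zeros(n)
        out[0] = 1.0
        return out
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    return acov / acov[0]


def integrated_autocorrelation_time(
    series: np.ndarray, frame_interval: float = 1.0, window_factor: float = 6.0
) -> float:
    """Integrated autocorrelation time tau (ps) with automatic windowing.

    tau(W) = dt * (1/2 + sum_{k=1..W} rho(k)); the truncation window is the
    smallest W with W >= window_factor * tau(W)/dt (Sokal's criterion).  A
    constant series has tau = 0 by definition; an i.i.d. series converges to
    dt/2.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValueError("series too short for autocorrelation analysis")
    if np.ptp(x) == 0:
        return 0.0
    rho = autocorrelation_function(x)
    max_lag = len(x) // 2
    csum = np.cumsum(rho[1:max_lag])
    tau_w = 0.5 + csum                      # tau(W)/dt for W = 1..max_lag-1
    windows = np.arange(1, max_lag)
    ok = windows >= window_factor * tau_w
    if np.any(ok):
        w = int(np.argmax(ok))              # smallest W satisfying the criterion
        tau_steps = tau_w[w]
    else:
        tau_steps = tau_w[-1]
        warnings.warn("autocorrelation window did not close; tau may be biased")
    return float(max(tau_steps, 0.0) * frame_interval)


def frequency_with_error(
    contacts: ContactSeries, tau: float, replicate_id: int = 0
) -> FrequencyEstimate:
    """Bernoulli occupancy estimate with autocorrelation-corrected error.

    ``tau`` should be the integrated autocorrelation time of the matching
    pair's energy series (largest value across replicates when pooling).
    n_eff = n * dt / (2 tau), capped at n; SE = sqrt(p(1-p)/n_eff).
    """
    if tau < 0:
        raise ValueError("autocorrelation time must be non-negative")
    occ = contacts.occupancy.astype(float)
    n = len(occ)
    p = float(occ.mean())
    var = p * (1.0 - p)
    if tau == 0:
        n_eff = float(n)
    else:
        n_eff = min(float(n), n * contacts.frame_interval / (2.0 * tau))
    se = float(np.sqrt(var / n_eff))
    return FrequencyEstimate(p, var, tau, n_eff, se, replicate_id)


def aggregate_replicates(
    estimates: list[FrequencyEstimate],
) -> tuple[float, float]:
    """Mean of replicate means +/- standard deviation of the mean.

    Error = SD(replicate means) / sqrt(R).  With a single replicate the
    error is undefined (returned as nan, with a warning).
    """
    means = np.array([e.mean for e in estimates], dtype=float)
    if len(means) == 0:
        raise ValueError("no replicate estimates given")
    if len(means) < 2:
        warnings.warn("fewer than 2 replicates: error undefined")
        return float(means[0]), float("nan")
    center = float(means.mean())
    err = float(means.std(ddof=1) / np.sqrt(len(means)))
    return center, err


def category_frequency_table(
    rows: list[dict],
) -> pd.DataFrame:
    """Assemble per-residue x category frequencies into a tidy table.

    Each row dict needs keys: residue, category, mean, err, n_eff, tau_ps.
    """
    df = pd.DataFrame(rows, columns=["residue", "category", "mean", "err", "n_eff", "tau_ps"])
    bad = df[(df["mean"] < 0) | (df["mean"] > 1)]
    if len(bad):
        raise ValueError("frequencies must lie in [0, 1]")
    return df
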