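"""Superposition, RMSD/RMSF, domain COM-distance distributions and
quasi-harmonic conformational entropy.

The entropy estimator follows the quantum quasi-harmonic route: build the
mass-weighted covariance of atomic fluctuations (after removing rigid-body
motion by least-squares fitting), diagonalize, map each eigenvalue lambda to
an oscillator frequency omega = sqrt(kB*T/lambda), and sum the quantum
harmonic-oscillator entropies (Andricioaei-Karplus).  Schlitter's upper
bound is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .contacts import integrated_autocorrelation_time
from .structure import AtomSelection, StructureModel, TrajectoryEnsemble, com
from .units import HBAR, KB, NM_TO_ANGSTROM, R_GAS

RIGID_EIGENVALUE_FLOOR = 1e-8  # amu*nm^2; eigenvalues below are rigid-body/noise


@dataclass
class RigidTransform:
    """Proper rotation + translation mapping mobile onto reference."""

    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,), nm

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class EntropyResult:
    label: str
    eigenvalues: np.ndarray      # amu*nm^2, descending
    frequencies: np.ndarray      # 1/ps, for retained modes
    entropy: float               # J/mol/K
    temperature: float           # K
    n_frames: int
    n_modes_dropped: int


@dataclass
class DistanceDistribution:
    """Per-frame COM distance series (Angstrom) with a histogram density."""

    distances: np.ndarray        # Angstrom
    bin_edges: np.ndarray
    density: np.ndarray
    replicate_id: int = 0

    @property
    def mean(self) -> float:
        return float(self.distances.mean())


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal weighted rigid superposition (Kabsch) and the resulting RMSD.

    Returns the transform that maps ``mobile`` onto ``reference`` and the
    weighted RMSD (same length units as the inputs).  Reflections are
    corrected by flipping the sign of the smallest singular vector.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("point sets must have identical shapes")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu_m = (mobile * w[:, None]).sum(axis=0)
    mu_r = (reference * w[:, None]).sum(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    h = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    transform = RigidTransform(rotation=rot, translation=mu_r - rot @ mu_m)
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt((w * ((moved - reference) ** 2).sum(axis=1)).sum()))
    return transform, rmsd


def _match_atoms(
    struct_a: StructureModel, struct_b: StructureModel, names: set[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Index pairs matched by (chain, residue number, atom name)."""
    key_b = {
        (str(c), int(r), str(n)): i
        for i, (c, r, n) in enumerate(
            zip(struct_b.chain_id, struct_b.residue_number, struct_b.atom_name)
        )
        if str(n).upper() in names
    }
    ia, ib = [], []
    dropped = 0
    for i, (c, r, n) in enumerate(
        zip(struct_a.chain_id, struct_a.residue_number, struct_a.atom_name)
    ):
        if str(n).upper() not in names:
            continue
        j = key_b.get((str(c), int(r), str(n)))
        if j is None:
            dropped += 1
            continue
        ia.append(i)
        ib.append(j)
    return np.array(ia, dtype=int), np.array(ib, dtype=int), dropped


def backbone_rmsd(
    struct_a: StructureModel,
    struct_b: StructureModel,
    backbone_names: tuple[str, ...] = ("N", "CA", "C", "O"),
    restrict_a: AtomSelection | None = None,
) -> tuple[float, int, int]:
    """Backbone RMSD (Angstrom) after optimal superposition.

    Atoms are paired by chain id + residue number + atom name; unmatched
    atoms are dropped and counted.  Returns (rmsd_A, n_matched, n_dropped).
    """
    names = {n.upper() for n in backbone_names}
    a = struct_a if restrict_a is None else struct_a.subset(restrict_a.indices)
    ia, ib, dropped = _match_atoms(a, struct_b, names)
    if len(ia) < 3:
        raise ValueError("fewer than 3 matched backbone atoms")
    _, rmsd_nm = kabsch_superpose(a.coordinates[ia], struct_b.coordinates[ib])
    return rmsd_nm * NM_TO_ANGSTROM, len(ia), dropped


def fit_frames(
    frames: np.ndarray,
    fit_indices: np.ndarray,
    weights: np.ndarray | None = None,
    reference: np.ndarray | None = None,
    n_iterations: int = 2,
) -> np.ndarray:
    """Least-squares fit every frame onto a reference over ``fit_indices``.

    By default the reference is the iteratively refined ensemble mean of the
    fitted frames.  All atoms are moved by each frame's transform.
    """
    frames = np.asarray(frames, dtype=float)
    ref = frames[0, fit_indices] if reference is None else reference[fit_indices]
    out = frames.copy()
    for _ in range(n_iterations if reference is None else 1):
        for f in range(out.shape[0]):
            t, _ = kabsch_superpose(out[f, fit_indices], ref, weights)
            out[f] = t.apply(out[f])
        if reference is not None:
            break
        ref = out[:, fit_indices].mean(axis=0)
    return out


def sidechain_rmsf(
    traj: TrajectoryEnsemble,
    fit_selection: AtomSelection,
    target_selection: AtomSelection,
) -> tuple[np.ndarray, float]:
    """Per-atom RMSF (Angstrom) of a side chain, and its per-residue mean.

    Frames are least-squares fitted onto the ensemble mean over
    ``fit_selection`` first, so rigid-body motion does not inflate the
    fluctuations.  RMSF_i = sqrt(<|x_i - <x_i>|^2>).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    fitted = fit_frames(traj.frames, fit_selection.indices,
                        weights=fit_selection.masses)
    sub = fitted[:, target_selection.indices, :]
    mean = sub.mean(axis=0)
    rmsf_nm = np.sqrt(((sub - mean) ** 2).sum(axis=2).mean(axis=0))
    rmsf_a = rmsf_nm * NM_TO_ANGSTROM
    return rmsf_a, float(rmsf_a.mean())


def com_distance_series(
    traj: TrajectoryEnsemble,
    domain_a: AtomSelection,
    domain_b: AtomSelection,
    bins: int | None = None,
    replicate_id: int = 0,
) -> DistanceDistribution:
    """Domain-domain COM distance distribution in Angstrom.

    Density via histogram with Scott-rule bin width unless ``bins`` is
    given.  Degenerate (constant) series get a single narrow bin.
    """
    from .contacts import com_distance

    r = com_distance(traj, domain_a, domain_b) * NM_TO_ANGSTROM
    if bins is None:
        sigma = r.std(ddof=1) if len(r) > 1 else 0.0
        if sigma == 0:
            edges = np.array([r[0] - 0.05, r[0] + 0.05])
        else:
            width = 3.49 * sigma / len(r) ** (1 / 3)   # Scott's rule
            nbins = max(1, int(np.ceil(np.ptp(r) / width)))
            edges = np.histogram_bin_edges(r, bins=nbins)
    else:
        edges = np.histogram_bin_edges(r, bins=bins)
    density, edges = np.histogram(r, bins=edges, density=True)
    return DistanceDistribution(r, edges, density, replicate_id)


def compare_distributions_z(
    series_a: np.ndarray,
    series_b: np.ndarray,
    tau_a: float = 0.0,
    tau_b: float = 0.0,
    frame_interval: float = 1.0,
) -> tuple[float, float]:
    """Two-tailed Z comparison of two series means.

    Standard errors use effective sample sizes n_eff = n*dt/(2*tau) (capped
    at n) from the integrated autocorrelation times; pass tau = 0 for
    independent samples.  Returns (Z, p) with p = 2*(1 - Phi(|Z|)).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("series must be non-empty")

    def _se(x: np.ndarray, tau: float) -> float:
        n = len(x)
        n_eff = n if tau <= 0 else min(n, n * frame_interval / (2.0 * tau))
        return float(np.sqrt(x.var(ddof=1) / n_eff)) if n > 1 else 0.0

    se_a, se_b = _se(a, tau_a), _se(b, tau_b)
    denom = np.hypot(se_a, se_b)
    if denom == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both series with unequal means")
    z = (a.mean() - b.mean()) / denom
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    return float(z), float(p)


def oscillator_entropy(x: np.ndarray) -> np.ndarray:
    """Quantum harmonic-oscillator entropy per mode, in units of R.

    x = hbar*omega/(kB*T); S/R = x/(e^x - 1) - ln(1 - e^-x).  Stiff modes
    (large x) contribute ~0; the x -> 0 limit diverges as classical
    oscillators do, but covariance eigenvalue floors keep x finite.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        term = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return np.where(x > 700, 0.0, term)


def quasiharmonic_entropy(
    traj: TrajectoryEnsemble,
    selection: AtomSelection,
    temperature: float,
    remove_rigid_body: bool = True,
    schlitter: bool = False,
) -> EntropyResult:
    """Quasi-harmonic conformational entropy of a selection, J/mol/K.

    Builds the mass-weighted covariance sigma_ij = <dx_i sqrt(m_i) dx_j
    sqrt(m_j)> over the trajectory (after least-squares fitting of each
    frame onto the ensemble mean of the selection, removing rotation and
    translation), diagonalizes it, and sums per-mode oscillator entropies
    with omega = sqrt(kB*T/lambda).  With rigid-body removal the six
    near-zero eigenvalues are excluded by a magnitude floor rather than a
    fixed count; a warning is issued when the dropped count differs from 6.

    ``schlitter=True`` returns Schlitter's upper-bound formula
    S <= (R/2) * sum ln(1 + e^2/x^2) on the same eigenvalues.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if len(selection) == 0:
        raise ValueError("empty selection")
    n_atoms = len(selection)
    n_frames = traj.n_frames
    if n_frames < 3 * n_atoms:
        warnings.warn(
            f"only {n_frames} frames for {3 * n_atoms} degrees of freedom; "
            "quasi-harmonic eigenvalues may be poorly converged"
        )
    coords = traj.frames[:, selection.indices, :]
    if remove_rigid_body:
        coords = fit_frames(coords, np.arange(n_atoms), weights=selection.masses)
    mean = coords.mean(axis=0)
    delta = (coords - mean).reshape(n_frames, 3 * n_atoms)
    sqrt_m = np.sqrt(np.repeat(selection.masses, 3))
    mw = delta * sqrt_m
    cov = mw.T @ mw / n_frames
    eig = np.linalg.eigvalsh(cov)[::-1]          # descending, amu*nm^2
    eig = np.clip(eig, 0.0, None)
    if remove_rigid_body:
        keep = eig > RIGID_EIGENVALUE_FLOOR
        n_dropped = int((~keep).sum())
        if n_dropped != 6:
            warnings.warn(
                f"dropped {n_dropped} near-zero modes after rigid-body "
                "removal (expected 6)"
            )
    else:
        keep = eig > RIGID_EIGENVALUE_FLOOR
        n_dropped = int((~keep).sum())
    lam = eig[keep]
    kbt = KB * temperature
    omega = np.sqrt(kbt / lam)                   # 1/ps (kJ/mol = amu nm^2/ps^2)
    x = HBAR * omega / kbt
    if schlitter:
        s = 0.5 * R_GAS * np.sum(np.log1p(np.e**2 / x**2))
    else:
        s = R_GAS * oscillator_entropy(x).sum()
    return EntropyResult(
        label=selection.label,
        eigenvalues=eig,
        frequencies=omega,
        entropy=float(s),
        temperature=temperature,
        n_frames=n_frames,
        n_modes_dropped=n_dropped,
    )


def entropy_from_eigenvalues(
    eigenvalues: np.ndarray, temperature: float
) -> float:
    """Closed-form quasi-harmonic entropy (J/mol/K) from mass-weighted
    covariance eigenvalues in amu*nm^2 — the oracle for planted ensembles."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > RIGID_EIGENVALUE_FLOOR]
    kbt = KB * temperature
    x = HBAR * np.sqrt(kbt / lam) / kbt
    return float(R_GAS * oscillator_entropy(x).sum())
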