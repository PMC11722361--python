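"""Well-tempered metadynamics engine with multiple walkers.

The bias potential is a sum of Gaussian hills deposited every ``stride`` ps
along the collective-variable (CV) trajectory; in the well-tempered variant
each new hill is scaled by exp(-V(s)/kB*dT) with dT = (gamma - 1) * T, so
bias deposition slows down in well-visited regions.  The free-energy
surface is recovered from the accumulated bias as

    F(s) = -(gamma / (gamma - 1)) * V(s),  shifted so min F = 0,

which is the standard well-tempered relation between bias and free energy
(the additive constant is absorbed by the shift).  Sampling on analytic toy
landscapes uses BAOAB Langevin dynamics with the CVs equal to the
coordinates themselves; one-sided harmonic walls confine the sampled range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .units import KB


@dataclass
class Wall:
    """One-sided harmonic restraint: side 'lower' or 'upper', position in CV
    units, force constant in kJ/mol per CV-unit^2."""

    side: str
    position: float
    force_constant: float = 3500.0
    cv: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("lower", "upper"):
            raise ValueError("wall side must be 'lower' or 'upper'")
        if self.force_constant < 0:
            raise ValueError("wall force constant must be non-negative")


@dataclass
class MetadConfig:
    """Well-tempered metadynamics parameters.

    ``hill_height`` is the per-deposition Gaussian height before tempering
    (kJ/mol); for a deposition *rate* omega (kJ/mol/ps) and stride t_G use
    ``MetadConfig.from_deposition_rate(omega, t_G, ...)`` where the height
    is omega * t_G.
    """

    hill_height: float = 1.0       # kJ/mol per deposition, pre-tempering
    stride: float = 10.0           # t_G, ps
    bias_factor: float = 4.0       # gamma = (T + dT)/T
    temperature: float = 300.0     # K
    sigmas: tuple[float, ...] = (0.05,)
    walls: tuple[Wall, ...] = ()

    def __post_init__(self) -> None:
        if self.hill_height <= 0:
            raise ValueError("hill height must be positive")
        if self.stride <= 0:
            raise ValueError("deposition stride must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("Gaussian widths must be positive")

    @classmethod
    def from_deposition_rate(cls, omega: float, stride: float, **kwargs) -> "MetadConfig":
        return cls(hill_height=omega * stride, stride=stride, **kwargs)

    @property
    def delta_t_energy(self) -> float:
        """kB * dT with dT = (gamma - 1) * T, in kJ/mol."""
        return KB * (self.bias_factor - 1.0) * self.temperature

    @property
    def n_cvs(self) -> int:
        return len(self.sigmas)


@dataclass
class HillsLog:
    """Deposited hills: parallel arrays ordered by (time, walker_id)."""

    times: np.ndarray          # ps
    centers: np.ndarray        # (n_hills, n_cvs)
    sigmas: np.ndarray         # (n_hills, n_cvs)
    heights: np.ndarray        # kJ/mol, post-tempering
    walker_ids: np.ndarray
    bias_factor: float

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.sigmas = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
        if np.any(self.heights <= 0) or np.any(self.sigmas <= 0):
            raise ValueError("hill heights and widths must be positive")

    @property
    def n_hills(self) -> int:
        return len(self.heights)

    def slice(self, start: int, stop: int) -> "HillsLog":
        return HillsLog(
            self.times[start:stop], self.centers[start:stop],
            self.sigmas[start:stop], self.heights[start:stop],
            self.walker_ids[start:stop], self.bias_factor,
        )


@dataclass
class ToySystem:
    """Analytic low-dimensional system whose coordinates are the CVs."""

    potential: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    mass: float = 1.0             # amu
    friction: float = 2.0         # 1/ps
    temperature: float = 300.0    # K
    x0: tuple[float, ...] = (0.0,)
    domain: tuple[tuple[float, float], ...] = ((-3.0, 3.0),)

    @property
    def n_dim(self) -> int:
        return len(self.x0)


def bias_potential(hills: HillsLog | None, points: np.ndarray) -> np.ndarray:
    """Total Gaussian bias (kJ/mol) at one or more CV points, by direct sum."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if hills is None or hills.n_hills == 0:
        out = np.zeros(pts.shape[0])
    else:
        # (n_points, n_hills, n_cvs)
        d2 = ((pts[:, None, :] - hills.centers[None, :, :]) ** 2
              / (2.0 * hills.sigmas[None, :, :] ** 2)).sum(axis=2)
        out = (hills.heights[None, :] * np.exp(-d2)).sum(axis=1)
    return out if np.ndim(points) > 1 else float(out[0]) if pts.shape[0] == 1 else out


def tempered_height(config: MetadConfig, bias_at_point: float) -> float:
    """Height of the next hill given the current bias at the walker's CVs."""
    return config.hill_height * np.exp(-bias_at_point / config.delta_t_energy)


def wall_potential(
    s: np.ndarray, walls: Sequence[Wall]
) -> tuple[np.ndarray, np.ndarray]:
    """Energy (kJ/mol) and force (-dU/ds) from one-sided harmonic walls.

    For a lower wall at a: U = k/2 (a - s)^2 when s < a, else 0; upper wall
    mirrored.  Both energy and force are continuous at the wall position.
    """
    pts = np.atleast_2d(np.asarray(s, dtype=float))
    energy = np.zeros(pts.shape[0])
    force = np.zeros_like(pts)
    for w in walls:
        x = pts[:, w.cv]
        if w.side == "lower":
            viol = np.clip(w.position - x, 0.0, None)
            energy += 0.5 * w.force_constant * viol**2
            force[:, w.cv] += w.force_constant * viol
        else:
            viol = np.clip(x - w.position, 0.0, None)
            energy += 0.5 * w.force_constant * viol**2
            force[:, w.cv] -= w.force_constant * viol
    if np.ndim(s) == 1:
        return float(energy[0]), force[0]
    return energy, force


class _BiasGrid:
    """Grid cache of the bias and its gradient for fast per-step lookup.

    Correctness is defined by direct summation in :func:`bias_potential`;
    the grid only accelerates the inner Langevin loop (values agree to the
    interpolation error of a spacing of sigma/8).
    """

    def __init__(self, domain, sigmas, pad=4.0):
        self.axes = []
        for (lo, hi), sig in zip(domain, sigmas):
            spacing = sig / 8.0
            n = int(np.ceil((hi - lo + 2 * pad * sig) / spacing)) + 1
            self.axes.append(np.linspace(lo - pad * sig, hi + pad * sig, n))
        self.ndim = len(self.axes)
        shape = tuple(len(a) for a in self.axes)
        self.v = np.zeros(shape)
        self.grad = np.zeros(shape + (self.ndim,))
        mesh = np.meshgrid(*self.axes, indexing="ij")
        self.points = np.stack([m.ravel() for m in mesh], axis=-1)

    def add_hill(self, center, sigmas, height):
        d = (self.points - center) / sigmas
        g = height * np.exp(-0.5 * (d**2).sum(axis=1))
        self.v += g.reshape(self.v.shape)
        for k in range(self.ndim):
            contrib = g * (-(self.points[:, k] - center[k]) / sigmas[k] ** 2)
            self.grad[..., k] += contrib.reshape(self.v.shape)

    def _locate(self, x):
        idx, frac = [], []
        for k, ax in enumerate(self.axes):
            t = (x[:, k] - ax[0]) / (ax[1] - ax[0])
            i = np.clip(np.floor(t).astype(int), 0, len(ax) - 2)
            idx.append(i)
            frac.append(np.clip(t - i, 0.0, 1.0))
        return idx, frac

    def value_and_grad(self, x):
        x = np.atleast_2d(x)
        idx, frac = self._locate(x)
        if self.ndim == 1:
            i, f = idx[0], frac[0]
            v = self.v[i] * (1 - f) + self.v[i + 1] * f
            g = self.grad[i, 0] * (1 - f) + self.grad[i + 1, 0] * f
            return v, g[:, None]
        i, j = idx
        fx, fy = frac
        w00 = (1 - fx) * (1 - fy)
        w10 = fx * (1 - fy)
        w01 = (1 - fx) * fy
        w11 = fx * fy
        v = (self.v[i, j] * w00 + self.v[i + 1, j] * w10
             + self.v[i, j + 1] * w01 + self.v[i + 1, j + 1] * w11)
        g = (self.grad[i, j] * w00[:, None] + self.grad[i + 1, j] * w10[:, None]
             + self.grad[i, j + 1] * w01[:, None]
             + self.grad[i + 1, j + 1] * w11[:, None])
        return v, g


def run_wtmetad(
    system: ToySystem,
    config: MetadConfig,
    n_walkers: int = 1,
    n_steps: int = 100_000,
    seed: int = 0,
    dt: float = 0.01,
    cv_stride: int = 10,
) -> tuple[HillsLog, np.ndarray]:
    """Run multiple-walker well-tempered metadynamics on a toy system.

    Walkers propagate independently with BAOAB Langevin dynamics under the
    system potential, the shared bias, and the walls; every ``stride`` ps
    each walker (in walker order) deposits a tempered hill into the shared
    log.  Returns the hills log and CV trajectories of shape
    (n_saved, n_walkers, n_cvs).  Given the same seed the run is
    bit-reproducible.
    """
    if len(config.sigmas) != system.n_dim:
        raise ValueError("config sigmas must match system dimensionality")
    rng = np.random.default_rng(seed)
    d = system.n_dim
    x = np.tile(np.asarray(system.x0, dtype=float), (n_walkers, 1))
    # spread walkers deterministically so they do not start identical
    x += 0.01 * rng.standard_normal(x.shape)
    v = rng.standard_normal(x.shape) * np.sqrt(KB * system.temperature / system.mass)

    grid = _BiasGrid(system.domain, config.sigmas)
    c1 = np.exp(-system.friction * dt)
    c2 = np.sqrt(KB * system.temperature / system.mass * (1.0 - c1**2))
    deposit_every = max(1, int(round(config.stride / dt)))
    bound = np.array(system.domain, dtype=float)
    blow = 10.0 * np.max(np.abs(bound))

    times, centers, sig_list, heights, walker_ids = [], [], [], [], []
    cv_traj = []

    def total_force(pos):
        _, wf = wall_potential(pos, config.walls)
        _, bg = grid.value_and_grad(pos)
        return -system.gradient(pos) - bg + wf

    f = total_force(x)
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f / system.mass
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(v.shape)
        x += 0.5 * dt * v
        f = total_force(x)
        v += 0.5 * dt * f / system.mass
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > blow):
            raise RuntimeError(
                f"unstable trajectory at step {step}: reduce dt or check walls"
            )
        if step % deposit_every == 0:
            t_now = step * dt
            for w in range(n_walkers):
                vb, _ = grid.value_and_grad(x[w: w + 1])
                h = tempered_height(config, float(vb[0]))
                grid.add_hill(x[w].copy(), np.asarray(config.sigmas), h)
                times.append(t_now)
                centers.append(x[w].copy())
                sig_list.append(np.asarray(config.sigmas, dtype=float))
                heights.append(h)
                walker_ids.append(w)
        if step % cv_stride == 0:
            cv_traj.append(x.copy())

    hills = HillsLog(
        times=np.asarray(times), centers=np.asarray(centers),
        sigmas=np.asarray(sig_list), heights=np.asarray(heights),
        walker_ids=np.asarray(walker_ids, dtype=int),
        bias_factor=config.bias_factor,
    )
    return hills, np.asarray(cv_traj)


def reconstruct_fes(
    hills: HillsLog,
    grid: np.ndarray | Sequence[np.ndarray],
    bias_factor: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Free-energy surface from a hills log: F = -(g/(g-1)) V, min at 0.

    ``grid`` is a 1-D array of CV values or a sequence of per-CV axes for
    2-D surfaces.  Returns (grid_points, F) with F in kJ/mol; for 2-D the
    grid points have shape (n, 2) in row-major axis order.  In the
    gamma -> infinity limit the prefactor tends to 1 (standard
    metadynamics).
    """
    if hills.n_hills == 0:
        raise ValueError("empty hills log")
    g = hills.bias_factor if bias_factor is None else bias_factor
    prefactor = 1.0 if np.isinf(g) else g / (g - 1.0)
    if isinstance(grid, np.ndarray) and grid.ndim == 1:
        pts = grid[:, None]
    elif isinstance(grid, np.ndarray) and grid.ndim == 2:
        pts = grid
    else:
        mesh = np.meshgrid(*grid, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
    v = bias_potential(hills, pts)
    f = -prefactor * np.asarray(v)
    f -= f.min()
    return pts, f


def fes_convergence(
    hills: HillsLog,
    grid: np.ndarray | Sequence[np.ndarray],
    n_blocks: int = 5,
) -> np.ndarray:
    """Block-wise FES deviation diagnostic.

    The hills log is partitioned into ``n_blocks`` consecutive equal blocks;
    each block's own FES estimate is compared with the final block's FES by
    the root-mean-square difference after aligning the two by their mean
    offset.  A converged run shows a decreasing trend towards 0 (the last
    entry is 0 by construction); large terminal deviations indicate an
    unconverged log.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    n = hills.n_hills
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    fes_blocks = []
    for b in range(n_blocks):
        block = hills.slice(edges[b], edges[b + 1])
        if block.n_hills == 0:
            raise ValueError("empty block; too many blocks for this log")
        _, f = reconstruct_fes(block, grid, bias_factor=hills.bias_factor)
        fes_blocks.append(f)
    final = fes_blocks[-1]
    devs = []
    for f in fes_blocks:
        diff = f - final
        diff = diff - diff.mean()
        devs.append(float(np.sqrt((diff**2).mean())))
    return np.asarray(devs)


HILLS_HEADER = "#! FIELDS time {cv_fields} {sigma_fields} height biasf"


def write_hills(path: str, hills: HillsLog, cv_names: Sequence[str] | None = None) -> None:
    """Serialize a hills log in the PLUMED HILLS text layout."""
    d = hills.centers.shape[1]
    names = list(cv_names) if cv_names else [f"cv{i+1}" for i in range(d)]
    header = HILLS_HEADER.format(
        cv_fields=" ".join(names),
        sigma_fields=" ".join(f"sigma_{n}" for n in names),
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(hills.n_hills):
            row = [f"{hills.times[i]:.6f}"]
            row += [f"{c:.9f}" for c in hills.centers[i]]
            row += [f"{s:.9f}" for s in hills.sigmas[i]]
            row += [f"{hills.heights[i]:.9f}", f"{hills.bias_factor:.3f}"]
            fh.write(" ".join(row) + "\n")


def read_hills(path: str) -> HillsLog:
    """Read a PLUMED-style HILLS file (time, centers, sigmas, height, biasf)."""
    data = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            data.append([float(v) for v in line.split()])
    if not data:
        raise ValueError(f"{path}: no hills found")
    arr = np.asarray(data)
    d = (arr.shape[1] - 3) // 2
    return HillsLog(
        times=arr[:, 0],
        centers=arr[:, 1: 1 + d],
        sigmas=arr[:, 1 + d: 1 + 2 * d],
        heights=arr[:, 1 + 2 * d],
        walker_ids=np.zeros(len(arr), dtype=int),
        bias_factor=float(arr[0, -1]),
    )
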