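"""Geometric hydrogen-bond detection, frequency normalization and the
PAM-specificity index.

A hydrogen bond is present in a frame when the donor-acceptor heavy-atom
distance is at most 3.5 A and the hydrogen-donor-acceptor angle is at most
30 degrees (small angle = nearly linear bond).  Frequencies are per-triplet
occupancies; category frequencies sum the triplet frequencies belonging to
a category (PAM nucleobase, PAM backbone, non-PAM).  The specificity index
compares a residue's hydrogen bonding with the PAM nucleotides against its
bonding with non-PAM nucleotides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure import AtomSelection, TrajectoryEnsemble
from .units import NM_TO_ANGSTROM

EPSILON_GUARD = 1e-6


@dataclass
class HBondCriteria:
    donor_acceptor_cutoff: float = 3.5  # Angstrom
    angle_cutoff: float = 30.0          # degrees, hydrogen-donor-acceptor

    def __post_init__(self) -> None:
        if self.donor_acceptor_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.angle_cutoff < 180.0:
            raise ValueError("angle cutoff must lie in (0, 180) degrees")


@dataclass
class HBondSeries:
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    presence: np.ndarray   # binary per frame
    category: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.presence)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("presence values must be binary")
        self.presence = arr.astype(np.int8)

    @property
    def frequency(self) -> float:
        return float(self.presence.mean())


@dataclass
class SpecificityIndex:
    residue: str
    value: float
    error: float
    flagged: bool = False


def pair_donor_hydrogens(
    structure, donors: AtomSelection, hydrogens: AtomSelection,
    max_bond_length: float = 0.125,
) -> list[tuple[int, int]]:
    """Pair each hydrogen with its covalently bonded donor heavy atom.

    Uses same-residue proximity in the reference coordinates (bond length
    cutoff in nm).  Raises if a hydrogen has no donor parent.
    """
    pairs = []
    coords = structure.coordinates
    for h in hydrogens.indices:
        same_res = (
            (structure.residue_number[donors.indices] == structure.residue_number[h])
            & (structure.chain_id[donors.indices] == structure.chain_id[h])
        )
        cand = donors.indices[same_res]
        if len(cand) == 0:
            raise ValueError(f"hydrogen atom index {h} has no candidate donor")
        d = np.linalg.norm(coords[cand] - coords[h], axis=1)
        j = int(np.argmin(d))
        if d[j] > max_bond_length:
            raise ValueError(
                f"hydrogen atom index {h} is {d[j]:.3f} nm from the nearest "
                f"donor; no covalent parent found"
            )
        pairs.append((int(cand[j]), int(h)))
    return pairs


def detect_hbonds(
    traj: TrajectoryEnsemble,
    donors: AtomSelection,
    hydrogens: AtomSelection,
    acceptors: AtomSelection,
    criteria: HBondCriteria | None = None,
    category: str = "",
) -> list[HBondSeries]:
    """Detect hydrogen bonds for every (donor-H, acceptor) combination.

    Returns one HBondSeries per (donor, hydrogen, acceptor) triplet that is
    present in at least one frame.
    """
    criteria = criteria or HBondCriteria()
    dh_pairs = pair_donor_hydrogens(traj.reference, donors, hydrogens)
    cutoff_nm = criteria.donor_acceptor_cutoff / NM_TO_ANGSTROM
    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff))
    out = []
    acc = acceptors.indices
    for d_idx, h_idx in dh_pairs:
        usable = acc[acc != d_idx]
        if len(usable) == 0:
            continue
        vd = traj.frames[:, usable, :] - traj.frames[:, [d_idx], :]  # D->A
        dist = np.linalg.norm(vd, axis=-1)                           # (F, A)
        vh = traj.frames[:, [h_idx], :] - traj.frames[:, [d_idx], :]  # D->H
        nh = np.linalg.norm(vh, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("faj,fij->fa", vd, vh) / (dist * nh)
        present = (dist <= cutoff_nm) & (cosang >= cos_cut)
        for col, a_idx in enumerate(usable):
            series = present[:, col]
            if series.any():
                out.append(
                    HBondSeries(d_idx, h_idx, int(a_idx), series.astype(np.int8),
                                category=category)
                )
    return out


def hbond_frequency(series: HBondSeries | np.ndarray) -> float:
    """Fraction of frames in which the hydrogen bond is present."""
    presence = series.presence if isinstance(series, HBondSeries) else np.asarray(series)
    if len(presence) == 0:
        raise ValueError("empty hydrogen-bond series")
    return float(np.mean(presence))


def category_frequency(series_list: list[HBondSeries]) -> float:
    """Sum of per-triplet frequencies over a category (0 if empty)."""
    return float(sum(s.frequency for s in series_list))


def normalize_frequencies(freqs: dict[str, float]) -> dict[str, float]:
    """Normalize a residue's category frequencies to sum to 1.

    An all-zero dataset is returned unchanged (all zeros) with a warning
    rather than dividing by zero.
    """
    values = np.array(list(freqs.values()), dtype=float)
    if np.any(values < 0):
        raise ValueError("frequencies must be non-negative")
    total = values.sum()
    if total == 0:
        warnings.warn("all-zero frequency dataset; normalization skipped")
        return dict(freqs)
    return {k: v / total for k, v in freqs.items()}


def specificity_index(
    freq_pam: float,
    freq_non_pam: float,
    err_pam: float = 0.0,
    err_non_pam: float = 0.0,
    residue: str = "",
    share_form: bool = False,
) -> SpecificityIndex:
    """Hydrogen-bond specificity for PAM versus non-PAM nucleotides.

    Default form is the ratio f_PAM / (f_nonPAM + eps); ``share_form``
    switches to f_PAM / (f_PAM + f_nonPAM).  Errors propagate to first
    order.  Both inputs zero yields 0 with a flag.
    """
    if freq_pam < 0 or freq_non_pam < 0:
        raise ValueError("frequencies must be non-negative")
    if freq_pam == 0 and freq_non_pam == 0:
        return SpecificityIndex(residue, 0.0, 0.0, flagged=True)
    if share_form:
        total = freq_pam + freq_non_pam
        value = freq_pam / total
        # d/df_p = f_n/total^2 ; d/df_n = -f_p/total^2
        err = np.hypot(freq_non_pam * err_pam, freq_pam * err_non_pam) / total**2
        return SpecificityIndex(residue, float(value), float(err))
    denom = freq_non_pam + EPSILON_GUARD
    value = freq_pam / denom
    err = np.hypot(err_pam / denom, freq_pam * err_non_pam / denom**2)
    return SpecificityIndex(residue, float(value), float(err))
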