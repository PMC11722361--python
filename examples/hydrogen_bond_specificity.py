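"""Hydrogen-bond detection, frequency normalization and the specificity index.

Sweeps an N-H...O geometry through the 3.5 A donor-acceptor cutoff to show
the geometric criterion, then normalizes a set of per-category hydrogen-bond
frequencies and computes the PAM-vs-non-PAM specificity index.
"""

import numpy as np

from pamscope import hbonds as hb
from pamscope import structure as st

# --- geometric criterion: linear N-H...O at increasing distance ------------
model_coords = np.zeros((3, 3))
model_coords[1] = [0.101, 0.0, 0.0]          # H bonded to the donor N

for d_angstrom in (2.9, 3.5, 3.6):
    coords = model_coords.copy()
    coords[2] = [d_angstrom / 10.0, 0.0, 0.0]  # acceptor O on the N-H axis
    model = st.StructureModel(
        atom_id=np.arange(1, 4),
        atom_name=np.array(["N", "H", "O"], dtype=object),
        element=np.array(["N", "H", "O"], dtype=object),
        residue_number=np.array([1, 1, 2]),
        residue_name=np.array(["ARG", "ARG", "DG"], dtype=object),
        chain_id=np.array(["A", "A", "B"], dtype=object),
        mass=np.array([14.007, 1.008, 15.999]),
        coordinates=coords,
    )
    traj = st.TrajectoryEnsemble(model, coords[None])
    found = hb.detect_hbonds(
        traj,
        donors=st.selection_from_indices(model, [0]),
        hydrogens=st.selection_from_indices(model, [1]),
        acceptors=st.selection_from_indices(model, [2]),
    )
    present = bool(found and found[0].presence[0])
    print(f"d(N,O) = {d_angstrom} A, angle 0 deg -> hydrogen bond: {present}")

# --- normalization and specificity ------------------------------------------
# per-category H-bond frequencies for one arginine (PAM nucleobase, PAM
# backbone, non-PAM nucleotides), e.g. from detect_hbonds on a trajectory
freqs = {"PAM-NB": 0.55, "PAM-BB": 0.15, "non-PAM": 0.10}
norm = hb.normalize_frequencies(freqs)
print("\nnormalized frequencies:", {k: round(float(v), 3) for k, v in norm.items()},
      f"(sum = {sum(norm.values()):.1f})")

si = hb.specificity_index(
    freq_pam=freqs["PAM-NB"] + freqs["PAM-BB"],
    freq_non_pam=freqs["non-PAM"],
    err_pam=0.05, err_non_pam=0.02, residue="R1335",
)
print(f"specificity index for {si.residue}: {si.value:.2f} +/- {si.error:.2f}")
print("(values > 1 mean the arginine hydrogen-bonds preferentially to the "
      "PAM nucleotides rather than to the rest of the DNA)")
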