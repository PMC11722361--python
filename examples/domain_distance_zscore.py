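"""Domain-domain COM distance distributions and a two-tailed Z comparison.

Emulates the open/closed conformational change of a two-domain protein: one
ensemble fluctuates around a 31.6 A inter-domain distance (closed), the
other around 41.6 A (open), and the shift is tested with autocorrelation-
corrected Z statistics.
"""

import numpy as np

from pamscope import conformation as conf
from pamscope import structure as st

rng = np.random.default_rng(5)


def two_domain_trajectory(separations_angstrom):
    coords = np.zeros((4, 3))
    model = st.StructureModel(
        atom_id=np.arange(1, 5),
        atom_name=np.array(["CA", "CA", "CA", "CA"], dtype=object),
        element=np.array(["C"] * 4, dtype=object),
        residue_number=np.array([500, 501, 800, 801]),
        residue_name=np.array(["ALA"] * 4, dtype=object),
        chain_id=np.array(["A"] * 4, dtype=object),
        mass=np.full(4, 12.011),
        coordinates=coords,
    )
    frames = np.zeros((len(separations_angstrom), 4, 3))
    frames[:, 2:, 0] = np.asarray(separations_angstrom)[:, None] / 10.0  # nm
    return st.TrajectoryEnsemble(model, frames), model


closed = rng.normal(31.6, 1.0, 3000)
open_ = rng.normal(41.6, 1.0, 3000)

traj_closed, model = two_domain_trajectory(closed)
dom_a = st.selection_from_indices(model, [0, 1], "REC3-like")
dom_b = st.selection_from_indices(model, [2, 3], "HNH-like")
dist_closed = conf.com_distance_series(traj_closed, dom_a, dom_b)

traj_open, _ = two_domain_trajectory(open_)
dist_open = conf.com_distance_series(traj_open, dom_a, dom_b)

print(f"closed-state COM distance: {dist_closed.mean:6.2f} A "
      f"({len(dist_closed.bin_edges) - 1} histogram bins, Scott's rule)")
print(f"open-state COM distance:   {dist_open.mean:6.2f} A")

z, p = conf.compare_distributions_z(
    dist_closed.distances, dist_open.distances, tau_a=5.0, tau_b=5.0
)
print(f"two-tailed Z comparison: Z = {z:.1f}, p = {p:.2e}")
print("(p < 1e-4: the ~10 A domain opening is highly significant even after "
      "discounting temporal correlation in the sampled frames)")
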