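"""Quasi-harmonic conformational entropy on a planted Gaussian ensemble.

Draws a 10-atom trajectory from a known diagonal coordinate covariance and
compares the entropy estimated from the sampled mass-weighted covariance
with the closed form evaluated on the planted eigenvalues.
"""

import numpy as np

from pamscope import conformation as conf
from pamscope import structure as st
from pamscope import synthetic as syn

rng = np.random.default_rng(17)
masses = rng.uniform(10.0, 20.0, 10)          # amu
variances = rng.uniform(1e-4, 5e-3, 30)       # nm^2 per coordinate

traj, truth = syn.gen_gaussian_ensemble(variances, masses, n=50_000, seed=17)
selection = st.selection_from_indices(traj.reference, range(10), "all atoms")

result = conf.quasiharmonic_entropy(traj, selection, temperature=300.0,
                                    remove_rigid_body=False)
s_true = conf.entropy_from_eigenvalues(truth["mass_weighted_eigenvalues"], 300.0)

print(f"estimated quasi-harmonic entropy: {result.entropy:8.2f} J/mol/K")
print(f"closed form from planted modes:   {s_true:8.2f} J/mol/K")
print(f"relative error:                   {abs(result.entropy - s_true)/s_true:8.2%}")
print(f"softest mode frequency:           {result.frequencies.min():8.3f} 1/ps")
print("(each covariance eigenvalue lambda maps to an oscillator with "
      "omega = sqrt(kB*T/lambda); soft, high-amplitude modes dominate S)")
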