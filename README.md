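# pamscope

Analysis machinery for studying how DNA-binding proteins read a recognition
motif, modelled on the question of PAM recognition by Cas9-family proteins:
which arginine–DNA contacts form and how often, how specific the
hydrogen-bonding is to the PAM, how flexible the reading residues are, how
domains rearrange, and what the underlying free-energy landscapes and
mutation free energies look like.

The package is a library of seven modules, each independently usable:

| module | what it does |
|---|---|
| `pamscope.structure` | PDB structures/trajectories, atom selections, unit conventions |
| `pamscope.contacts` | dual-criterion contact classification (COM distance **and** interaction energy), occupancy statistics with autocorrelation-corrected errors |
| `pamscope.hbonds` | geometric hydrogen-bond detection (3.5 Å / 30°), frequency normalization, PAM-specificity index |
| `pamscope.conformation` | Kabsch superposition, backbone RMSD, side-chain RMSF, domain COM-distance densities with two-tailed Z comparison, quasi-harmonic entropy |
| `pamscope.metadynamics` | well-tempered metadynamics engine (multiple walkers, harmonic walls, PLUMED-style HILLS logs), FES reconstruction and convergence diagnostics |
| `pamscope.alchemy` | MBAR free energies with uncertainties, λ-window schedule optimization to a target exchange acceptance, thermodynamic-cycle ΔΔG, block-averaged enthalpy decompositions |
| `pamscope.synthetic` | generators with closed-form ground truth for every stage |

The statistical core in brief: contact/H-bond indicators are Bernoulli
series whose standard errors use effective sample counts
n_eff = n·Δt/(2τ) from the integrated autocorrelation time τ; entropy is
the quantum quasi-harmonic sum S = R·Σ[x/(eˣ−1) − ln(1−e⁻ˣ)] over
mass-weighted covariance eigenmodes; well-tempered metadynamics recovers
F(s) = −(γ/(γ−1))·V(s) from tempered Gaussian hills; and alchemical ΔG
comes from the self-consistent MBAR equations with asymptotic covariance.
Details, defaults and numerical choices are in [docs/methods.md](docs/methods.md).

## Worked example

`examples/` contains one narrative script per capability.  For instance,
the free-energy workflow (`python examples/mbar_free_energy.py`):

```
optimized lambda schedule: [0.   0.25 0.5  0.75 1.  ]
neighbor acceptance rates: [0.37  0.259 0.197 0.145] (all >= 0.10: True)

MBAR dG(0->1) = 1.631 +/- 0.127 kJ/mol (analytic 1.729, -0.8 sigma)
cycle ddG = -4.50 +/- 0.50 kcal/mol (negative: the mutation favours the DNA-bound state)
residue R1335: dE = -120.0 +/- 0.1 kJ/mol (4500 frames after discarding the first 10%)
```

The λ windows of a harmonic test family are spaced until every neighbor
pair exchanges with ≥10% Metropolis acceptance; MBAR then recovers the
analytic free-energy difference within its estimated uncertainty, and two
mutation legs combine into a thermodynamic-cycle ΔΔG whose sign convention
(negative = DNA binding favoured) matches standard alchemical practice.

And the sampling engine (`python examples/well_tempered_metadynamics.py`):

```
deposited 16000 hills over 2000 ps x 4 walkers
hill heights decayed from 0.963 to 0.006 kJ/mol (well-tempered decay)
barrier: 2.42 kJ/mol (reference 2.50)
inter-basin dF: +0.10 kJ/mol (0 by symmetry)
block-wise FES deviation from the final block (kJ/mol): [0.9  0.31 0.28 0.22 0.  ]
```

Four walkers reconstruct the 2.5 kJ/mol double-well barrier from the shared
hill log; the block-wise deviations shrinking toward zero are the
convergence diagnostic.

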