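# allonet

Residue interaction-energy correlation networks, ligand occupancy and
helix tilt-angle analysis for coarse-grained molecular-dynamics
trajectories of pentameric ligand-gated ion channels (pLGICs) and
similar multi-subunit proteins.

## The problem

General anesthetics bound at one site of a channel such as GLIC (the
*Gloeobacter violaceus* ligand-gated ion channel) change conformational
dynamics at distant effector sites. The signal travels through an
*internal allosteric network* of energetically coupled residues. This
package infers that network from a trajectory's nonbonded
residue–residue interaction energies rather than from positions:

1. For every non-adjacent residue pair (i, j), the per-frame nonbonded
   interaction energy E_ij(t) is computed (shifted Lennard-Jones plus
   optional short-range Coulomb, minimum-image periodic boundaries).
   Pairs with |mean energy| below 0.02 kcal/mol (0.08368 kJ/mol) are
   discarded.
2. The **pair correlation matrix** C holds the Pearson correlation over
   frames between every two retained pair series,

       C_mn = Σ_t (E_m(t) − Ē_m)(E_n(t) − Ē_n) /
              √[ Σ_t (E_m(t) − Ē_m)² · Σ_t (E_n(t) − Ē_n)² ],

   keeping entries with |C| > 0.4.
3. The **residue correlation matrix** R projects C back onto residues:
   R_ij = Σ_{m≠n} |C_mn| over retained pairs m containing i and n
   containing j. Row sums of R score each residue's coupling to the
   whole structure; residues above the 75th percentile are the network's
   **hot-spots**. Element-wise RMS averages compare binding conditions
   (consensus and difference matrices), and divisive (DIANA-style)
   clustering of the rows of R under D_ij = ‖R_i − R_j‖ yields a
   cross-sectional decomposition of the network.

Alongside the network core, the package computes **ligand occupancy**
(fraction of frames with any ligand bead within 7 Å of a residue's
backbone bead, combined across subunits) and the **radial/lateral tilt**
of pore-lining helices and extracellular leaflets against the pore axis,
with Mann-Whitney-Wilcoxon comparisons between conditions under a
Bonferroni-corrected threshold.

A synthetic-data module generates pentamers with scripted tilt
schedules, scripted ligand contact plans and latent-factor-correlated
energy series, so every analysis step is testable against known ground
truth.

## Worked example

```python
import numpy as np
from allonet import InteractionCorrelationModel
from allonet.synthetic_data import SyntheticSpec, make_coupled_series

planted = [("A", 0), ("A", 3), ("B", 5), ("C", 8), ("D", 2), ("E", 10)]
spec = SyntheticSpec(
    n_frames=2000, seed=101, sigma_e=0.5,
    planted_modules=[{"residues": planted, "loading": 0.8}],
    n_background_pairs=40,
)
series, manifest = make_coupled_series(spec)
results = InteractionCorrelationModel(series).fit()
print(results.summary(top=6))
print(sorted(results.hotspots(percentile=75).members))
```

prints

```
Interaction-correlation network
===============================
frames:                2000
pairs (input):         55
pairs retained:        55 (|mean E| >= 0.08368 kJ/mol)
pair correlations:     210 (|C| > 0.4)
residues in network:   60

top 6 residues by correlation score:
      ('D', 2)     87.0516
     ('E', 10)     86.9310
      ('A', 0)     86.9305
      ('A', 3)     86.9167
      ('B', 5)     86.7246
      ('C', 8)     86.6483
[('A', 0), ('A', 3), ('B', 5), ('C', 8), ('D', 2), ('E', 10)]
```

The six residues sharing the planted latent factor (within-module
Pearson correlation λ²/(λ²+σ²) = 0.64/0.89 ≈ 0.72, above the 0.4 cut)
dominate the scores and are recovered exactly as the 75th-percentile
hot-spot set; the 40 background pairs contribute no retained
correlations.

End-to-end runs are driven by a YAML config:

```sh
allonet run --config run.yaml --seed 1
```

with stages `simulate, energies, correlate, project, consensus,
hotspots, cluster, occupancy, tilt, compare`, each writing
delimited-text artifacts plus a content-hash cache and a run report.

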