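# Methods

## Interaction-correlation networks

The analysis assumes a coarse-grained (MARTINI-style) representation in
which all protein–protein nonbonded energetics are short-ranged:
12-6 Lennard-Jones plus a screened short-range Coulomb term whose
long-range part is absent by construction. Per frame, the interaction
energy E_ij of residues i and j sums all bead-pair terms under
minimum-image periodic boundary conditions (orthorhombic boxes only;
triclinic input is rejected). Sequence-adjacent residues of a chain
(|Δindex| = 1) are covalently bonded and excluded; there is no other
bonded topology, so no 1-3/1-4 scaling applies.

Three truncation dialects are provided because analysis pipelines meet
all of them in practice:

- `plain`: truncated at r_cut, discontinuous there;
- `cut_shift`: the potential is shifted by its cutoff value;
- `gromacs_shift` (default): the classic polynomial force-shift applied
  separately to the r⁻¹² and r⁻⁶ terms over [r_shift, r_cut]
  (defaults 0.9 and 1.2 nm, the common coarse-grained choice), and to
  the Coulomb r⁻¹ term over [0, r_cut]. Energy and force are continuous
  and vanish at the cutoff; for a 1/r^p term the shifted force is
  p/r^(p+1) + A(r−r₁)² + B(r−r₁)³ with A, B fixed by F(r_c) = F′(r_c) = 0
  and the integration constant fixed by V(r_c) = 0.

Coulomb uses ε_r = 2.5 by default (the polarizable-water convention) and
can be disabled; whether the original analyses summed LJ only or
LJ + short-range Coulomb is not documented anywhere we know of, so both
are supported with LJ + Coulomb as the default. Neighbor search uses a
periodic KD-tree keyed on r_cut; it is contractually identical to the
all-pairs double loop and tested as such.

### Filters and matrices

Pairs whose time-mean energy has magnitude below 0.02 kcal/mol
(0.08368 kJ/mol, the exact conversion) are discarded. The filter acts on
|mean|: interaction energies are predominantly negative, and a literal
one-sided reading would discard every attractive contact.

The pair correlation matrix is the Pearson coefficient between retained
pair series over frames. Constant (zero-variance) series yield no
entries rather than 0/0. Entries with |C| ≤ 0.4 are dropped; negative
correlations are retained by magnitude since the projection below takes
absolute values anyway and anticorrelation carries the same allosteric
information.

The residue correlation matrix sums |C_mn| over *ordered* retained-pair
pairs (m, n), m ≠ n, with residue i ∈ m and j ∈ n. Iterating ordered
pairs doubles every entry relative to unordered iteration — a global
factor that cancels in rankings, percentile cuts and overlap statistics;
ordered was chosen for symmetry of implementation. Self pair-pairs
(m = n) are excluded by default: each would add a constant |C_mm| = 1
per directly interacting pair and swamp the signal (a flag restores
them). The diagonal R_ii is computed by the same formula but zeroed
before row-sum scoring, so scores measure coupling to the *rest* of the
structure; this too is configurable.

Scores may be folded across subunits of a homo-oligomer by the per-
position mean (sum gives identical rankings). Hot-spots are residues
*strictly above* the percentile cut (default 75th), with the percentile
computed by linear interpolation between closest ranks — the numpy
default, fixed here as the documented convention. With all-equal scores
the hot-spot set is empty by construction.

Cross-sectional clustering uses D_ij = ‖R_i − R_j‖ over all columns
(including columns i and j; a masking option exists) and a hand-written
DIANA-style divisive procedure: repeatedly split the cluster of largest
diameter, seeding the splinter with the object of maximal average
dissimilarity and migrating objects whose average dissimilarity to the
splinter is lower, one object at a time. No installed library provides
divisive clustering, hence the in-package implementation; it is
deterministic given D, with ties broken toward the lowest index. The
default stop is 10 flat clusters, matching the scale of structure
observed in channel analyses; a diameter-threshold stop is available.

## Occupancy and tilt geometry

A residue copy is occupied in a frame when the minimum-image distance
from its central backbone bead to *any* ligand bead is below the cutoff
(default 0.7 nm). Copies combine across subunits by the mean of per-copy
fractions (default; keeps proportions comparable under multi-ligand
floods) or by "any". Ligand proximity is the minimum over ligand beads
because no single reference bead is canonical for a multi-bead ligand.

Element axes are the major principal axes (largest-eigenvalue
eigenvector of the coordinate covariance) of an element's backbone
beads, sign-oriented along the pore axis. The pore axis is either fixed
+z through the backbone centroid or the per-frame principal axis of all
backbone beads, oriented extracellular-positive. The tilt decomposition
builds e_z = pore axis, e_r = outward radial direction at the element
centroid, e_t = e_z × e_r, and reports radial = atan2(u·e_r, u·e_z),
lateral = atan2(u·e_t, u·e_z) in degrees. Sign conventions (radial
positive = leaning away from the pore; lateral by the right-handed
tangent) are fixed by this construction; the synthetic generator uses
the identical convention, which is what recovery tests rely on.

Summaries report per-element mean and sample (n−1) standard deviation,
plus Δ = condition mean − reference mean. Conditions are compared per
element and angle with the two-sided Mann-Whitney-Wilcoxon test: exact
when both samples have ≤ 8 values and no ties, otherwise the normal
approximation with tie correction; identical constant samples give
p = 1. Trajectory frames are autocorrelated, so testing every frame
(stride 1, the default, mirroring common practice) is anti-conservative;
`decorrelate_stride` subsamples frames first and is the statistically
safer choice. The Bonferroni threshold α/n takes the comparison count as
an explicit parameter — published analyses count the family globally
across conditions (e.g. 120), which cannot be inferred from a single
two-condition comparison.

## Synthetic ground truth

The generator builds a five-chain pseudo-symmetric pentamer about z.
Each chain contributes a straight "helix" rod and, above it, a
"leaflet" rod of backbone beads whose directions realize the scheduled
(radial, lateral) tilts exactly before i.i.d. isotropic Gaussian
positional noise is added. Default schedules use per-subunit values
typical of a resting channel (helix radial ≈ 10–14°, lateral ≈ −1 to
−6°); rods rather than true helices suffice because the decomposition
contract concerns principal axes, not secondary structure. No dynamics
are emulated — the analysis consumes only coordinates and energies.

Scripted ligand contacts place one single-bead ligand per (position,
subunit) within 0.45·cutoff of the backbone bead in exactly
round(f·n_frames) pseudo-randomly chosen frames and park it far from the
protein otherwise, so both combine modes recover the planned fraction
exactly. Neighbouring positions within the cutoff of a contact point
acquire incidental occupancy; planned positions are the ground truth.

Planted energy correlations use a latent-factor (spiked covariance)
model: within a module, E_ij(t) = μ_ij + λF(t) + ε_ij(t) with a shared
standard-Gaussian factor and i.i.d. noise σ_E, giving the analytically
known within-module correlation λ²/(λ²+σ_E²) — with the default λ = 0.8,
σ_E = 0.5 that is ≈ 0.72, comfortably above the 0.4 cut, while
background pairs at 2000 frames have correlation fluctuations of order
1/√T ≈ 0.02. Baselines μ (≈ −1 kJ/mol with ±10% jitter) exceed the
mean-energy filter except for explicitly requested sub-threshold decoys.
Every generator is deterministic under its seed and emits a
machine-readable manifest of its ground truth.

What passing these tests shows — and does not. Synthetic data exercise
the estimators' contracts (exact geometric recovery, known correlation
structure, scripted occupancy) at desk scale: tens of residues and a few
thousand frames. They do not reproduce the density of contacts, the
autocorrelation, or the conformational heterogeneity of a real
multi-microsecond membrane-protein trajectory, so passing says the
machinery is correct, not that any particular biological network would
be recovered at a given trajectory length.

## Numerical choices and limitations

- Units: nm and kJ/mol internally; file formats convert at the boundary
  (PDB Å ↔ nm; 0.02 kcal/mol = 0.08368 kJ/mol exactly; 7 Å = 0.7 nm).
- Residue indexing is 0-based internally; the 1-based numbering of
  GRO/PDB converts at I/O. GRO has no chain field: chains are delimited
  by residue-number restarts and labelled A, B, C, … in file order; PDB
  preserves chain IDs. Bead types double as atom names (MARTINI-style
  BB/SC1), so write/read round-trips preserve the backbone flag.
- Multi-frame trajectories are concatenated-frame GRO or multi-model
  PDB; binary trajectory codecs are out of scope.
- Zero-variance series, empty hot-spot sets under ties, and degenerate
  tilt geometry (element centroid on the pore axis) raise or return the
  documented values rather than propagating NaNs.
- Pipeline artifacts are delimited text with content-hash sidecars;
  reruns with identical configs are bit-identical, and the O(P²)
  correlation stage is cached.
- The acceptance script uses 2000-frame series, a 110-bead pentamer and
  1000-replicate null calibrations — sizes chosen so the whole suite
  recomputes in seconds while leaving every statistical margin wide.
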