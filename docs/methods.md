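# Methods

Conventions, parameter defaults and their rationale, and the known
limitations of each component. Units are Å for lengths, degrees for
angles, unless stated otherwise.

## Map and model representation

A `DensityMap` stores a 3-D grid indexed `[ix, iy, iz]` (x fastest in
index order), per-axis voxel size, and the Å position of the center of
voxel `(0, 0, 0)` as the origin. MRC/CCP4 files are read through
gemmi; grids are normalized to x/y/z axis order on input regardless of
the file's axis permutation, and the origin is taken from the header
ORIGIN words when nonzero, else from the start-index words times the
voxel size. Non-orthogonal cells are rejected — the package targets
single-particle maps, which are orthorhombic in practice.

An `AtomicModel` is an ordered list of atoms keyed by (chain, residue
number, atom name). PDB input keeps the highest-occupancy altloc,
drops waters and HETATM records by default, and requires residue order
to be monotone within a chain. Hydrogens are read but excluded from
density simulation by default (negligible scattering contribution).

## Simulated density

Each heavy atom contributes an isotropic Gaussian

    rho_i(r) = Z_i / ((2 pi)^{3/2} sigma^3) * exp(-|r - x_i|^2 / (2 sigma^2))

with `sigma = resolution / (2 sqrt(2 ln 2))`, i.e. the kernel FWHM
equals the nominal resolution, scaled by a configurable
`sigma_factor`. The kernel is **mass-normalized** (each atom
integrates to its atomic number), so coarsening the resolution lowers
peaks and widens them while conserving total mass — the property that
makes resolution comparisons and the flexible-region blur (below)
well-behaved. Kernels are truncated at 3 sigma. Default voxel size
1 Å, grid padding 5 Å around the model.

The molecular mask marks voxels whose centers lie within
`2.5 + resolution/2` of any atom: an atomic-contact core (2.5 Å)
plus a term growing with the blur, so the mask tracks the visible
envelope rather than the atomic van der Waals surface.

## Global scores

- `ccc`: cosine similarity of the two grids (no mean offset). Equals
  1.0 iff the maps are proportional.
- `real_space_cc`: Pearson correlation (mean-offset) over a voxel
  selection. Modes: `box` (all voxels), `volume` (the N highest
  voxels of the model map, N = molecular-mask voxel count), `mask`
  (the molecular mask itself), `peaks` (union of the top-N voxels of
  both maps). Top-N selection breaks ties by ascending linear index
  (deterministic across runs).
- `mutual_information`: 20-bin joint histogram over the value ranges,
  MI in bits. Constant maps give 0.
- `atom_inclusion`: fraction of atoms whose trilinearly interpolated
  density is at or above a contour threshold. The default threshold
  is "contour by volume": the level enclosing as many voxels as the
  molecular mask, which makes the self-fit identity (inclusion = 1 on
  a model's own clean map) hold by construction.

Degenerate inputs (all-zero map, constant selection) raise
`UndefinedScoreError` rather than returning NaN silently; `score_all`
converts per-model failures into all-NaN rows so one bad model cannot
abort a batch.

## Local scores

**SMOC** (sliding-window Manders overlap): for each residue, the
window of `window` residues centered on it (default 7, truncated at
chain termini) defines a set of atoms; the score is
`sum(A*B) / sqrt(sum(A^2) * sum(B^2))` over voxels whose centers lie
within `radius` of any window atom (sphere union). The default radius
`3 + resolution/4` covers side-chain density at the evaluated
resolutions. Scores lie in [0, 1] for non-negative maps; the self-fit
value is 1 at every residue. Displacing one residue leaves windows
that cannot see it bit-identical; in practice the influence extends
about two residues beyond the window half-width through the sphere
union and kernel tails.

**Side-chain chi1 peak statistic** (`emringer_like`): for every
eligible residue (unbranched-at-CB types with CA, CB present), a Cγ
probe is swept around the Cα–Cβ axis (bond 1.52 Å, angle 114°) and
the interpolated density peak angle is recorded. For each threshold
in a quantile schedule over the positive map values (20 quantiles,
0–0.95), residues whose peak density passes the threshold are tested:
a peak is *rotameric* if within ±30° of 60/180/300°. The binomial
z-score against p = 0.5 is rescaled by `sqrt(n_scanned / n_at_threshold)`
and the statistic is the maximum over thresholds. This is a
simplification of the published side-chain scan: fixed ideal ring
geometry, one probe atom, threshold schedule from map quantiles. It
is intended for relative comparisons on the synthetic fixtures, not
as a reimplementation of the original tool.

## Refinement

The model is a Gaussian mixture with one component per atom (width
`sigma`, default `resolution / pi` — narrower than the simulation
kernel so atoms compete for density at sub-kernel distances). The
responsibility of atom i at voxel v is `R_i(v) = G_i(v) / sum_j G_j(v)`
(kernels truncated at `kernel_cutoff` = 4 sigma), and the expectation
step moves each atom to

    x_i <- sum_v M(v) R_i(v) pos(v) / sum_v M(v) R_i(v)

with M the map clamped to non-negative values. Atoms whose kernels
see no mass stay in place. Each of the 5 macro-cycles alternates this
step with restraint regularization; a trace records ccc, displacement
and stereochemistry per cycle; if ccc drops by more than the
divergence guard (0.05) the loop stops and the best-so-far model is
returned.

Regularization minimizes harmonic bond and angle terms toward
idealized template values plus a soft-core repulsion between nonlocal
pairs (different chains or residue separation ≥ 2; onset 2.5 Å) with
L-BFGS-B and analytic gradients, under a per-call displacement cap
(default 1 Å inside refinement, 0.15 Å for fixture junction healing)
and optional frozen-atom masks. `stereo_report` summarizes bond RMSD,
angle RMSD and clash count (pairs closer than 2.1 Å). A
`MinimizerHook` protocol allows callers to observe or stop the inner
minimization.

## Segmentation

Per-chain soft weights `w(v) = S_target(v) / (S_target(v) + S_other(v) + 1e-12)`
where S_c sums unit Gaussians (width `sigma_seg`, default 2 Å ≈ an
atomic radius at the evaluated resolutions, cutoff 5 sigma) over the
atoms of chain c. Points equidistant from two single-atom chains get
exactly 0.5; voxels with no support get 0. The segmented map is the
input map times the weight, so scoring one chain of a complex ignores
density explained by its neighbors.

## Ensemble statistics

- Accuracy filtering consumes externally supplied GDT_TS/LDDT values;
  monomer targets require both strictly above 70, multimer targets
  only LDDT (a subunit can score low on rigid-body GDT_TS while
  locally accurate).
- Per-residue mean and SD of SMOC profiles across models use the n−1
  denominator; residues missing from some models are averaged over
  the models that contain them and flagged incomplete.
- `profile_correlations` reports the Pearson correlation of the
  ensemble SD (and mean) with the reference model's profile over
  shared residues. The expected signature on flexible regions:
  SD anticorrelates with the reference fit, the mean tracks it.
- `paired_improvement_test` is the one-sided paired t-test
  (after > before), computed in closed form; degenerate cases are
  explicit (no change → t = 0, p = 0.5; constant nonzero shift →
  ±inf, p = 0).
- `score_correlation_matrix` correlates score columns across models
  with pairwise deletion, optionally dropping targets with ≤ 10
  models first.

## Synthetic fixtures

Structures are built from ideal internal coordinates by sequential
placement: helix (φ, ψ) = (−57°, −47°), strand (−120°, 120°), loops
with random coil-like torsions rejected on CA–CA clashes (< 3.2 Å,
|Δresidue| ≥ 3; loops only check the CA trace, so occasional O/CG
contacts can survive in loop regions). Each residue carries N, CA, C,
O, CB and an unbranched CG (side-chain statistics computable), with
the CB placement torsion solved so the built geometry is an exact
fixed point of the restraint set. Chains are laid side by side with
≥ 8 Å gaps.

Perturbation recipes generate the characteristic prediction error
classes: `loop_shift` (random per-residue displacement of fixed
length), `sse_shift` (rigid translation by exactly the magnitude),
`sse_rotate` (rigid rotation about the segment's principal axis),
`domain_reorient` (rigid rotation about the first residue's CA).
Rigid recipes freeze the perturbed segment and locally regularize the
two flanking residues (cap 0.15 Å) to heal the junction; a
zero-magnitude recipe is the identity.

`simulate_experimental_map` degrades the clean map: atoms in declared
flexible regions are rendered with twice the Gaussian width
(mass-preserving, peak drops 8-fold — locally lower resolution), then
Gaussian noise with SD = `noise_sd` × map peak is added and the map
clamped to non-negative values. `make_ensemble` jitters each residue
rigidly with RMS 0.3 Å (1.5 Å in flexible regions), reproducing the
elevated inter-model variability where the map is degraded.

All randomness derives from a single seed through named sub-streams
(structure / perturbation / noise), so each stage is independently
reproducible and ensembles have the prefix property (the first k
models do not depend on the ensemble size).

## Problem sizes and runtime

The package is exercised on 20–30-residue chains and 40–70³ voxel
grids at 1 Å voxels: full test suite ~25 s, the acceptance report
(`scripts/acceptance.py`) ~15 s on one CPU. The dense per-atom
responsibility reference (`responsibilities_dense`) is O(atoms ×
voxels) and intended only for validation; the production update uses
per-atom local cubes.

## Limitations

- Density simulation ignores atomic B-factors, solvent, and
  resolution anisotropy; amplitude is proportional to atomic number
  rather than electron scattering factors.
- The side-chain statistic uses idealized ring geometry and a
  simplified threshold schedule (see above).
- Refinement moves atoms independently per expectation step; large
  rigid-body errors (≫ the kernel cutoff) are outside its capture
  range.
- The synthetic maps are Gaussian-kernel renderings plus white noise;
  they do not emulate CTF effects, masking artifacts, or the noise
  spectra of real reconstructions. They reproduce the *relationships*
  the analyses detect (local degradation ↔ fit ↔ ensemble
  variability), not real map statistics.
- GDT_TS and LDDT are consumed as inputs, never computed.
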