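# Methods

## Model and procedure

The package maps a protein's conformation space by stochastic optimization
in a data-defined reduced space rather than by simulating dynamics. The
working assumptions are:

* **Conformational selection.** Structures deposited for a wildtype and its
  near variants (at most 3 substitutions) are treated as representatives of
  stable or semi-stable states available to *any* sequence of the family,
  possibly with different weights. Their CA traces can therefore be threaded
  onto a target sequence and used both to define the search space and to
  seed the search.
* **Linearity of the dominant motions.** PCA over aligned, centered CA
  traces is assumed to capture the functionally relevant collective motions
  in its top components, so that a d-dimensional linear subspace (with d
  chosen by reconstruction error on withheld traces) is a usable search
  space. Nonlinear dimensionality reduction is deliberately out of scope.
* **Energies come from a backend.** The search itself is agnostic to the
  energy model; fitness is whatever scalar the refinement backend returns
  (lower is fitter). Landscapes built from those energies are potential
  energy maps with no entropic term.

The search loop is: seed (project + refine each experimental trace, double
the population until one more doubling would exceed P, top up one at a
time), then for each of N generations reproduce every parent (variance-
scaled uniform step), refine and re-project every offspring, and apply
crowding selection on the (PC1, PC2) grid. Every refined offspring is
archived; the landscape is built from the archive, not the final
population, because the archive is the actual sample of the energy surface.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| population size P | 500 | individuals | large enough to cover several basins; doubling-based seeding reaches it from tens of seeds |
| generations N | 100 | — | convergence of diversity/best-energy curves is typically visible by generation 50; 100 adds margin |
| max step s_max | 1.0 | PC units (Å·√M scale) | steps along PC1 of at most one grid cell; other PCs scaled down by Var(PCᵢ)/Var(PC₁) |
| dimensionality d | 10 | PCs | default for study-scale ensembles; `select_dimensionality` recomputes it per dataset |
| neighborhood C | 25 | cells | 5x5 block; preserves diversity while keeping selection pressure local |
| cell width | 1.0 | PC units | matches the landscape grid so selection locality and landscape cells coincide |
| selection RMSD threshold | 0.5 | Å | reconstruction error at which a withheld trace is considered recovered; config-overridable |
| functional threshold | max seed energy | backend units | no retained conformation may score worse than the worst refined experimental structure; applied post hoc only, never during search |
| outlier rule k | 3.0 | robust σ | flag traces with alignment RMSD > median + k·max(1.4826·MAD, 0.1·median); advisory only |

Surrogate backend: w_clash = 1.0, w_anchor = 0.5, 50 descent steps of at
most 0.05 Å per atom with backtracking (energy never increases). Synthetic
landscape backend: Gaussian wells, optional gradient-descent refinement
(default 3 steps at rate 0.4 in the benchmark setup) standing in for the
local minimization an all-atom engine would perform.

## Numerical choices

* **Superposition** uses the SVD-based Kabsch solution with the determinant
  sign correction, so reflections are never returned; (near-)collinear point
  sets raise a degeneracy error rather than returning an arbitrary rotation.
* **Matrix conventions.** The data matrix is n x 3M (one row per trace); PCs
  are stored as orthonormal columns, projection is `(CT − AT) · U`. PC signs
  are fixed so each component's largest-magnitude entry is positive, making
  bases reproducible across runs. Variances use the n−1 divisor. Coordinates
  are centered but not standardized before the SVD — all coordinates share
  units (Å), so scaling would distort the motion amplitudes.
* **Projection frame.** Traces not part of the training alignment are
  Kabsch-aligned to the mean trace before projection. Inside the search
  loop, a backend's refined trace is aligned back onto its pre-refinement
  trace before re-projection, which removes exactly the rigid drift the
  refinement introduced and makes an identity backend a strict no-op.
* **Selection determinism.** Offspring are processed in a seeded-random
  order; a surviving offspring immediately joins the parent pool
  (overlapping model). The replacement target is the worst-fitness candidate
  in the neighborhood, ties broken toward the lowest population slot, and an
  equal-energy offspring never displaces an incumbent. These choices make
  runs bit-reproducible from the run seed.
* **Grid indexing** floors coordinates from origin 0, so negative
  coordinates fall in cells −1, −2, … deterministically. Landscape cell
  statistics are exact (median; sample variance with n−1, zero for
  singleton cells) and reported as offsets from the minimum cell.
* **Dimensionality selection** uses raw (non-superposed) reconstruction
  RMSD, which is exactly the rank-truncation residual norm and therefore
  provably non-increasing in d; if no candidate meets the threshold the
  largest is returned with an explicit flag.
* **Backbone reconstruction** places N, C, O analytically from ideal
  trans-peptide internal coordinates anchored on local CA bond frames,
  scaling along-bond offsets with the observed CA–CA distance. This is a
  deliberate simplification: it reproduces ideal bond lengths on well-formed
  traces and is exactly rigid-motion equivariant, but fits no dihedral
  libraries and does not reproduce a statistical reconstruction method's
  output. The search contract only requires a deterministic CA-to-backbone
  map.

## Synthetic fixtures: what they do and do not show

The generators produce trace ensembles as a base trace plus orthonormal
deformation modes with a prescribed variance spectrum. Modes are smooth
along the chain (low-frequency cosine profiles) and constructed orthogonal
to the six rigid-body directions of the base trace, so rigid alignment
leaves the deformations essentially intact and PCA output can be compared
against the generating spectrum. Amplitudes are Gaussian. The default
fixture mimics the study scale: a 166-residue chain, 46 training and 40
withheld samples, 10 modes with a decaying spectrum.

Real crystallographic ensembles differ in ways the fixtures do not emulate:
amplitudes are multi-modal (distinct functional states), modes are not
exactly orthogonal to rigid motions after imperfect alignment, coordinate
noise is heteroscedastic, and energies come from a rugged all-atom surface
rather than smooth Gaussian wells. Passing tests therefore demonstrate the
correctness of the machinery (projection algebra, operators, selection,
bookkeeping, determinism) and the search's ability to find well-separated
minima in a known surface — not the physical accuracy of any particular
energy model on real proteins, which is entirely delegated to the backend.

The four-basin benchmark (`basin_search_setup`) fixes a 60-residue,
five-mode ensemble (variances 40…4) and four Gaussian wells with centers at
least 5 PC units apart in the top-2 coordinates, depths 1–2, widths
0.8–1.2: deep enough to be unambiguous, separated by more than the per-
generation step so discovery requires sustained exploration, and small
enough to run in seconds.

## Design decisions taken where the design was open

* Outlier handling is an explicit robust rule (median + k·MAD with a
  relative floor) with caller-side override, instead of manual curation.
* Chain choice for multi-chain entries is per-id configuration; by default
  the first chain is used.
* 'X' residues count as mismatches in mutation counting (conservative).
* The crowding loser is the worst-fitness neighborhood member — standard
  crowding, preserving the best local individual.
* The energy threshold is derived, not fixed: the maximum refined-seed
  energy generalizes a fixed conservative cutoff to arbitrary backends.
* Landscape medians are computed over all archived functional conformations
  (the archive is the sample of the surface), not the final population.
* Basin labeling is automatic (4-connected components below a depth
  cutoff, numbered by ascending minimum) rather than manual annotation.

## Problem sizes

Tests and the acceptance script run at desk scale by design: PCA fixtures
use 166 residues with up to 500 samples; the search benchmark uses a
60-residue chain, P = 100 and 50 generations (5 100 refinements per run);
the selection oracle enumerates 800 random instances of at most 8
individuals. The full-scale configuration (P = 500, N = 100, d = 10) is the
default in `EAConfig` and the CLI and runs unchanged; with the built-in
backends it completes in minutes, while wall time with an external all-atom
engine is dominated entirely by the engine.

## Known limitations

* External all-atom engines are specified as a subprocess adapter contract
  and are not bundled; the surrogate backend is a CA-level stand-in with no
  claim to physical energetics (no side chains, no solvent, no force field).
* Equal-length traces are assumed throughout; there is no sequence-
  alignment-based residue correspondence for insertions/deletions.
* mmCIF support extends only as far as coordinate extraction; NMR models
  are excluded by the inclusion criteria.
* PCA is linear; strongly curved conformational manifolds would need more
  dimensions than their intrinsic dimensionality.
* Landscapes are potential-energy maps; no entropic or free-energy
  estimation is attempted.
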