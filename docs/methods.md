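# Methods

This note records the models, conventions and numerical choices behind
each metric, the design of the synthetic-data generators, and what the
passing tests do and do not establish about real simulation data.

## Superposition and RMSD

Rigid superposition is the closed-form weighted Kabsch solution
(SVD of the weighted cross-covariance), restricted to proper rotations:
if the best orthogonal map is a reflection, the smallest singular
direction is flipped. This matters for the dissimilarity threshold,
whose meaning ("as different as a mirror image") collapses if
reflections are allowed. Configurations with fewer than three points or
with rank < 2 (collinear) have no unique rotation and raise a
degeneracy error rather than returning an arbitrary frame.

`rmsd_series` superposes the *selection* (default Cα) of every frame
onto the reference selection and reports the RMSD of that selection.
Cα is the default because the similarity thresholds and the Lindemann
literature are calibrated on backbone/Cα measures; `backbone` and
`heavy` are selectable where a different convention is wanted.

The test suite checks the Kabsch result against an independent
brute-force minimizer (`tests/oracles.py`): rotation space is covered
with random unit quaternions and the incumbent is refined through
twelve shrinking perturbation levels, reaching an angular resolution
far below the 1e−6 Å agreement demanded. The oracle shares nothing
with the SVD path except the centroid translation, which is exact for
both.

## RMSF and analysis windows

RMSF(residue) is the square root of the time-averaged squared
displacement of the residue's selected atoms from their time-mean
positions. When alignment is on (default), each frame is superposed
onto the window-mean structure, one iteration: the mean of the raw
frames defines the target, frames are aligned, and the mean of the
aligned frames is the fluctuation reference. One iteration is standard
practice; further iterations change the profile by far less than
sampling noise on the ensembles used here.

Windows are expressed as fractions of the trajectory so the same
protocol applies at any length: scalar averages (RMSD, Rg) discard the
first 20 % of frames, and RMSF profiles use the final 10 % — the
fractional equivalents of "last 800 ns of 1 μs" and "last 100 ns".
Both are configurable per run.

## Block averaging

The analysis window is split into contiguous blocks (default: 16
blocks, the fractional equivalent of ~50 ns blocks over an 800 ns
window); a trailing partial block is discarded, never padded. The mean
is the mean of block means — identical to the grand mean over the used
frames whenever the block length divides the window — and the standard
error is the sample standard deviation of the block means divided by
√n_blocks. Fewer than two complete blocks is an error, not a silent
single-block estimate.

## Lindemann values

ΔL = ⟨RMSF⟩/a, with the mean taken over a residue set and
a = 4.375 Å, the average nonbonded-distance parameter used across the
protein Lindemann literature (configurable). Computing mean-RMSF first
and dividing once is algebraically identical to averaging per-residue
ratios; the former matches how the benchmark tables are captioned. The
core/surface split takes a user-supplied core residue list (the
benchmark's β-sheet cores were assigned structurally, with no published
algorithm — automatic core detection is out of scope); the surface is
the complement, and ΔL_total always lies between ΔL_core and ΔL_surf.
The experimental room-temperature band 0.15–0.16 for folded proteins is
carried as a report annotation, not a pass/fail check.

## Similarity thresholds and Rg references

The similarity (D0,sim) and dissimilarity (D0,dis) thresholds are
empirical functions of chain length. They are implemented as power laws
c·n^(1/3) — compact-globule size scaling — with prefactors calibrated so
that the thresholds at the 55-residue TSR4 construct equal the
published anchors 1.34 Å and 4.49 Å. The calibration anchors are the
only constants taken from the benchmark; the functional form is the
package's own choice and is the main approximation in this module. The
published empirical fits were built on globular proteins of ≥ 20
residues; smaller chains get an extrapolation flag. Verdicts are
inclusive at both boundaries: rmsd ≤ D0,sim is "similar", rmsd ≥ D0,dis
is "dissimilar".

The polymer-scaling Rg reference defaults to Rg = 3.0·n^(1/3) Å, a
poor-solvent (compact-globule) scaling parameterized against folded
PDB structures; it typically sits slightly above crystal-structure Rg
values, as solution ensembles do. Both prefactor and exponent are
plain parameters, since different compilations fit slightly different
constants.

## Dihedrals and helix classification

φ(i) = C(i−1)–N(i)–CA(i)–C(i) and ψ(i) = N(i)–CA(i)–C(i)–N(i+1),
computed with the IUPAC sign convention (verified against mdtraj in the
tests), wrapped to (−180°, 180°]. Terminal residues, and residues
missing a required backbone atom, are masked undefined; capping groups
that provide the terminal C/N atoms extend the defined range when
present in the topology. A residue needs both angles defined to
participate in classification, and undefined residues break sequential
runs.

Sequential definition: a residue is α-helical in a frame iff it belongs
to a run of ≥ 3 consecutive residues with φ ∈ [−160°, −30°] and
ψ ∈ [−67°, −7°] (closed intervals; the source wording "between" is
ambiguous, and the canonical helix values are deep inside the windows,
so the choice is inconsequential there).

Pairwise definition: for each defined pair, s = ψ(i) + φ(i+1) wrapped
to (−180°, 180°]; π for s ∈ [−135°, −115°), α for s ∈ [−115°, −95°],
3₁₀ for s ∈ [−85°, −65°], else none. The windows tile [−135°, −65°]
without overlap; the shared α/π boundary at −115° is assigned to α as a
deterministic tie-break. The label is attributed to residue i (a pair
convention must be fixed; this one keeps the profile aligned with ψ),
and in every frame the first and last defined pairs are excluded. The
"combined" profile is the percentage of frames carrying any pairwise
label; the sequential percentage is reported as a separate curve, never
merged into "combined".

## Synthetic generators

The generators emulate the *statistical structure* the analysis assumes
— nothing dynamical, no solvent, no forces — so recovering their ground
truth validates the estimators, not any force field.

- **Ideal helices**: poly-alanine N/CA/C/O backbones built by
  internal-coordinate chain extension (NeRF-style placement) with
  canonical dihedrals — α (−57°, −47°), π (−57°, −70°), 3₁₀
  (−49°, −26°) — trans ω, and standard geometry (N–CA 1.458 Å,
  CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; angles 111.2°/116.2°/121.7°).
  The builder and the dihedral extractor are mutual inverses to well
  under 0.5°.
- **Gaussian ensembles**: reference + i.i.d. zero-mean displacements of
  per-coordinate standard deviation σ (scalar, per-residue or
  per-atom). Without alignment, E[RMSF] = σ√3 exactly; with alignment,
  superposition absorbs ~6 rigid degrees of freedom and lowers RMSF by
  O(1/n_atoms) — the closed-form recovery tests therefore disable
  alignment. Frames are drawn in order from one seeded stream, so
  extending an ensemble never perturbs earlier frames.
- **Rigid-body ensembles**: uniform random proper rotations (via
  scipy's rotation sampler) plus bounded translations; every internal
  observable is exactly that of the reference.
- **Two-state helix/coil series**: each residue is independently
  helical with probability p_i per frame. The helical state carries the
  canonical dihedrals of the chosen type; the coil state keeps the
  helical φ and flips ψ uniformly into [120°, 180°] — a ψ-flip
  helix↔extended model, akin to the ψ-dominated α↔PPII/β exchange of
  real coil ensembles. This design makes the pairwise sum
  ψ(i) + φ(i+1) depend only on residue i's state, so the prescribed p_i
  *is* the expected classified helicity: coil sums land in [63°, 131°],
  far from every helix window, giving zero false positives. Both angles
  receive 2.5° Gaussian jitter (≈ 3.5° on the pair sum), which keeps a
  truly helical pair inside its ±10° window with probability > 0.987 —
  small enough that recovery holds to within binomial error at 10⁴
  frames. A larger per-angle jitter (e.g. 5°, giving ~7° on the sum)
  would misclassify 6–16 % of helical pairs and turn the generator's
  nominal p_i into a biased target, which is why the jitter is fixed
  where classification is effectively exact.

What passing the synthetic tests shows: the estimators are unbiased and
correctly scaled on ensembles satisfying their assumptions
(independent frames, Gaussian or two-state statistics, whole
molecules). What they do not show: robustness to autocorrelation beyond
what block averaging addresses, periodic-boundary artifacts (inputs are
assumed re-imaged/whole), force-field realism of the fluctuation
spectra, or the behavior of the similarity thresholds far outside the
chain lengths they were calibrated on.

## Problem sizes

The test suite and the acceptance script run on deliberately small
systems chosen to make the statistical tolerances meaningful: 10–20
residue backbones, 20 000 frames for σ-recovery (2 % tolerance), 10 000
frames for helicity recovery (3 binomial standard errors), 50 random
instances for the superposition oracle. These sizes put every
stochastic check several standard errors clear of its tolerance while
completing in seconds.

## I/O conventions

PDB structures are read through mdtraj: first model of multi-model
files, one protein chain (first by default, selectable), waters, ions
and heteroatoms excluded, hydrogens retained but excluded from the
default heavy-atom selections. Residues are re-indexed 0-based and
contiguous internally; original author numbering is kept for reports.
Trajectories (DCD/XTC) must match the topology atom count exactly — a
mismatch reports both counts rather than guessing a sub-selection.
Tables are CSV or JSON; table rounding for benchmark reproduction is
half-away-from-zero at 2 decimals.

## Known limitations

- The D0 thresholds use a calibrated power law, not the original
  empirical fit, whose constants are not reproduced here; only the
  anchored chain length is exact by construction and nearby lengths are
  approximations of the original fit.
- Core/surface Lindemann partitions require a user-supplied core list.
- Single chains only; no mmCIF; no PBC re-imaging; no reweighting of
  biased ensembles.
- The two-state generator's coil model is one-dimensional by design
  (ψ-flip); it is a device for exact ground truth, not a model of coil
  thermodynamics.
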