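# Methods

This note records the model, the fixed parameters, the synthetic data
generator, and the numerical/design choices behind `tcrkernel`.

## 1. Structural representation

A TCR–pMHC complex is parsed from PDB text (Biopython). Chain roles (α, β,
peptide, MHC) and IMGT residue numbering are supplied by a YAML *sidecar*
rather than inferred, keeping numbering decisions external, explicit and
auditable. Alternate locations resolve to the highest-occupancy conformer
(ties: first in file); hydrogens are dropped.

**CDR grid.** Fingerprints are indexed by a fixed grid of IMGT positions per
chain: CDR1 27–38 (12 slots), CDR2 56–65 (10), CDR3 105–117 (13) — 35 per
chain, 70 in total, α before β. A `contiguous` variant (IMGT 27–117, 182
slots) is available. Loops shorter than their range are IMGT-gapped from both
ends inward (ends filled first, gap in the middle), the standard convention
for variable-length CDR loops.

**Peptide frame.** Peptides of length L ∈ [8, 20] are centred in a 20-slot
frame: residue k (1-based) maps to slot `10 − ⌊(L−1)/2⌋ + (k−1)`. Odd
lengths put the middle residue at slot 10; even lengths put the middle pair
at 10–11. This aligns peptides of different lengths about their bulged
centre, where TCR contacts concentrate.

## 2. Pairwise energy model

Energies are a simplified, self-contained decomposition (four channels),
evaluated between every CDR-grid residue and every peptide residue by summing
over atom pairs. Parameters live in `src/tcrkernel/data/energy_params.yaml`
and are element-based (C/N/O/S plus a default).

For an atom pair at distance r with LJ radii R_i, R_j (r_m = R_i + R_j) and
well depths ε_i, ε_j (ε = √(ε_i ε_j)):

- **atr / rep** — Lennard-Jones 12-6, `ε[(r_m/r)^12 − 2(r_m/r)^6]`, split at
  the minimum: outside r_m the whole LJ value is attractive; inside, the
  attractive part saturates at −ε and the remainder (LJ + ε ≥ 0) is
  repulsive. This keeps atr ≤ 0 and rep ≥ 0 everywhere and both continuous.
- **elec** — Coulomb with a distance-dependent dielectric,
  `332·q_i·q_j / (10·max(r, 1.6)·r)`, with partial charges on backbone N/O/C
  and charged/polar side-chain atoms (Asp/Glu carboxylates, Lys NZ, Arg NH,
  His ring nitrogens). The 1.6 Å floor avoids the singularity for clashing
  inputs.
- **sol** — Gaussian-exclusion implicit solvation (EEF1-like):
  `f_i(r)·V_j + f_j(r)·V_i` with
  `f_i(r) = ΔG_i / (2π^{3/2} λ_i r²) · exp(−((r − R_i)/λ_i)²)`; burying a
  polar atom (ΔG > 0) is penalised, burying an apolar one is rewarded.

All terms are multiplied by a linear switch S(r): 1 below 5.5 Å, 0 above
6.0 Å, so every channel goes smoothly and exactly to zero at the cutoff.
Unknown elements fall back to default parameters with a logged warning
rather than failing. The MHC chain is stripped before fingerprinting: the
classifier sees only the TCR–peptide interface.

## 3. Features

- **Distance fingerprint** — closest heavy-atom distance per grid × frame
  cell (70 × 20); cells whose residue is absent are missing (NaN).
- **Energy fingerprints** — one 70 × 20 matrix per channel (atr, rep, elec,
  sol).
- **Atchley encoding** — each of the 70 grid slots and 20 frame slots is
  encoded by the five Atchley factors of its residue (450 values; empty
  slots missing).

Matrices are flattened peptide-position-major (all 70 grid slots at frame
slot 1, then frame slot 2, …) into a table with two-level columns
(feature set, descriptor).

**Preprocessing** (fit on training rows only, frozen for prediction):
median imputation of missing values (features missing on every training row
impute to 0.5, with a warning), min-max scaling to [0, 1] with clipping for
out-of-range test values (constant features map to 0), then optional L2
normalisation of each row within each feature set.

## 4. Dataset construction rules

- **Shuffled negatives** — each positive TCR is re-paired, without
  replacement and deduplicated, with non-cognate pMHCs from the positives'
  own pool (default ratio 1:1).
- **All-vs-all panels** — full TCR × pMHC cross products with labels from a
  binding map; by default every TCR must have a cognate pMHC in the panel
  (`require_cognate=False` admits binding-dead controls).
- **Single-cell tetramer calls** — UMI counts are summed over a clone's
  barcodes; a (clone, tetramer) pair is a binder iff the summed count is
  strictly > 10 and strictly > 5× the clone's highest summed negative-control
  count.
- **Affinity calls** — binder iff K_D < 200 μM; undetermined K_D rows are
  dropped.
- **Homology category** — a modelled complex has "good" template coverage
  iff pMHC similarity > 45% **and** whole-complex similarity > 60% (strict).
- **BLOSUM similarity** — best BLOSUM62 global alignment score (gap open
  −10, extend −1) of a query pair's CDR3α/CDR3β/peptide against a training
  set, for leakage audits.

## 5. Kernel bank and EasyMKL

For each feature set, all Euclidean distances between positive and negative
training rows are collected and σ is read off at the 1st, 2nd, 5th, 50th,
95th, 98th and 99th percentiles (linear interpolation); each σ gives an RBF
kernel `exp(−γ‖x−x′‖²)` with γ = 1/(2σ²) (σ = 0 from duplicate rows caps γ
at 10⁶). Seven kernels per feature set.

EasyMKL (λ = 0) weights the bank by solving

> minimise γᵀ Ŷ K̄ Ŷ γ over the bi-simplex (γ ≥ 0, each class sums to 1)

where K̄ is the unweighted mean Gram and Ŷ = diag(y) — the nearest-points
problem between the two class convex hulls in the mean-kernel feature space.
No off-the-shelf QP solver is assumed: the problem is solved by FISTA-style
accelerated projected gradient with an exact O(n log n) Euclidean projection
onto each class simplex, step size 1/L from the largest eigenvalue of the
Hessian. The solution is verified in the test suite against an independent
SLSQP solve, 1000 random feasible points, and an exhaustive grid over convex
kernel combinations. Kernel weights are the per-kernel quadratic forms at the
optimum, `η_r ∝ γ*ᵀ Ŷ K_r Ŷ γ*`, normalised to sum to 1 (nonnegative for PSD
Grams).

A precomputed-kernel SVC is trained on `K* = Σ η_r K_r`; C is chosen from the
decade grid 10⁻⁵…10² by internal stratified cross-validation (10 folds,
reduced with a warning when the minority class is smaller), maximising mean
fold ROC AUC with ties broken toward the smaller (more regularised) C.

## 6. Evaluation

Generalisation is estimated by repeated stratified Monte-Carlo holdout
(default 10 repeats, 70/30): preprocessing, the γ heuristic, the kernel bank,
EasyMKL and the C search are all refit inside each training split; ROC AUC is
measured on the held-out rows, and a mean ROC curve is interpolated onto a
common 101-point false-positive-rate grid. `evaluate` adds average precision,
thresholded accuracy/precision/recall, and per-epitope ROC AUC restricted to
epitopes with ≥ 2 positives and ≥ 2 negatives.

## 7. Synthetic generator

The generator emits PDB text + sidecars for toy complexes with a binding
signal placed jointly in geometry and sequence. Peptides are extended chains
(Cα every 3.8 Å); residues carry backbone N/CA/C/O plus one pseudo side-chain
atom whose element tracks residue chemistry (S for Cys/Met, O for polar, C
for apolar), so all four energy channels see diversity. Binders' CDR3 loops
place `contact_motif_size` side-chain atoms ~4.3 Å above peptide residues and
carry the epitope's sequence motif; each motif residue is written into the
CDR3 with probability `binding_effect`. Non-binders are **independent decoy
TCRs** paired with a different epitope's peptide, displaced from the
interface by `8·binding_effect` Å and motif-shuffled with probability
`binding_effect`. At `binding_effect = 0` the two classes are exchangeable by
construction (holdout AUC ≈ 0.5, verified over multiple seeds); at 1 with no
noise they separate deterministically.

**Realism limits.** The chains are not physically plausible protein folds —
no folded framework, idealised backbone geometry, single pseudo side-chain
atoms, a decoy MHC slab. The geometric cue (uniform loop displacement) is
deliberately strong: AUC transitions sharply from ≈ 0.5 at effect 0 to ≈ 1
by effect ≈ 0.1, so the generator supports signal/null contrasts rather than
graded difficulty curves. A companion UMI-table generator produces
barcode-level tetramer counts with Poisson background and spiked true binders
(guaranteed to clear both calling thresholds, split across multi-barcode
clones) for testing the 10X calling rule.

## 8. Numerical and design choices

- All randomness flows through `numpy.random.default_rng(seed)`; fixed seeds
  give bit-identical cohorts (down to the PDB text) and models (verified on
  dual coefficients).
- Percentiles use NumPy's linear interpolation; distances use
  `scipy.spatial.distance.cdist`.
- The energy implementation is vectorised per residue pair but is tested to
  1e-9 relative tolerance against a plain double-loop oracle written
  independently of the implementation.
- Structures are frozen dataclasses; preprocessing state is immutable and
  carried by the model, making train/test leakage structurally impossible
  rather than merely avoided.

## 9. Limitations

- The energy model is a coarse stand-in for a full molecular-mechanics
  scoring function: element-level parameters, no torsions, no hydrogen
  bonding term, no side-chain repacking.
- IMGT numbering is consumed, not computed: the package does not run a
  numbering tool, it trusts the sidecar.
- The experimental 14 × 9 panel reconstruction reproduces the published
  combinatorics (126 pairs, 16 positives) with placeholder CDR sequences; it
  is a bookkeeping object, not a structural dataset.
- Performance numbers quoted anywhere in this repository are measured on
  synthetic cohorts; no claims are made about accuracy on curated
  experimental structure databases.
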