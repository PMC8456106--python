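# tcrkernel

Structure-derived classification of T cell receptor (TCR) – peptide-MHC
(pMHC) binding with multiple kernel learning.

T cells recognise antigens when the αβ TCR engages a short peptide presented
by an MHC molecule. Whether a given TCR binds a given pMHC is written into
the 3D interface: which complementarity-determining-region (CDR) residues sit
close to which peptide residues, and how favourable those contacts are.
`tcrkernel` turns a 3D TCR–pMHC complex into **pairwise fingerprints** —
matrices of one quantity (closest-atom distance, or an attractive/repulsive
van der Waals, electrostatic or solvation energy term) over CDR-position ×
peptide-position cells — and classifies binding with a support-vector machine
over a bank of Gaussian kernels whose weights are learned by EasyMKL.

## What the package provides

- **`tcrkernel.structures`** — PDB parsing (Biopython), IMGT numbering via
  YAML sidecars, a fixed 70-slot CDR grid (IMGT 27–38, 56–65, 105–117 on both
  chains), a 20-position peptide frame that centres any 8–20-mer (odd middle
  residue at position 10, even middle pair at 10–11), MHC stripping and PDB
  writing.
- **`tcrkernel.energetics`** — a simplified pairwise residue–residue energy
  decomposition: Lennard-Jones 12-6 split into attractive/repulsive parts at
  the minimum, distance-dependent-dielectric Coulomb electrostatics, and a
  Gaussian-exclusion implicit-solvation term, all smoothly switched off
  between 5.5 and 6 Å.
- **`tcrkernel.features`** — distance and per-term energy fingerprints,
  Atchley-factor sequence encoding, flattening into feature tables, and
  leakage-free preprocessing (train-median imputation, min-max scaling,
  optional per-feature-set row L2 normalisation).
- **`tcrkernel.datasets`** — pair bookkeeping: shuffled (non-cognate)
  negatives, all-vs-all TCR × pMHC panels, single-cell tetramer UMI binder
  calling (summed UMI > 10 and > 5× the best negative control), affinity
  calling (binder iff K_D < 200 μM), template-homology categories and BLOSUM
  similarity of a query pair to a training set.
- **`tcrkernel.mkl`** — per-feature-set banks of 7 Gaussian kernels with
  widths σ read off at the {1, 2, 5, 50, 95, 98, 99} percentiles of the
  positive–negative distance distribution (γ = 1/(2σ²)), EasyMKL kernel
  weighting, SVC with internal cross-validated C selection, repeated
  stratified 70/30 holdout and per-epitope evaluation.
- **`tcrkernel.synthetic`** — a self-contained generator of toy complexes
  with a tunable binding signal (`binding_effect` from 0 = null to 1 =
  deterministic separation), used throughout the tests.

## Worked example

Simulate a cohort, extract features, cross-validate, and inspect the learned
kernel weights (all numbers below are the actual output for these seeds):

```python
import numpy as np
from tcrkernel import SimulationConfig, generate_complexes, assemble
from tcrkernel.mkl import repeated_holdout, train_model, predict, evaluate

cfg = SimulationConfig(seed=42, n_epitopes=4, tcrs_per_epitope=15)
cohort = generate_complexes(cfg)
print(len(cohort), sum(sc.record.label == 1 for sc in cohort))
# 120 60            (60 binders + 60 decoy non-binders)

table = assemble(
    [sc.load() for sc in cohort],
    ("dist", "atr", "atchley"),
    labels={sc.complex_id: sc.record.label for sc in cohort},
)
print(table.data.shape)
# (120, 3250)       (2 × 1400 fingerprint cells + 450 Atchley values)

y = table.labels.to_numpy()
res = repeated_holdout(table, y, ["distances", "atr", "atchley"],
                       n_repeats=10, seed=0)
print(round(res.mean_auc, 3), round(res.sd_auc, 3))
# 1.0 0.0           (default effect 0.9 is strongly separable)

model = train_model(table, y, ["distances", "atr", "atchley"], seed=0)
per_set = {}
for w, (fset, _, _) in zip(model.eta, model.kernel_meta):
    per_set[fset] = per_set.get(fset, 0.0) + float(w)
print({k: round(v, 3) for k, v in per_set.items()})
# {'distances': 0.609, 'atr': 0.36, 'atchley': 0.031}

scores = predict(model, table)
m = evaluate(scores, y, epitopes=[sc.record.peptide for sc in cohort])
print(round(m["roc_auc"], 3), {k: round(v, 3) for k, v in m["per_epitope_auc"].items()})
# 1.0 {'CSQKKVCQF': 1.0, 'VCVTGPESR': 1.0, 'EILLAMERQ': 1.0, 'DTLMIEWSP': 1.0}
```

Turning the signal off gives chance performance — with `binding_effect=0.0`
(and `noise_sd=0.5`) the same pipeline yields mean holdout AUC **0.468 ±
0.065** on seed 42.

The same pipeline is scriptable from the command line:

```bash
tcrkernel simulate --seed 42 --out scratch/cohort
tcrkernel extract scratch/cohort/manifest.tsv --out scratch/table.tsv  # id,pdb,sidecar,label
tcrkernel cv scratch/table.tsv --feature-sets distances,atchley
```

## Reproduction

```bash
pip install --no-build-isolation -e ".[test]"
python -m pytest -q tests/                       # full suite, ~30 s
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the headline quantities at runtime: the
14-TCR × 9-pMHC experimental panel (126 pairs, 12.70% positive), the
1-binder/9-non-binder all-vs-all construction, the 7-kernel bank with
γ = 1/(2σ²) (γ = 0.125 at σ = 2), peptide-frame centering, and holdout AUCs
for strong-signal (1.0), label-permuted (≈ 0.5) and null-generator (≈ 0.5)
synthetic cohorts. See `docs/methods.md` for the methods note.
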