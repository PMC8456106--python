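"""Labelled binder / non-binder pair construction and stratification covariates.

The training pool pairs each TCR with its cognate peptide-MHC (a binder) and
with decoy pMHCs drawn from the remaining pool (non-binders); validation sets
come either from exhaustive all-vs-all pairing, from single-cell tetramer UMI
counts, or from measured dissociation constants.  Covariates used to stratify
performance — homology-template similarity categories and BLOSUM similarity
to the training set — are computed here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairRecord",
    "shuffle_negatives",
    "all_vs_all",
    "call_10x_binders",
    "call_affinity_binders",
    "homology_category",
    "blosum_to_train",
    "experimental_constructs",
    "UMI_MIN_COUNT",
    "UMI_CONTROL_FOLD",
    "KD_BINDER_THRESHOLD_UM",
]

#: Tetramer-binding call rule: summed UMI must exceed this count ...
UMI_MIN_COUNT = 10
#: ... and exceed this multiple of the clone's highest negative control.
UMI_CONTROL_FOLD = 5
#: Affinity call rule: K_D below this (μM) is a binder, at/above a non-binder.
KD_BINDER_THRESHOLD_UM = 200.0

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PairRecord:
    """One TCR-pMHC pair with its binding label and optional covariates."""

    tcr_id: str
    peptide: str
    mhc_allele: str = ""
    cdrs: Mapping[str, str] = field(default_factory=dict)  # cdr1a..cdr3b
    label: int = 0  # +1 binder, -1 non-binder, 0 unlabelled
    provenance: str = ""
    kd_um: float | None = None
    umi: int | None = None
    template_pmhc_pct: float | None = None
    template_complex_pct: float | None = None
    template_tcr_pct: float | None = None

    def __post_init__(self) -> None:
        pep = self.peptide
        if pep and (pep != pep.upper() or not set(pep) <= _STANDARD_AA):
            raise ValueError(f"peptide {pep!r} is not uppercase standard amino acids")

    @property
    def pmhc(self) -> tuple[str, str]:
        return (self.peptide, self.mhc_allele)


def shuffle_negatives(
    positives: Sequence[PairRecord], ratio: int = 1, seed: int | None = None
) -> list[PairRecord]:
    """Create decoy non-binders by re-pairing each TCR with non-cognate pMHCs.

    For every positive, ``ratio`` negatives are drawn uniformly (without
    replacement per TCR) from the pool of pMHCs in ``positives``, excluding
    every pMHC that TCR is known to bind.  Output records carry label -1.
    """
    rng = np.random.default_rng(seed)
    pool = sorted({p.pmhc for p in positives})
    if len(pool) < 2:
        raise ValueError("cannot shuffle negatives from a single-pMHC pool")
    cognate: dict[str, set] = {}
    for p in positives:
        cognate.setdefault(p.tcr_id, set()).add(p.pmhc)
    taken: dict[str, set] = {t: set() for t in cognate}
    negatives: list[PairRecord] = []
    for pos in positives:
        choices = [
            pm for pm in pool
            if pm not in cognate[pos.tcr_id] and pm not in taken[pos.tcr_id]
        ]
        if len(choices) < ratio:
            raise ValueError(
                f"pool too small to draw {ratio} distinct decoys for TCR {pos.tcr_id}"
            )
        picks = rng.choice(len(choices), size=ratio, replace=False)
        for idx in sorted(int(i) for i in picks):
            pep, mhc = choices[idx]
            taken[pos.tcr_id].add((pep, mhc))
            negatives.append(
                PairRecord(
                    tcr_id=pos.tcr_id,
                    peptide=pep,
                    mhc_allele=mhc,
                    cdrs=pos.cdrs,
                    label=-1,
                    provenance="shuffled",
                )
            )
    return negatives


def all_vs_all(
    tcrs: Sequence[Mapping | PairRecord],
    pmhcs: Sequence[tuple[str, str]],
    binding_map: Mapping[str, Iterable[tuple[str, str]]],
    require_cognate: bool = True,
) -> list[PairRecord]:
    """Pair every TCR with every pMHC; label binder iff the pair is cognate.

    With one cognate pMHC per TCR and ten pMHCs in the pool, this yields one
    binding and nine non-binding records per TCR.  ``require_cognate=False``
    admits TCRs with no cognate pMHC (e.g. binding-dead mutant constructs),
    which then contribute only non-binding records.
    """
    records: list[PairRecord] = []
    for tcr in tcrs:
        if isinstance(tcr, PairRecord):
            tcr_id, cdrs = tcr.tcr_id, tcr.cdrs
        else:
            tcr_id, cdrs = tcr["tcr_id"], tcr.get("cdrs", {})
        cognate = {tuple(pm) for pm in binding_map.get(tcr_id, ())}
        if not cognate and require_cognate:
            raise ValueError(f"TCR {tcr_id} has no cognate pMHC in the binding map")
        for pep, mhc in pmhcs:
            records.append(
                PairRecord(
                    tcr_id=tcr_id,
                    peptide=pep,
                    mhc_allele=mhc,
                    cdrs=cdrs,
                    label=1 if (pep, mhc) in cognate else -1,
                    provenance="all_vs_all",
                )
            )
    return records


def call_10x_binders(
    umi: pd.DataFrame,
    controls: pd.DataFrame,
    barcode_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Call tetramer-specific binding events from single-cell UMI counts.

    ``umi`` and ``controls`` are barcode × tetramer / barcode × negative-
    control count tables.  Counts of a clone's barcodes are summed; a
    tetramer is called bound iff the summed UMI exceeds ``UMI_MIN_COUNT``
    and ``UMI_CONTROL_FOLD`` × the clone's highest summed negative control.
    A clone may be called a binder for several tetramers.
    """
    if (controls.to_numpy() < 0).any() or (umi.to_numpy() < 0).any():
        raise ValueError("UMI and control counts must be nonnegative")
    calls = {}
    for clone, barcodes in barcode_map.items():
        missing = [b for b in barcodes if b not in umi.index]
        if missing or not list(barcodes):
            raise KeyError(f"clone {clone!r} has barcodes absent from the UMI table: {missing}")
        total = umi.loc[list(barcodes)].sum(axis=0)
        ctrl = controls.loc[[b for b in barcodes if b in controls.index]].sum(axis=0)
        max_ctrl = float(ctrl.max()) if len(ctrl) else 0.0
        calls[clone] = (total > UMI_MIN_COUNT) & (total > UMI_CONTROL_FOLD * max_ctrl)
    return pd.DataFrame(calls).T


def call_affinity_binders(records: pd.DataFrame, kd_column: str = "kd_uM") -> pd.Series:
    """Label by dissociation constant: binder iff K_D < 200 μM.

    Rows whose K_D is not determined (``n.d.``/NaN) are dropped — their
    binding status cannot be established.  Returns +1/-1 indexed like the
    surviving rows.
    """
    if len(records) == 0:
        return pd.Series(dtype=int)
    raw = records[kd_column].astype(object)
    kd = pd.to_numeric(raw.where(~raw.isin(["n.d.", "nd", "N.D."])), errors="coerce")
    kept = kd.dropna()
    if (kept < 0).any():
        raise ValueError("negative K_D values in affinity table")
    return pd.Series(
        np.where(kept < KD_BINDER_THRESHOLD_UM, 1, -1), index=kept.index, dtype=int
    )


def homology_category(pmhc_similarity: float, complex_similarity: float) -> str:
    """Template-availability category for a modelled complex.

    ``good`` iff the best pMHC template exceeds 45% sequence similarity AND
    the best whole-complex template exceeds 60% (both strict); otherwise
    ``poor``.
    """
    for name, v in (("pmhc", pmhc_similarity), ("complex", complex_similarity)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} similarity {v} outside [0, 100] %")
    return "good" if (pmhc_similarity > 45.0 and complex_similarity > 60.0) else "poor"


def _aligner(matrix_name: str, gap_open: float, gap_extend: float):
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def blosum_to_train(
    record: PairRecord,
    train_records: Sequence[PairRecord],
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    chains: Sequence[str] = ("cdr3a", "cdr3b", "peptide"),
) -> dict[str, float]:
    """Similarity of one pair to the nearest training example, per chain.

    Global alignment score (BLOSUM62, affine gaps −10/−1 by default) against
    every training record; the maximum is returned for each chain.  A record
    identical to a training example attains its self-alignment score.
    """
    if not train_records:
        raise ValueError("empty training set")
    aligner = _aligner(matrix, gap_open, gap_extend)

    def seq_of(rec: PairRecord, chain: str) -> str:
        s = rec.peptide if chain == "peptide" else rec.cdrs.get(chain, "")
        if not s:
            raise ValueError(f"record {rec.tcr_id} lacks a {chain} sequence")
        return s

    out = {}
    for chain in chains:
        query = seq_of(record, chain)
        out[chain] = max(aligner.score(query, seq_of(t, chain)) for t in train_records)
    return out


def experimental_constructs() -> tuple[list[dict], list[tuple[str, str]], dict]:
    """The functionally characterised TCR construct panel and its pMHC pool.

    Fourteen TCRs (2 CMV-reactive, 2 HA1- and 1 HA2-reactive influenza, 1
    EBV-reactive, the A7 TCR plus its three affinity-matured variants which
    recognise both the Tax and HuD peptides, and 2 neoantigen-reactive TCRs
    with 2 non-binding mutants) crossed with a nine-peptide HLA-A2/B35 pool
    that includes two wild-type control peptides.  Returns
    ``(tcrs, pmhcs, binding_map)`` ready for :func:`all_vs_all`: 126 pairs,
    16 of them binders (12.70%).

    CDR sequences and the neoantigen peptide are synthetic placeholders (the
    panel's published description names only the epitope peptides); only the
    pairing combinatorics are meaningful.
    """
    peptides = {
        "CMV": ("NLVPMVATV", "A02"),
        "HA1": ("VLHDDLLEA", "A02"),
        "HA2": ("YIGEVLVSV", "A02"),
        "EBV": ("CLGGLLTMV", "A02"),
        "Tax": ("LLFGYPVYV", "A02"),
        "HuD": ("LGYGFVNYI", "A02"),
        "Neo": ("FAFQEDDSY", "A02"),  # synthetic stand-in for the unpublished neoantigen
        "WT235": ("CMTWNQMNL", "B35"),
        "WTlung": ("FAFQEDDSF", "A02"),
    }
    specificities = {
        "CMV-1": ["CMV"],
        "CMV-2": ["CMV"],
        "HA1-1": ["HA1"],
        "HA1-2": ["HA1"],
        "HA2-1": ["HA2"],
        "EBV-1": ["EBV"],
        "A7": ["Tax", "HuD"],
        "A7m-1": ["Tax", "HuD"],
        "A7m-2": ["Tax", "HuD"],
        "A7m-3": ["Tax", "HuD"],
        "Neo-1": ["Neo"],
        "Neo-2": ["Neo"],
        "Neo-1mut": [],
        "Neo-2mut": [],
    }
    pmhcs = [peptides[k] for k in peptides]
    tcrs = [{"tcr_id": t, "cdrs": {}} for t in specificities]
    binding_map = {
        t: {peptides[e] for e in eps} for t, eps in specificities.items()
    }
    return tcrs, pmhcs, binding_map
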