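"""Per-complex fingerprints, Atchley sequence encodings and feature tables.

Every structural channel (minimum pairwise distances and the four energy
terms) is a matrix over the fixed (chain, IMGT position) CDR grid × the
20-position peptide frame; the Atchley channel places the five published
physicochemical factors of each residue on the same grid.  Fingerprints are
flattened into fixed-width rows — peptide position major, grid position
minor, i.e. (27-1, 28-1, …, 117-1, 27-2, …) — and assembled into a
``FeatureTable`` which also owns the train-fitted preprocessing state
(median imputation, min-max scaling, per-feature-set row normalisation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import TcrPmhcComplex, cdr_grid_positions

__all__ = [
    "ATCHLEY_FACTORS",
    "Fingerprint",
    "FeatureTable",
    "PreprocessState",
    "CHANNELS",
    "distance_fingerprint",
    "atchley_encode",
    "imgt_place",
    "contact_frequency",
    "assemble",
    "fit_preprocess",
    "apply_preprocess",
    "unflatten",
]

#: Channel → feature-set name used in column descriptors.
CHANNELS = {
    "dist": "distances",
    "atr": "atr",
    "rep": "rep",
    "elec": "elec",
    "sol": "sol",
    "atchley": "atchley",
}

#: Five physicochemical factor scores per amino acid (Atchley et al. 2005):
#: I polarity/hydrophobicity, II secondary-structure propensity, III size,
#: IV codon composition, V electrostatic charge.
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}


@dataclass(frozen=True)
class Fingerprint:
    """One feature channel over the CDR grid × peptide frame; NaN = missing."""

    channel: str
    values: np.ndarray  # shape (len(grid), 20)
    grid: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.grid), 20):
            raise ValueError(
                f"fingerprint shape {self.values.shape} does not match grid "
                f"({len(self.grid)} × 20)"
            )


def distance_fingerprint(
    complex_: TcrPmhcComplex, grid_variant: str = "cdr"
) -> Fingerprint:
    """Minimum heavy-atom distance (Å) per CDR-residue × peptide-residue pair."""
    grid = cdr_grid_positions(grid_variant)
    values = np.full((len(grid), 20), np.nan)
    pep = [
        (r.pep_frame_position, np.array([a.xyz for a in r.atoms]))
        for r in complex_.peptide.residues
        if r.pep_frame_position is not None
    ]
    coords: dict[tuple[str, int], np.ndarray] = {}
    for role in ("alpha", "beta"):
        for r in complex_.chains[role].residues:
            if r.imgt_position is not None:
                coords[(role, r.imgt_position)] = np.array([a.xyz for a in r.atoms])
    for gi, key in enumerate(grid):
        xyz_a = coords.get(key)
        if xyz_a is None:
            continue
        for pos, xyz_b in pep:
            values[gi, pos - 1] = cdist(xyz_a, xyz_b).min()
    return Fingerprint(channel="dist", values=values, grid=grid)


def imgt_place(sequence: str, lo: int, hi: int) -> dict[int, str]:
    """Place a CDR sequence on IMGT positions ``lo..hi``.

    Follows the IMGT gapping convention for loops shorter than the range:
    residues fill from both ends toward the middle, leaving the gap at the
    centre of the range.
    """
    span = hi - lo + 1
    n = len(sequence)
    if n > span:
        raise ValueError(f"sequence of length {n} does not fit IMGT range {lo}-{hi}")
    n_front = (n + 1) // 2
    placed = {lo + i: sequence[i] for i in range(n_front)}
    for j in range(n - n_front):
        placed[hi - j] = sequence[n - 1 - j]
    return placed


def _sequence_slots(source, grid) -> dict:
    """Residue one-letter codes per grid slot and peptide frame position."""
    from .structures import CDR_RANGES

    slots: dict = {}
    if isinstance(source, TcrPmhcComplex):
        for role in ("alpha", "beta"):
            for r in source.chains[role].residues:
                if r.imgt_position is not None:
                    slots[(role, r.imgt_position)] = r.aa
        for r in source.peptide.residues:
            if r.pep_frame_position is not None:
                slots[("peptide", r.pep_frame_position)] = r.aa
    else:
        # sequence record: mapping with cdr1/2/3 per chain + peptide
        from .datasets import PairRecord
        from .structures import renumber_peptide

        if isinstance(source, PairRecord):
            cdrs, peptide = source.cdrs, source.peptide
        else:
            cdrs, peptide = dict(source.get("cdrs", source)), source["peptide"]
        for role, suffix in (("alpha", "a"), ("beta", "b")):
            for (lo, hi), idx in zip(CDR_RANGES, (1, 2, 3)):
                seq = cdrs.get(f"cdr{idx}{suffix}")
                if seq:
                    for pos, aa in imgt_place(seq, lo, hi).items():
                        slots[(role, pos)] = aa
        L = len(peptide)
        start = 10 - (L - 1) // 2
        for k, aa in enumerate(peptide):
            slots[("peptide", start + k)] = aa
    return slots


def atchley_encode(source, grid_variant: str = "cdr") -> np.ndarray:
    """Atchley-factor encoding over the CDR grid plus the 20-peptide frame.

    ``source`` may be a :class:`TcrPmhcComplex` (residues read off the
    structure) or a sequence record (CDR sequences placed by the IMGT
    gapping convention).  Output length is ``(len(grid) + 20) * 5`` with NaN
    at unoccupied slots; grid slots come first, each contributing its five
    factors consecutively.
    """
    grid = cdr_grid_positions(grid_variant)
    slots = _sequence_slots(source, grid)
    keys = list(grid) + [("peptide", p) for p in range(1, 21)]
    out = np.full(len(keys) * 5, np.nan)
    for i, key in enumerate(keys):
        aa = slots.get(key)
        if aa is None:
            continue
        if aa not in ATCHLEY_FACTORS:
            raise ValueError(f"non-standard residue code {aa!r} at position {key}")
        out[i * 5 : i * 5 + 5] = ATCHLEY_FACTORS[aa]
    return out


def contact_frequency(
    complexes: Iterable[TcrPmhcComplex],
    cutoff: float = 6.0,
    grid_variant: str = "cdr",
    class_labels: Sequence[str] | None = None,
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Count, per grid cell, how many complexes make a contact below ``cutoff``.

    With ``class_labels`` (e.g. MHC class per complex) a separate count
    matrix is returned per label.
    """
    complexes = list(complexes)
    if not complexes:
        raise ValueError("contact_frequency requires at least one complex")
    grid = cdr_grid_positions(grid_variant)
    index = pd.MultiIndex.from_tuples(grid, names=["chain", "imgt"])
    cols = pd.RangeIndex(1, 21, name="pep")

    def count(group: list[TcrPmhcComplex]) -> pd.DataFrame:
        total = np.zeros((len(grid), 20), dtype=int)
        for cx in group:
            fp = distance_fingerprint(cx, grid_variant)
            with np.errstate(invalid="ignore"):
                total += np.where(np.isnan(fp.values), False, fp.values < cutoff)
        return pd.DataFrame(total, index=index, columns=cols)

    if class_labels is None:
        return count(complexes)
    groups: dict[str, list[TcrPmhcComplex]] = {}
    for cx, lab in zip(complexes, class_labels):
        groups.setdefault(lab, []).append(cx)
    return {lab: count(group) for lab, group in groups.items()}


@dataclass(frozen=True)
class PreprocessState:
    """Frozen train-set statistics: per-column median/min/max + row-norm mode."""

    medians: pd.Series
    mins: pd.Series
    maxs: pd.Series
    row_norm: str = "l2"  # {"l2", "none"}, applied within each feature set


@dataclass
class FeatureTable:
    """Samples × flattened features with feature-set column descriptors.

    ``data`` has a two-level column index ``(feature_set, descriptor)`` where
    the descriptor encodes the grid cell (``alpha:27|pep:1``) or Atchley slot
    (``alpha:27|f1``).  ``labels`` take values +1/-1 (0 = unlabelled).
    """

    data: pd.DataFrame
    labels: pd.Series | None = None
    preprocess: PreprocessState | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_sets(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    def columns_of(self, feature_set: str) -> pd.DataFrame:
        return self.data[feature_set]

    def subset(self, sample_ids) -> "FeatureTable":
        labels = self.labels.loc[sample_ids] if self.labels is not None else None
        return FeatureTable(self.data.loc[sample_ids], labels, self.preprocess)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        if self.labels is not None:
            out.insert(0, ("_meta", "label"), self.labels)
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        data = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
        labels = None
        if ("_meta", "label") in data.columns:
            labels = data[("_meta", "label")].astype(int)
            data = data.drop(columns=[("_meta", "label")])
        return cls(data, labels)


def _flatten_grid(values: np.ndarray) -> np.ndarray:
    # peptide-position major, grid minor: (27-1, 28-1, ..., 117-1, 27-2, ...)
    return np.ravel(values, order="F")


def _grid_descriptors(grid) -> list[str]:
    return [f"{role}:{imgt}|pep:{p}" for p in range(1, 21) for role, imgt in grid]


def _atchley_descriptors(grid) -> list[str]:
    keys = list(grid) + [("peptide", p) for p in range(1, 21)]
    return [f"{role}:{pos}|f{k}" for role, pos in keys for k in range(1, 6)]


def assemble(
    complexes: Sequence[TcrPmhcComplex],
    channels: Sequence[str] = ("dist", "atchley"),
    labels: Mapping[str, int] | None = None,
    params=None,
    grid_variant: str = "cdr",
) -> FeatureTable:
    """Extract the requested channels from each complex into one table.

    ``channels`` draw from dist/atr/rep/elec/sol/atchley; energy channels are
    computed once per complex through the energetics backend.
    """
    from .energetics import energy_fingerprints

    grid = cdr_grid_positions(grid_variant)
    need_energy = any(c in ("atr", "rep", "elec", "sol") for c in channels)
    ids = [cx.complex_id for cx in complexes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate complex ids in assemble()")

    blocks: dict[str, list[np.ndarray]] = {c: [] for c in channels}
    for cx in complexes:
        energies = energy_fingerprints(cx, params, grid_variant) if need_energy else None
        for ch in channels:
            if ch == "dist":
                blocks[ch].append(_flatten_grid(distance_fingerprint(cx, grid_variant).values))
            elif ch == "atchley":
                blocks[ch].append(atchley_encode(cx, grid_variant))
            else:
                blocks[ch].append(_flatten_grid(energies.channel(ch)))

    frames = []
    for ch in channels:
        fset = CHANNELS[ch]
        desc = _atchley_descriptors(grid) if ch == "atchley" else _grid_descriptors(grid)
        cols = pd.MultiIndex.from_product([[fset], desc])
        frames.append(pd.DataFrame(np.vstack(blocks[ch]), index=ids, columns=cols))
    data = pd.concat(frames, axis=1)
    lab = None
    if labels is not None:
        lab = pd.Series({i: labels.get(i, 0) for i in ids}, name="label")
    return FeatureTable(data, lab)


def unflatten(table: FeatureTable, sample_id, channel: str, grid_variant: str = "cdr") -> np.ndarray:
    """Reconstruct the (grid × 20) fingerprint matrix of one sample/channel."""
    grid = cdr_grid_positions(grid_variant)
    row = table.data.loc[sample_id, CHANNELS[channel]].to_numpy(dtype=float)
    return row.reshape((20, len(grid))).T  # inverse of order="F" flattening


def fit_preprocess(train: FeatureTable, row_norm: str = "l2") -> PreprocessState:
    """Fit imputation/scaling statistics on the training rows only."""
    X = train.data
    medians = X.median(axis=0, skipna=True)
    all_missing = medians.isna()
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} features missing on every training row; "
            "imputing 0.5 after scaling",
            stacklevel=2,
        )
    mins = X.min(axis=0, skipna=True)
    maxs = X.max(axis=0, skipna=True)
    return PreprocessState(medians=medians, mins=mins, maxs=maxs, row_norm=row_norm)


def apply_preprocess(state: PreprocessState, table: FeatureTable) -> FeatureTable:
    """Impute → min-max scale (clipped to [0,1]) → row-normalise per feature set."""
    cols = table.data.columns
    X = table.data.to_numpy(dtype=float)
    med = state.medians.reindex(cols).to_numpy(dtype=float)
    lo = state.mins.reindex(cols).to_numpy(dtype=float)
    hi = state.maxs.reindex(cols).to_numpy(dtype=float)

    no_stats = np.isnan(med)  # all-missing on train: impute 0.5, no scaling
    missing = np.isnan(X)
    X = np.where(missing, np.broadcast_to(med, X.shape), X)
    X[:, no_stats] = np.where(missing[:, no_stats], 0.5, X[:, no_stats])

    span = hi - lo
    safe_span = np.where((span == 0) | np.isnan(span), 1.0, span)
    scaled = (X - np.where(np.isnan(lo), 0.0, lo)) / safe_span
    scaled[:, (span == 0)] = 0.0  # degenerate constant train features
    scaled[:, no_stats] = X[:, no_stats]
    scaled = np.clip(scaled, 0.0, 1.0)

    if state.row_norm == "l2":
        level0 = np.asarray(cols.get_level_values(0))
        for fset in dict.fromkeys(level0):
            idx = level0 == fset
            norms = np.linalg.norm(scaled[:, idx], axis=1, keepdims=True)
            norms[norms == 0.0] = 1.0
            scaled[:, idx] = scaled[:, idx] / norms
    elif state.row_norm != "none":
        raise ValueError(f"unknown row_norm {state.row_norm!r}")
    out = pd.DataFrame(scaled, index=table.data.index, columns=cols)
    return FeatureTable(out, table.labels, state)
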