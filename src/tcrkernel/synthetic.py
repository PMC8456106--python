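"""Self-contained synthetic fixtures: toy complexes with tunable binding signal.

The generator stands in for a curated structure database.  It emits PDB text
plus numbering sidecars for toy TCR-peptide-MHC complexes in which the
binding signal is placed jointly in geometry and sequence:

* each epitope gets a random peptide, built as an extended chain along the
  x-axis (Cα spacing 3.8 Å), and a sequence motif;
* a binder's CDR3 loops hover above the peptide with ``contact_motif_size``
  designed contacts (side-chain atoms 3.5-5 Å from peptide residues) and
  carry the epitope motif at the contact positions;
* a non-binder pairs a TCR with a different epitope's peptide, its loops
  displaced away from the interface by a distance proportional to
  ``binding_effect`` and its motif shuffled with probability
  ``binding_effect``.

At ``binding_effect = 0`` binders and non-binders are therefore drawn from
the same distribution (a null dataset); at 1 with no noise they separate
deterministically.  Residues are backbone (N, CA, C, O) plus one pseudo
side-chain atom whose element depends on residue class, so every energy
term sees chemical diversity.  The chains are not physically realistic
protein folds — they exist to exercise the pipeline end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import PairRecord
from .features import imgt_place
from .structures import (
    Atom,
    Chain,
    NumberingSidecar,
    Residue,
    TcrPmhcComplex,
    read_complex,
    renumber_peptide,
    sidecar_for,
    write_pdb,
)

__all__ = ["SimulationConfig", "SyntheticComplex", "generate_complexes", "generate_umi_table"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_POLAR = set("STNQYDEKRH")
_SULFUR = set("CM")

PEPTIDE_LENGTH = 9
CDR_LENGTHS = {"cdr1": 6, "cdr2": 5, "cdr3": 12}
CDR_IMGT_RANGES = {"cdr1": (27, 38), "cdr2": (56, 65), "cdr3": (105, 117)}

_CONTACT_Z = 4.3  # side-chain atom height above a contacted peptide residue
_LOOP_Z = 8.5  # non-contact CDR3 backbone height
_FRAME_Z = 11.0  # CDR1/2 height
_DISPLACEMENT = 8.0  # z-offset applied to non-binder loops, scaled by effect


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults give 4 epitopes × 15 TCRs with a strong but noisy binding
    signal (effect 0.9, coordinate noise 0.35 Å, four designed contacts)
    and one decoy non-binder per binder.
    """

    seed: int
    n_epitopes: int = 4
    tcrs_per_epitope: int = 15
    binding_effect: float = 0.9
    contact_motif_size: int = 4
    noise_sd: float = 0.35
    negative_ratio: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.binding_effect <= 1.0):
            raise ValueError("binding_effect must lie in [0, 1]")
        if min(self.n_epitopes, self.tcrs_per_epitope, self.negative_ratio) < 1:
            raise ValueError("counts must be positive")
        if self.contact_motif_size > CDR_LENGTHS["cdr3"]:
            raise ValueError("contact motif larger than the CDR3 loop")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_epitopes < 2 and self.negative_ratio >= 1:
            raise ValueError("need at least 2 epitopes to build non-binders")


@dataclass(frozen=True)
class SyntheticComplex:
    """One emitted structure: PDB text + sidecar + its labelled pair record."""

    complex_id: str
    pdb_text: str
    sidecar: NumberingSidecar
    record: PairRecord

    def load(self) -> TcrPmhcComplex:
        """Round-trip through the PDB reader and peptide renumbering."""
        cx = read_complex(self.pdb_text, self.sidecar, complex_id=self.complex_id)
        return renumber_peptide(cx)


def _side_chain(aa: str, ca: np.ndarray, direction: np.ndarray) -> Atom:
    if aa in _SULFUR:
        name, element = "SG", "S"
    elif aa in _POLAR:
        name, element = "OG", "O"
    else:
        name, element = "CB", "C"
    xyz = ca + 1.5 * direction
    return Atom(name=name, element=element, xyz=tuple(float(v) for v in xyz))


def _residue(
    number: int, aa: str, ca: np.ndarray, side_dir: np.ndarray, rng, noise_sd: float
) -> Residue:
    offsets = {
        "N": np.array([-1.2, 0.8, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.2, 0.8, 0.0]),
        "O": np.array([1.2, 2.0, 0.0]),
    }
    atoms = []
    for name, off in offsets.items():
        xyz = ca + off + rng.normal(0.0, noise_sd, 3)
        element = name[0]
        atoms.append(Atom(name=name, element=element, xyz=tuple(float(v) for v in xyz)))
    sc = _side_chain(aa, ca + rng.normal(0.0, noise_sd, 3), side_dir)
    atoms.append(sc)
    return Residue(author_number=number, icode=" ", aa=aa, atoms=tuple(atoms))


def _build_peptide(sequence: str, rng, noise_sd: float) -> Chain:
    residues = []
    for k, aa in enumerate(sequence):
        ca = np.array([3.8 * k, 0.0, 0.0])
        residues.append(_residue(k + 1, aa, ca, np.array([0.0, 0.0, -1.0]), rng, noise_sd))
    return Chain(chain_id="C", role="peptide", residues=tuple(residues))


def _build_tcr_chain(
    chain_id: str,
    role: str,
    cdr_seqs: dict[str, str],
    contact_plan: dict[int, float],
    z_shift: float,
    rng,
    noise_sd: float,
) -> Chain:
    """One TCR chain from its three CDR loops.

    ``contact_plan`` maps CDR3 residue index (within the loop) to the x
    coordinate of the contacted peptide Cα; other residues sit higher above
    the interface.  ``z_shift`` displaces the whole chain (non-binders).
    """
    residues = []
    author = 1
    x_anchor = min(contact_plan.values()) if contact_plan else 0.0
    for loop in ("cdr1", "cdr2", "cdr3"):
        seq = cdr_seqs[loop]
        lo, hi = CDR_IMGT_RANGES[loop]
        placement = sorted(imgt_place(seq, lo, hi).items())
        for j, (imgt_pos, aa) in enumerate(placement):
            if loop == "cdr3":
                if j in contact_plan:
                    ca = np.array([contact_plan[j], 0.0, _CONTACT_Z + 1.5 + z_shift])
                    side_dir = np.array([0.0, 0.0, -1.0])
                else:
                    ca = np.array([x_anchor + 1.6 * j, 2.5, _LOOP_Z + z_shift])
                    side_dir = np.array([0.0, 1.0, 0.0])
            else:
                y = 5.0 if loop == "cdr1" else -5.0
                ca = np.array([x_anchor + 1.6 * j, y, _FRAME_Z + z_shift])
                side_dir = np.array([0.0, 1.0 if y > 0 else -1.0, 0.0])
            res = _residue(author, aa, ca, side_dir, rng, noise_sd)
            res = Residue(
                author_number=res.author_number,
                icode=res.icode,
                aa=res.aa,
                atoms=res.atoms,
                imgt_position=imgt_pos,
            )
            residues.append(res)
            author += 1
    return Chain(chain_id=chain_id, role=role, residues=tuple(residues))


def _build_mhc(rng, noise_sd: float) -> Chain:
    # decoy groove floor, far beneath the interface
    residues = []
    for k in range(6):
        ca = np.array([3.8 * k, 0.0, -30.0])
        residues.append(_residue(k + 1, "G", ca, np.array([0.0, 0.0, -1.0]), rng, noise_sd))
    return Chain(chain_id="D", role="mhc", residues=tuple(residues))


def _random_seq(rng, n: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), n))


def _shuffled(rng, s: str) -> str:
    idx = rng.permutation(len(s))
    out = "".join(s[i] for i in idx)
    if out == s and len(set(s)) > 1:  # force a change when possible
        return s[1:] + s[0]
    return out


def _assemble_complex(
    complex_id: str,
    tcr: dict,
    peptide_seq: str,
    contact_pep_idx: dict[str, list[int]],
    z_shift: float,
    shuffle_motif: bool,
    rng,
    noise_sd: float,
    label: int,
) -> SyntheticComplex:
    cdrs = {k: v for k, v in tcr["cdrs"].items()}
    if shuffle_motif:
        for suffix in ("a", "b"):
            cdr3 = cdrs[f"cdr3{suffix}"]
            pos = tcr["motif_positions"][suffix]
            motif = "".join(cdr3[p] for p in pos)
            shuf = _shuffled(rng, motif)
            chars = list(cdr3)
            for p, c in zip(pos, shuf):
                chars[p] = c
            cdrs[f"cdr3{suffix}"] = "".join(chars)

    chains = {"peptide": _build_peptide(peptide_seq, rng, noise_sd)}
    for role, cid, suffix in (("alpha", "A", "a"), ("beta", "B", "b")):
        plan = {
            cdr3_idx: 3.8 * pep_idx
            for cdr3_idx, pep_idx in zip(
                tcr["motif_positions"][suffix], contact_pep_idx[suffix]
            )
        }
        chains[role] = _build_tcr_chain(
            cid,
            role,
            {loop: cdrs[f"{loop}{suffix}"] for loop in ("cdr1", "cdr2", "cdr3")},
            plan,
            z_shift,
            rng,
            noise_sd,
        )
    chains["mhc"] = _build_mhc(rng, noise_sd)
    cx = TcrPmhcComplex(complex_id=complex_id, chains=chains)
    record = PairRecord(
        tcr_id=tcr["tcr_id"],
        peptide=peptide_seq,
        mhc_allele="A02",
        cdrs={k: cdrs[k] for k in sorted(cdrs)},
        label=label,
        provenance="synthetic",
    )
    return SyntheticComplex(
        complex_id=complex_id,
        pdb_text=write_pdb(cx),
        sidecar=sidecar_for(cx),
        record=record,
    )


def generate_complexes(config: SimulationConfig) -> list[SyntheticComplex]:
    """Generate the labelled synthetic cohort defined by ``config``.

    Returns one :class:`SyntheticComplex` per pair: for every epitope,
    ``tcrs_per_epitope`` binders plus ``negative_ratio`` decoys per binder
    (the same TCR re-paired with another epitope's peptide, displaced and
    motif-shuffled according to ``binding_effect``).  Deterministic for a
    fixed seed, down to the PDB text.
    """
    rng = np.random.default_rng(config.seed)
    m = config.contact_motif_size
    cdr3_len = CDR_LENGTHS["cdr3"]
    # contact positions: central stretch of the CDR3; peptide indices split
    # between the two chains (alpha N-terminal half, beta C-terminal half)
    start = (cdr3_len - m) // 2
    motif_positions = {s: list(range(start, start + m)) for s in ("a", "b")}
    pep_idx = {
        "a": [(k % (PEPTIDE_LENGTH // 2)) for k in range(m)],
        "b": [PEPTIDE_LENGTH // 2 + (k % (PEPTIDE_LENGTH - PEPTIDE_LENGTH // 2)) for k in range(m)],
    }

    epitopes = []
    for e in range(config.n_epitopes):
        epitopes.append(
            {
                "peptide": _random_seq(rng, PEPTIDE_LENGTH),
                "motif": {s: _random_seq(rng, m) for s in ("a", "b")},
            }
        )

    def make_tcr(tcr_id: str, motif: dict[str, str]) -> dict:
        cdrs = {}
        for suffix in ("a", "b"):
            cdrs[f"cdr1{suffix}"] = _random_seq(rng, CDR_LENGTHS["cdr1"])
            cdrs[f"cdr2{suffix}"] = _random_seq(rng, CDR_LENGTHS["cdr2"])
            cdr3 = list(_random_seq(rng, cdr3_len))
            # sequence signal scales with effect: each motif residue is
            # written into the CDR3 with probability binding_effect
            for p, c in zip(motif_positions[suffix], motif[suffix]):
                if rng.random() < config.binding_effect:
                    cdr3[p] = c
            cdrs[f"cdr3{suffix}"] = "".join(cdr3)
        return {"tcr_id": tcr_id, "cdrs": cdrs, "motif_positions": motif_positions}

    out: list[SyntheticComplex] = []
    for e, ep in enumerate(epitopes):
        for t in range(config.tcrs_per_epitope):
            tcr = make_tcr(f"tcr-e{e}-{t}", ep["motif"])
            out.append(
                _assemble_complex(
                    f"e{e}t{t}-pos",
                    tcr,
                    ep["peptide"],
                    pep_idx,
                    z_shift=0.0,
                    shuffle_motif=False,
                    rng=rng,
                    noise_sd=config.noise_sd,
                    label=1,
                )
            )
            # decoys: independent TCRs carrying this epitope's (shuffled)
            # motif, re-paired with another epitope's peptide and displaced
            decoy_choices = [j for j in range(config.n_epitopes) if j != e]
            picks = rng.choice(
                len(decoy_choices),
                size=min(config.negative_ratio, len(decoy_choices)),
                replace=False,
            )
            for k, pick in enumerate(int(i) for i in picks):
                decoy = make_tcr(f"tcr-e{e}-{t}-dec{k}", ep["motif"])
                out.append(
                    _assemble_complex(
                        f"e{e}t{t}-neg{k}",
                        decoy,
                        epitopes[decoy_choices[pick]]["peptide"],
                        pep_idx,
                        z_shift=_DISPLACEMENT * config.binding_effect,
                        shuffle_motif=bool(rng.random() < config.binding_effect),
                        rng=rng,
                        noise_sd=config.noise_sd,
                        label=-1,
                    )
                )
    return out


def generate_umi_table(
    n_clones: int,
    n_tetramers: int,
    n_spiked: int,
    seed: int,
    n_controls: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]], pd.DataFrame]:
    """Synthetic barcode-level tetramer UMI counts with known truth.

    Background counts are small Poisson noise; ``n_spiked`` randomly chosen
    (clone, tetramer) cells receive counts guaranteed to clear both the
    absolute and the control-fold binding thresholds.  Some clones carry two
    barcodes, with spiked counts split between them, to exercise barcode
    summation.  Returns ``(umi, controls, barcode_map, truth)``.
    """
    if n_spiked > n_clones:
        raise ValueError("cannot spike more clones than exist")
    rng = np.random.default_rng(seed)
    clones = [f"clone{i}" for i in range(n_clones)]
    barcode_map = {}
    barcodes = []
    for i, clone in enumerate(clones):
        n_bc = 2 if rng.random() < 0.3 else 1
        bcs = [f"bc{i}_{j}" for j in range(n_bc)]
        barcode_map[clone] = bcs
        barcodes.extend(bcs)
    tetramers = [f"tet{j}" for j in range(n_tetramers)]
    ctrl_names = [f"ctrl{j}" for j in range(n_controls)]

    umi = pd.DataFrame(
        rng.poisson(0.5, size=(len(barcodes), n_tetramers)), index=barcodes, columns=tetramers
    )
    controls = pd.DataFrame(
        rng.poisson(0.5, size=(len(barcodes), n_controls)), index=barcodes, columns=ctrl_names
    )
    truth = pd.DataFrame(False, index=clones, columns=tetramers)

    spiked_clones = rng.choice(n_clones, size=n_spiked, replace=False)
    for ci in sorted(int(i) for i in spiked_clones):
        clone = clones[ci]
        tet = tetramers[int(rng.integers(0, n_tetramers))]
        max_ctrl = int(controls.loc[barcode_map[clone]].sum(axis=0).max())
        spike = max(11, 5 * max_ctrl + 5) + int(rng.poisson(20))
        # split across the clone's barcodes
        bcs = barcode_map[clone]
        share = spike // len(bcs)
        for j, bc in enumerate(bcs):
            umi.loc[bc, tet] += share if j < len(bcs) - 1 else spike - share * (len(bcs) - 1)
        truth.loc[clone, tet] = True
    return umi, controls, barcode_map, truth
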