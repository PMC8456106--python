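"""Reading, validation and renumbering of TCR-pMHC complex structures.

A complex is an αβ T-cell receptor bound to a peptide presented (optionally)
by an MHC molecule.  Structures arrive as PDB files plus a *numbering
sidecar* that assigns chain roles and per-residue IMGT positions; IMGT
numbering is never inferred here — it is an input produced by external
annotation tools.  The peptide is recentred onto a fixed 20-position frame
so that fingerprints from complexes with different peptide lengths are
comparable.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "TcrPmhcComplex",
    "NumberingSidecar",
    "StructuralError",
    "AnnotationError",
    "PdbParseError",
    "PeptideLengthError",
    "read_complex",
    "write_pdb",
    "renumber_peptide",
    "strip_mhc",
    "cdr_grid_positions",
    "CDR_RANGES",
    "PEPTIDE_FRAME_SIZE",
]

ROLES = ("alpha", "beta", "peptide", "mhc")
MANDATORY_ROLES = ("alpha", "beta", "peptide")

#: IMGT ranges of the three complementarity-determining regions, shared by
#: the α and β chains: CDR1 27-38, CDR2 56-65, CDR3 105-117.
CDR_RANGES = ((27, 38), (56, 65), (105, 117))

PEPTIDE_FRAME_SIZE = 20
MIN_PEPTIDE_LENGTH = 8

_3to1 = dict(protein_letters_3to1)


class StructuralError(ValueError):
    """A mandatory chain is missing or the structure violates an invariant."""


class AnnotationError(ValueError):
    """The numbering sidecar does not match the structure."""


class PdbParseError(ValueError):
    """The PDB source is empty or cannot be parsed."""


class PeptideLengthError(StructuralError):
    """Peptide length outside the supported 8-20 residue range."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    author_number: int
    icode: str
    aa: str
    atoms: tuple[Atom, ...]
    imgt_position: int | None = None
    pep_frame_position: int | None = None


@dataclass(frozen=True)
class Chain:
    chain_id: str
    role: str
    residues: tuple[Residue, ...]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass(frozen=True)
class TcrPmhcComplex:
    """Validated TCR-peptide-(MHC) complex in the standardized frame."""

    complex_id: str
    chains: Mapping[str, Chain]  # keyed by role

    @property
    def alpha(self) -> Chain:
        return self.chains["alpha"]

    @property
    def beta(self) -> Chain:
        return self.chains["beta"]

    @property
    def peptide(self) -> Chain:
        return self.chains["peptide"]

    @property
    def mhc(self) -> Chain | None:
        return self.chains.get("mhc")

    def residue_at(self, role: str, imgt_position: int) -> Residue | None:
        """TCR residue occupying an IMGT position, or None if unresolved."""
        for res in self.chains[role].residues:
            if res.imgt_position == imgt_position:
                return res
        return None

    def peptide_residue_at(self, frame_position: int) -> Residue | None:
        for res in self.peptide.residues:
            if res.pep_frame_position == frame_position:
                return res
        return None


@dataclass(frozen=True)
class NumberingSidecar:
    """Chain role assignment plus (author_number, icode) → IMGT maps.

    Serialized form (YAML or JSON)::

        chains:
          A: {role: alpha, imgt: [[1, " ", 27], [2, " ", 28], ...]}
          B: {role: beta,  imgt: [...]}
          C: {role: peptide}
          D: {role: mhc}
    """

    chains: Mapping[str, dict]

    def __post_init__(self) -> None:
        roles = [spec.get("role") for spec in self.chains.values()]
        for role in MANDATORY_ROLES:
            if role not in roles:
                raise AnnotationError(f"sidecar assigns no chain the role {role!r}")
        for cid, spec in self.chains.items():
            pairs = spec.get("imgt") or []
            keys = [(int(a), str(i)) for a, i, _ in pairs]
            vals = [int(g) for _, _, g in pairs]
            if len(set(keys)) != len(keys) or len(set(vals)) != len(vals):
                raise AnnotationError(f"sidecar mapping for chain {cid!r} is not injective")

    def role_of(self, chain_id: str) -> str | None:
        spec = self.chains.get(chain_id)
        return None if spec is None else spec.get("role")

    def imgt_map(self, chain_id: str) -> dict[tuple[int, str], int]:
        spec = self.chains.get(chain_id, {})
        return {(int(a), str(i)): int(g) for a, i, g in (spec.get("imgt") or [])}

    @classmethod
    def from_dict(cls, data: Mapping) -> "NumberingSidecar":
        return cls(chains=dict(data["chains"]))

    @classmethod
    def from_yaml(cls, text_or_path) -> "NumberingSidecar":
        text = _slurp(text_or_path)
        return cls.from_dict(yaml.safe_load(text))

    def to_dict(self) -> dict:
        return {"chains": {k: dict(v) for k, v in self.chains.items()}}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def _slurp(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if "\n" not in text and len(text) < 4096:
        try:
            with open(text) as fh:
                return fh.read()
        except (OSError, ValueError):
            pass
    return text


def _pdb_text(source) -> str:
    text = _slurp(source)
    if not text.strip():
        raise PdbParseError("empty PDB source")
    return text


def read_complex(pdb_source, sidecar: NumberingSidecar, complex_id: str | None = None) -> TcrPmhcComplex:
    """Parse a PDB file and apply the sidecar's roles and IMGT numbering.

    Hydrogens are dropped; alternate locations resolve to the highest
    occupancy (ties to the first conformer in the file).  TCR residues absent
    from the sidecar carry ``imgt_position=None``.  Sidecar entries that do
    not match any residue in the chain raise :class:`AnnotationError`.
    """
    text = _pdb_text(pdb_source)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(complex_id or "complex", io.StringIO(text))
    except Exception as exc:  # Bio.PDB raises a zoo of exception types
        raise PdbParseError(f"cannot parse PDB source: {exc}") from exc
    models = list(structure)
    if not models:
        raise PdbParseError("PDB source contains no model")
    model = models[0]

    chains: dict[str, Chain] = {}
    for bio_chain in model:
        cid = bio_chain.id
        role = sidecar.role_of(cid)
        if role is None:
            continue
        imgt = sidecar.imgt_map(cid)
        seen_keys: set[tuple[int, str]] = set()
        residues = []
        for bio_res in bio_chain:
            het, num, icode = bio_res.id
            if het.strip():  # skip waters / heteroatoms
                continue
            atoms = _select_atoms(bio_res)
            if not atoms:
                raise StructuralError(
                    f"residue {num}{icode.strip()} in chain {cid} has no non-hydrogen atom"
                )
            aa = _3to1.get(bio_res.get_resname().upper(), "X")
            key = (num, icode)
            seen_keys.add(key)
            residues.append(
                Residue(
                    author_number=num,
                    icode=icode,
                    aa=aa,
                    atoms=tuple(atoms),
                    imgt_position=imgt.get(key) if role in ("alpha", "beta") else None,
                )
            )
        if role in ("alpha", "beta"):
            missing = set(imgt) - seen_keys
            if missing:
                raise AnnotationError(
                    f"sidecar maps residues absent from chain {cid}: {sorted(missing)}"
                )
        if role in chains:
            raise StructuralError(f"role {role!r} assigned to more than one chain")
        chains[role] = Chain(chain_id=cid, role=role, residues=tuple(residues))

    for role in MANDATORY_ROLES:
        if role not in chains:
            raise StructuralError(f"mandatory chain missing: {role}")

    complex_ = TcrPmhcComplex(complex_id=complex_id or "complex", chains=chains)
    _validate(complex_)
    return complex_


def _select_atoms(bio_res) -> list[Atom]:
    # resolve altlocs to the highest occupancy; ties keep the first conformer
    picked: dict[str, tuple[float, int, Atom]] = {}
    order = 0
    for atom in bio_res.get_unpacked_list():
        element = (atom.element or "").strip().upper() or atom.get_name()[0].upper()
        if element == "H":
            continue
        name = atom.get_name()
        occ = atom.get_occupancy()
        occ = 1.0 if occ is None else float(occ)
        candidate = (occ, -order, _to_atom(atom))
        prev = picked.get(name)
        if prev is None or candidate[:2] > prev[:2]:
            picked[name] = candidate
        order += 1
    return [entry[2] for entry in picked.values()]


def _to_atom(bio_atom) -> Atom:
    x, y, z = (float(v) for v in bio_atom.get_coord())
    element = (bio_atom.element or "").strip().upper() or bio_atom.get_name()[0].upper()
    return Atom(name=bio_atom.get_name(), element=element, xyz=(x, y, z))


def _validate(complex_: TcrPmhcComplex) -> None:
    pep_len = len(complex_.peptide.residues)
    if not (MIN_PEPTIDE_LENGTH <= pep_len <= PEPTIDE_FRAME_SIZE):
        raise PeptideLengthError(
            f"peptide length {pep_len} outside supported range "
            f"[{MIN_PEPTIDE_LENGTH}, {PEPTIDE_FRAME_SIZE}]"
        )
    for chain in complex_.chains.values():
        for res in chain.residues:
            for atom in res.atoms:
                if not all(math.isfinite(v) for v in atom.xyz):
                    raise StructuralError(
                        f"non-finite coordinate in chain {chain.chain_id} residue {res.author_number}"
                    )
        assigned = [r.imgt_position for r in chain.residues if r.imgt_position is not None]
        if any(b <= a for a, b in zip(assigned, assigned[1:])):
            raise AnnotationError(
                f"IMGT positions not strictly increasing along chain {chain.chain_id}"
            )


def renumber_peptide(complex_: TcrPmhcComplex) -> TcrPmhcComplex:
    """Recentre the peptide onto the 1-20 frame.

    The residue at 1-based chain index ``k`` is assigned frame position
    ``10 - floor((L-1)/2) + (k-1)``, which puts the middle residue of an
    odd-length peptide at position 10 and the middle pair of an even-length
    peptide at positions 10 and 11; a 20-mer spans the whole 1-20 frame.
    """
    L = len(complex_.peptide.residues)
    if not (MIN_PEPTIDE_LENGTH <= L <= PEPTIDE_FRAME_SIZE):
        raise PeptideLengthError(f"peptide length {L} outside [8, 20]")
    start = 10 - (L - 1) // 2
    residues = tuple(
        replace(res, pep_frame_position=start + k)
        for k, res in enumerate(complex_.peptide.residues)
    )
    chains = dict(complex_.chains)
    chains["peptide"] = replace(complex_.peptide, residues=residues)
    return replace(complex_, chains=chains)


def strip_mhc(complex_: TcrPmhcComplex) -> TcrPmhcComplex:
    """Drop the MHC chain; no-op (and idempotent) when it is absent."""
    if "mhc" not in complex_.chains:
        return complex_
    chains = {role: ch for role, ch in complex_.chains.items() if role != "mhc"}
    return replace(complex_, chains=chains)


def cdr_grid_positions(variant: str = "cdr") -> tuple[tuple[str, int], ...]:
    """The fixed (chain, IMGT position) feature grid.

    ``variant="cdr"`` (default) is the union of the CDR ranges 27-38, 56-65
    and 105-117 — 35 positions per chain, 70 in total, α before β.
    ``variant="contiguous"`` covers every position 27-117 inclusive.
    """
    if variant == "cdr":
        per_chain = [p for lo, hi in CDR_RANGES for p in range(lo, hi + 1)]
    elif variant == "contiguous":
        per_chain = list(range(27, 118))
    else:
        raise ValueError(f"unknown grid variant {variant!r}")
    return tuple((role, pos) for role in ("alpha", "beta") for pos in per_chain)


_ROLE_ORDER = {"alpha": 0, "beta": 1, "peptide": 2, "mhc": 3}

_1to3 = {v: k for k, v in _3to1.items()}


def write_pdb(complex_: TcrPmhcComplex) -> str:
    """Serialize a complex back to PDB text (standard ATOM records)."""
    lines = []
    serial = 1
    for role in sorted(complex_.chains, key=_ROLE_ORDER.get):
        chain = complex_.chains[role]
        for res in chain.residues:
            resname = _1to3.get(res.aa, "UNK")
            for atom in res.atoms:
                name = atom.name
                # PDB atom-name column convention: element-aligned packing
                pname = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.xyz
                lines.append(
                    f"ATOM  {serial:>5d} {pname:<4s}{resname:>4s} {chain.chain_id}"
                    f"{res.author_number:>4d}{res.icode:1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def sidecar_for(complex_: TcrPmhcComplex) -> NumberingSidecar:
    """Build the sidecar that reproduces a complex's roles and numbering."""
    chains = {}
    for role, chain in complex_.chains.items():
        spec: dict = {"role": role}
        if role in ("alpha", "beta"):
            spec["imgt"] = [
                [r.author_number, r.icode, r.imgt_position]
                for r in chain.residues
                if r.imgt_position is not None
            ]
        chains[chain.chain_id] = spec
    return NumberingSidecar(chains=chains)
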