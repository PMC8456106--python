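"""Pairwise residue-residue interaction energies at the TCR-peptide interface.

The classifier consumes a four-term decomposition of each CDR-peptide residue
pair: attractive and repulsive van der Waals (``atr``, ``rep``), screened
electrostatics (``elec``) and an implicit-solvation term (``sol``), computed
on the complex with the MHC chain removed so that only context-independent
TCR-peptide interactions contribute.

The built-in backend is a deliberately simple physics model with the same
decomposition and sign conventions as full molecular-mechanics scorers:

* Lennard-Jones 12-6 with Lorentz combination ``r_m = R_i + R_j`` and
  geometric-mean well depth, split so that the attractive channel is the LJ
  value for ``r >= r_m`` and saturates at ``-eps`` inside the minimum, while
  the repulsive channel collects the excess ``LJ(r) + eps`` for ``r < r_m``.
* Coulomb electrostatics with a distance-dependent dielectric
  ``eps(r) = 10 * max(r, 1.6 Å)``.
* Gaussian-exclusion solvation: each atom's desolvation free-energy density
  integrated over the partner atom's volume, positive (unfavourable) when a
  polar atom is buried.

All terms are multiplied by a linear switching function that is 1 up to
5.5 Å and 0 beyond 6.0 Å, matching the 6 Å contact radius used for the
contact-frequency summaries.  Any backend with the signature
``(complex) -> EnergyTerms`` (e.g. an adapter around a molecular-mechanics
package) can replace the default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import yaml

from .structures import Residue, TcrPmhcComplex, cdr_grid_positions, strip_mhc

__all__ = [
    "AtomParams",
    "EnergyTerms",
    "ENERGY_CHANNELS",
    "default_params",
    "pair_energy",
    "energy_fingerprints",
]

log = logging.getLogger(__name__)

ENERGY_CHANNELS = ("atr", "rep", "elec", "sol")


@dataclass(frozen=True)
class ElementParams:
    lj_radius: float
    lj_welldepth: float
    solv_dgfree: float
    solv_volume: float
    solv_lambda: float


@dataclass(frozen=True)
class AtomParams:
    """Force-field constants: per-element LJ/solvation plus charge rules."""

    elements: Mapping[str, ElementParams]
    backbone_charges: Mapping[str, float]
    sidechain_charges: Mapping[str, Mapping[str, float]]
    switch_start: float = 5.5
    switch_end: float = 6.0
    coulomb_constant: float = 332.0
    dielectric_slope: float = 10.0
    dielectric_floor: float = 1.6

    def element(self, symbol: str) -> ElementParams:
        ep = self.elements.get(symbol.upper())
        if ep is None:
            log.warning("unknown element %r: using default parameters", symbol)
            ep = self.elements["default"]
        return ep

    def charge(self, aa: str, atom_name: str) -> float:
        side = self.sidechain_charges.get(aa.upper(), {})
        if atom_name in side:
            return side[atom_name]
        return self.backbone_charges.get(atom_name, 0.0)

    @classmethod
    def from_dict(cls, data: Mapping) -> "AtomParams":
        elements = {
            sym.upper(): ElementParams(**vals) for sym, vals in data["elements"].items()
        }
        if "default" not in {s.lower() for s in elements}:
            raise ValueError("parameter file must define a 'default' element entry")
        elements["default"] = elements.pop("DEFAULT", elements.get("default"))
        charges = data.get("charges", {})
        switch = data.get("switch", {})
        elec = data.get("electrostatics", {})
        return cls(
            elements=elements,
            backbone_charges=dict(charges.get("backbone", {})),
            sidechain_charges={k: dict(v) for k, v in charges.get("sidechain", {}).items()},
            switch_start=float(switch.get("start", 5.5)),
            switch_end=float(switch.get("end", 6.0)),
            coulomb_constant=float(elec.get("coulomb_constant", 332.0)),
            dielectric_slope=float(elec.get("dielectric_slope", 10.0)),
            dielectric_floor=float(elec.get("dielectric_floor", 1.6)),
        )

    @classmethod
    def from_yaml(cls, text_or_path) -> "AtomParams":
        if hasattr(text_or_path, "read"):
            text = text_or_path.read()
        else:
            text = str(text_or_path)
            if "\n" not in text:
                with open(text) as fh:
                    text = fh.read()
        return cls.from_dict(yaml.safe_load(text))


def default_params() -> AtomParams:
    """The packaged default parameter set (``data/energy_params.yaml``)."""
    text = resources.files("tcrkernel.data").joinpath("energy_params.yaml").read_text()
    return AtomParams.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class EnergyTerms:
    """One fingerprint matrix per energy channel (grid rows × 20 peptide cols).

    Cells are NaN where either residue is unresolved; exactly zero for pairs
    whose atoms never come within the switching cutoff.
    """

    atr: np.ndarray
    rep: np.ndarray
    elec: np.ndarray
    sol: np.ndarray
    grid: tuple[tuple[str, int], ...]

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _switch(r: float, start: float, end: float) -> float:
    if r <= start:
        return 1.0
    if r >= end:
        return 0.0
    return (end - r) / (end - start)


def pair_energy(
    residue_a: Residue, residue_b: Residue, params: AtomParams | None = None
) -> tuple[float, float, float, float]:
    """Sum the four interaction terms over all atom pairs of two residues.

    Returns ``(atr, rep, elec, sol)``; symmetric in its residue arguments,
    continuous in distance and exactly zero when the closest atom pair is
    beyond the outer switching radius.
    """
    params = params or default_params()
    atr = rep = elec = sol = 0.0
    two_pi_32 = 2.0 * math.pi ** 1.5
    for ai in residue_a.atoms:
        pi = params.element(ai.element)
        qi = params.charge(residue_a.aa, ai.name)
        for aj in residue_b.atoms:
            dx = ai.xyz[0] - aj.xyz[0]
            dy = ai.xyz[1] - aj.xyz[1]
            dz = ai.xyz[2] - aj.xyz[2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r >= params.switch_end:
                continue
            s = _switch(r, params.switch_start, params.switch_end)
            pj = params.element(aj.element)
            qj = params.charge(residue_b.aa, aj.name)
            r_m = pi.lj_radius + pj.lj_radius
            eps = math.sqrt(pi.lj_welldepth * pj.lj_welldepth)
            if r > 0:
                ratio6 = (r_m / r) ** 6
                lj = eps * (ratio6 * ratio6 - 2.0 * ratio6)
            else:
                lj = math.inf
            if r >= r_m:
                atr += lj * s
            else:
                atr += -eps * s
                rep += (lj + eps) * s
            if qi != 0.0 and qj != 0.0 and r > 0:
                diel = params.dielectric_slope * max(r, params.dielectric_floor)
                elec += params.coulomb_constant * qi * qj / (diel * r) * s
            if r > 0:
                fi = (
                    pi.solv_dgfree
                    / (two_pi_32 * pi.solv_lambda * r * r)
                    * math.exp(-(((r - pi.lj_radius) / pi.solv_lambda) ** 2))
                )
                fj = (
                    pj.solv_dgfree
                    / (two_pi_32 * pj.solv_lambda * r * r)
                    * math.exp(-(((r - pj.lj_radius) / pj.solv_lambda) ** 2))
                )
                sol += (fi * pj.solv_volume + fj * pi.solv_volume) * s
    return atr, rep, elec, sol


def energy_fingerprints(
    complex_: TcrPmhcComplex,
    params: AtomParams | None = None,
    grid_variant: str = "cdr",
) -> EnergyTerms:
    """Energy fingerprints over the CDR grid × peptide frame.

    The MHC chain is removed internally before scoring, so only TCR-peptide
    interactions contribute.  Grid cells whose CDR or peptide position is
    unoccupied are NaN.
    """
    params = params or default_params()
    complex_ = strip_mhc(complex_)
    grid = cdr_grid_positions(grid_variant)
    n_pep = 20
    mats = {ch: np.full((len(grid), n_pep), np.nan) for ch in ENERGY_CHANNELS}

    pep_residues = {
        r.pep_frame_position: r
        for r in complex_.peptide.residues
        if r.pep_frame_position is not None
    }
    tcr_residues: dict[tuple[str, int], Residue] = {}
    for role in ("alpha", "beta"):
        for r in complex_.chains[role].residues:
            if r.imgt_position is not None:
                tcr_residues[(role, r.imgt_position)] = r

    for gi, key in enumerate(grid):
        res_a = tcr_residues.get(key)
        if res_a is None:
            continue
        for pos, res_b in pep_residues.items():
            vals = pair_energy(res_a, res_b, params)
            for ch, v in zip(ENERGY_CHANNELS, vals):
                mats[ch][gi, pos - 1] = v
    return EnergyTerms(grid=grid, **mats)


EnergyBackend = Callable[[TcrPmhcComplex], EnergyTerms]
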