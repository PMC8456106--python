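import warnings

import numpy as np
import pytest

from tcrkernel.features import assemble
from tcrkernel.structures import Atom, Chain, Residue, TcrPmhcComplex
from tcrkernel.synthetic import SimulationConfig, generate_complexes


def make_residue(number, aa, atom_specs, imgt=None, pep_frame=None):
    """Toy residue from (name, element, xyz) triples."""
    atoms = tuple(Atom(name=n, element=e, xyz=tuple(map(float, xyz))) for n, e, xyz in atom_specs)
    return Residue(
        author_number=number,
        icode=" ",
        aa=aa,
        atoms=atoms,
        imgt_position=imgt,
        pep_frame_position=pep_frame,
    )


def single_atom_residue(aa="A", element="C", xyz=(0.0, 0.0, 0.0), name=None, number=1):
    return make_residue(number, aa, [(name or element, element, xyz)])


@pytest.fixture(scope="session")
def strong_cohort():
    """Synthetic cohort with strong binding signal: 4 epitopes × 15 TCRs."""
    cfg = SimulationConfig(seed=7, n_epitopes=4, tcrs_per_epitope=15, binding_effect=0.9)
    return generate_complexes(cfg)


@pytest.fixture(scope="session")
def strong_table(strong_cohort):
    """Distances + attractive vdW + Atchley features of the strong cohort."""
    complexes = [sc.load() for sc in strong_cohort]
    labels = {sc.complex_id: sc.record.label for sc in strong_cohort}
    return assemble(complexes, ("dist", "atr", "atchley"), labels=labels)


@pytest.fixture
def toy_complex():
    """Minimal hand-built complex: 2 CDR3 residues per chain, 9-mer peptide."""
    def pep_res(k, aa):
        x = 3.8 * k
        return make_residue(
            k + 1,
            aa,
            [("N", "N", (x - 1.2, 0.8, 0)), ("CA", "C", (x, 0, 0)),
             ("C", "C", (x + 1.2, 0.8, 0)), ("O", "O", (x + 1.2, 2.0, 0))],
            pep_frame=6 + k,
        )

    def tcr_res(num, aa, imgt, x, z):
        return make_residue(
            num, aa,
            [("CA", "C", (x, 0, z)), ("CB", "C", (x, 0, z - 1.5))],
            imgt=imgt,
        )

    peptide = Chain("C", "peptide", tuple(pep_res(k, "AGSTKLVDE"[k]) for k in range(9)))
    alpha = Chain("A", "alpha", (tcr_res(1, "Y", 109, 3.8, 5.8), tcr_res(2, "W", 110, 7.6, 5.8)))
    beta = Chain("B", "beta", (tcr_res(1, "F", 109, 15.2, 5.8), tcr_res(2, "L", 110, 19.0, 5.8)))
    mhc = Chain("D", "mhc", (make_residue(1, "G", [("CA", "C", (0, 0, -30.0))]),))
    return TcrPmhcComplex(
        complex_id="toy",
        chains={"alpha": alpha, "beta": beta, "peptide": peptide, "mhc": mhc},
    )


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="reducing internal CV folds")
        warnings.filterwarnings("ignore", message=r"\d+ features missing on every training row")
        yield
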