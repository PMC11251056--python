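"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import bisect

import gemmi

from msbind import BindingModel, SpeciesDefinition


# ---------------------------------------------------------------------------
# independent equilibrium oracle: explicit species enumeration + scipy bisect
# ---------------------------------------------------------------------------

def oracle_equilibrium(k_d, p_total, l_total, n_grid=2001):
    """Brute-force sequential-binding equilibrium, independent of the package.

    Enumerates the species concentrations [PL_i] explicitly from the
    stepwise constants at a trial free-ligand value, scans a dense grid
    for a sign change of the mass-balance residual, and polishes the root
    with scipy's bisection. Returns (l_free, fractions).
    """
    k_d = np.atleast_1d(np.asarray(k_d, dtype=float))
    k_a = 1.0 / k_d

    def fractions(x):
        conc = [1.0]  # [P] in arbitrary units
        for j in range(k_a.size):
            conc.append(conc[-1] * k_a[j] * x)
        conc = np.array(conc)
        return conc / conc.sum()

    def residual(x):
        f = fractions(x)
        bound = sum(i * f[i] for i in range(f.size))
        return x + p_total * bound - l_total

    if l_total == 0:
        return 0.0, fractions(0.0)
    grid = np.linspace(0.0, l_total, n_grid)
    vals = np.array([residual(x) for x in grid])
    idx = int(np.argmax(vals > 0))
    if idx == 0:  # residual positive from the start -> root at 0
        return 0.0, fractions(0.0)
    root = bisect(residual, grid[idx - 1], grid[idx], xtol=1e-13)
    return root, fractions(root)


def quadratic_single_site(k_d, p_total, l_total):
    """Closed-form single-site free ligand: x^2 + (K_D + P − L)x − K_D·L = 0."""
    b = k_d + p_total - l_total
    return (-b + np.sqrt(b * b + 4.0 * k_d * l_total)) / 2.0


# ---------------------------------------------------------------------------
# model / species fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def atp_model():
    """Two-site nucleotide model at the fitted ATP stepwise constants."""
    return BindingModel.from_kd([47.8, 124.4])


@pytest.fixture
def adp_model():
    return BindingModel.from_kd([17.8, 62.3])


@pytest.fixture
def lipid_model():
    """Four tight sequential lipid sites (sub-to-low µM)."""
    return BindingModel.from_kd([0.25, 0.5, 1.0, 2.0])


@pytest.fixture
def atp_species():
    """Dimer + 0..2 ATP mass ladder."""
    return SpeciesDefinition(base_mass=128_700.0,
                             ligand_masses={"ATP": 507.18},
                             max_counts={"ATP": 2})


# ---------------------------------------------------------------------------
# synthetic structure files (labelled synthetic: coordinates invented here)
# ---------------------------------------------------------------------------

def make_dimer_structure(ca_a, ca_b, residue_number=561, extra_chain=False):
    """Build a minimal two-chain gemmi structure with one marker residue.

    Synthetic stand-in for a transporter homodimer: each chain holds a
    threonine whose CA sits at the given coordinate, plus a CB offset
    atom so atom-name lookup is exercised.
    """
    st = gemmi.Structure()
    st.name = "synthetic-dimer"
    model = gemmi.Model("1")
    for chain_name, ca in (("A", ca_a), ("B", ca_b)):
        chain = gemmi.Chain(chain_name)
        res = gemmi.Residue()
        res.name = "THR"
        res.seqid = gemmi.SeqId(residue_number, " ")
        for atom_name, offset in (("CA", (0, 0, 0)), ("CB", (1.5, 0, 0))):
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.pos = gemmi.Position(ca[0] + offset[0], ca[1] + offset[1],
                                      ca[2] + offset[2])
            res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
    if extra_chain:
        chain = gemmi.Chain("C")
        res = gemmi.Residue()
        res.name = "HOH"
        res.seqid = gemmi.SeqId(1, " ")
        atom = gemmi.Atom()
        atom.name = "O"
        atom.element = gemmi.Element("O")
        atom.pos = gemmi.Position(0, 0, 0)
        res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


@pytest.fixture
def dimer_pdb(tmp_path):
    """A synthetic dimer written to PDB with CA atoms 50 Å apart."""
    st = make_dimer_structure((0.0, 0.0, 0.0), (50.0, 0.0, 0.0))
    path = tmp_path / "synthetic_dimer.pdb"
    st.write_pdb(str(path))
    return path


@pytest.fixture
def dimer_cif(tmp_path):
    st = make_dimer_structure((0.0, 0.0, 0.0), (0.0, 30.0, 40.0))
    path = tmp_path / "synthetic_dimer.cif"
    st.make_mmcif_document().write_file(str(path))
    return path
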