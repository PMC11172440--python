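import numpy as np
import pytest

from peprefine.structmodel import AtomRecord, ComplexModel, MolecularStructure, Role


def mk_atom(serial, name, element, resname, resid, chain, pos, role):
    return AtomRecord(serial, name, element, resname, resid, chain, np.asarray(pos, float), role)


def mk_peptide(chain="B", role=Role.LIGAND, n_res=3, spacing=3.8, serial0=100):
    """Minimal peptide: N, CA, C, O, CB per residue along the x axis."""
    atoms = []
    serial = serial0
    for i in range(n_res):
        base = np.array([spacing * i, 0.0, 0.0])
        for name, el, off in [
            ("N", "N", (-1.2, -0.8, 0.0)),
            ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.3, -0.7, 0.2)),
            ("O", "O", (1.5, -1.9, 0.1)),
            ("CB", "C", (0.7, 1.2, 0.6)),
        ]:
            atoms.append(mk_atom(serial, name, el, "ALA", i + 1, chain, base + np.array(off), role))
            serial += 1
    return MolecularStructure(atoms, f"peptide-{chain}")


def mk_target(n_res=4, serial0=1):
    """Non-collinear target scaffold with Calpha atoms suitable for fitting."""
    atoms = []
    serial = serial0
    rng = np.random.default_rng(11)
    for i in range(n_res):
        base = np.array([3.8 * i, -6.0 + 0.5 * np.cos(2 * i), 0.8 * np.sin(1.5 * i)])
        for name, el, off in [
            ("N", "N", (-1.2, 0.8, 0.0)),
            ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.3, 0.7, 0.2)),
            ("O", "O", (1.5, 1.9, 0.1)),
        ]:
            atoms.append(
                mk_atom(serial, name, el, "ALA", i + 1, "A", base + np.array(off), Role.TARGET)
            )
            serial += 1
    return MolecularStructure(atoms, "target")


def mk_water(resid, pos, serial):
    return mk_atom(serial, "O", "O", "HOH", resid, "W", pos, Role.WATER)


@pytest.fixture
def toy_complex():
    return ComplexModel(mk_target(), mk_peptide())


@pytest.fixture
def fixture_pair():
    from peprefine.fixtures import FixtureConfig, make_toy_complex

    cfg = FixtureConfig(seed=7)
    docked, reference = make_toy_complex(cfg)
    return cfg, docked, reference
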