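"""Shared fixtures: synthetic lattices, templates and toy structures."""

import numpy as np
import pytest
from hypothesis import settings

import doubletlattice as dl

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def protein_chain(sequence: str, chain_id: str = "A",
                  start: int = 1, spacing: float = 3.8) -> dl.StructureModel:
    """Minimal CA-only chain carrying a given one-letter sequence."""
    n = len(sequence)
    return dl.StructureModel(
        [chain_id] * n,
        [THREE_LETTER[c] for c in sequence],
        list(range(start, start + n)),
        ["CA"] * n,
        ["C"] * n,
        np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)]),
    )


@pytest.fixture(scope="session")
def template_alpha():
    return dl.make_template_monomer("alpha")


@pytest.fixture(scope="session")
def template_beta():
    return dl.make_template_monomer("beta")


@pytest.fixture(scope="session")
def singlet13():
    return dl.build_singlet(dl.LatticeSpec(n_pf=13, n_repeats=2))


@pytest.fixture(scope="session")
def singlet13_assignment(singlet13):
    return dl.assign_pfs(singlet13)


@pytest.fixture(scope="session")
def doublet():
    return dl.build_doublet(dl.LatticeSpec(n_pf=13, n_repeats=2),
                            dl.LatticeSpec(n_pf=15, n_repeats=2, open_arc=10))


@pytest.fixture(scope="session")
def doublet_assignment(doublet):
    return dl.assign_pfs(doublet)


@pytest.fixture(scope="session")
def doublet_map(doublet):
    """Noiseless doublet density padded enough for 4-nm register shifts."""
    return dl.simulate_density(doublet, 8.0, 3.0, pad=45.0)


def single_atom(element="C", position=(0.0, 0.0, 0.0), name="C1",
                resname="GLY", chain="A", seq=1):
    return dl.StructureModel([chain], [resname], [seq], [name], [element],
                             np.asarray(position, float).reshape(1, 3))


def atom_pair(distance, element="C", chains=("A", "B")):
    return dl.StructureModel(
        list(chains), ["GLY", "GLY"], [1, 2], ["C1", "C1"],
        [element, element],
        np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]))
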