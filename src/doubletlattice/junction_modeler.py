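"""Hypothetical outer-junction models.

The outer junction of the doublet — PF-B1 bound between PFs-A10 and A11 — is
tested for positional specificity by grafting the junction onto every other
adjacent A-tubule PF pair: the A10 dimer template is superposed onto one host
PF and the rigid A11/B1 complex onto the other (fitting only its A11 region),
then each graft is scored by A10–B1 salt bridges, steric clashes and the
minimum inter-PF gap.  Pairs with too-low local curvature clash; pairs with
too-high curvature leave a gap that forms no bridges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import StructureModel
from .interface_analysis import (CLASH_OVERLAP, SALT_BRIDGE_CUTOFF,
                                 count_clashes, detect_salt_bridges)
from .lattice_geometry import PFAssignment, superpose

__all__ = [
    "JunctionTemplates",
    "JunctionModel",
    "JunctionScore",
    "extract_junction_templates",
    "build_hypothetical_junction",
    "score_junction",
    "junction_scan",
]


@dataclass
class JunctionTemplates:
    a10: StructureModel               # one A10 dimer
    a11_b1: StructureModel            # rigid A11+B1 complex (two dimers)
    a11_chains: tuple[str, ...]       # chains of the A11 region inside a11_b1
    b1_chains: tuple[str, ...]


@dataclass
class JunctionModel:
    host_pair: tuple[str, str]
    model: StructureModel             # grafted A10 template + A11/B1 complex
    a10_chains: tuple[str, ...]
    b1_chains: tuple[str, ...]
    rmsd_a10: float
    rmsd_a11: float


@dataclass
class JunctionScore:
    host_pair: tuple[str, str]
    n_salt_bridges: int
    n_clashes: int
    min_gap: float
    verdict: str = field(init=False)

    def __post_init__(self):
        if self.n_clashes > 0:
            self.verdict = "clash"
        elif self.n_salt_bridges == 0:
            self.verdict = "no-bridge-gap"
        else:
            self.verdict = "compatible"


def _pf_dimer(doublet: StructureModel, assignment: PFAssignment,
              pf: str) -> StructureModel:
    if pf not in assignment.chains_of_pf:
        raise ValueError(f"assignment lacks PF {pf}")
    chains = assignment.chains_of_pf[pf][:2]
    return doublet.subset(np.isin(doublet.chain_ids, chains))


def extract_junction_templates(doublet: StructureModel,
                               assignment: PFAssignment) -> JunctionTemplates:
    """One A10 dimer and the rigid A11/B1 two-dimer complex."""
    a10 = _pf_dimer(doublet, assignment, "A10")
    a11 = _pf_dimer(doublet, assignment, "A11")
    b1 = _pf_dimer(doublet, assignment, "B1")
    complex_model = StructureModel.concat([a11, b1])
    return JunctionTemplates(a10, complex_model,
                             tuple(a11.chains), tuple(b1.chains))


def _superpose_subset(mobile: StructureModel, mobile_region: StructureModel,
                      target: StructureModel):
    """Fit mobile_region onto target; apply the transform to all of mobile."""
    if len(mobile_region) == len(target):
        t, rmsd = superpose(mobile_region, target)
    else:
        n = min(len(mobile_region), len(target))
        from .lattice_geometry import kabsch
        t, rmsd = kabsch(mobile_region.coords[:n], target.coords[:n])
    return mobile.with_coords(t.apply(mobile.coords)), rmsd


def build_hypothetical_junction(doublet: StructureModel,
                                assignment: PFAssignment,
                                host_pair: tuple[str, str],
                                templates: JunctionTemplates | None = None
                                ) -> JunctionModel:
    """Graft the outer junction onto an adjacent A-tubule PF pair.

    The A10 template is superposed onto the host pair's first PF and the
    A11/B1 complex onto the second using only its A11-region atoms; B1 is
    carried along rigidly (internal geometry untouched).
    """
    pf_i, pf_j = host_pair
    if (host_pair not in assignment.adjacent_pairs("A")
            and (pf_j, pf_i) not in assignment.adjacent_pairs("A")):
        raise ValueError(f"host pair {host_pair} is not adjacent in the A-tubule")
    templates = templates or extract_junction_templates(doublet, assignment)
    host_i = _pf_dimer(doublet, assignment, pf_i)
    host_j = _pf_dimer(doublet, assignment, pf_j)

    a10_fitted, rmsd_a10 = _superpose_subset(
        templates.a10, templates.a10, host_i)
    a11_region = templates.a11_b1.subset(
        np.isin(templates.a11_b1.chain_ids, templates.a11_chains))
    complex_fitted, rmsd_a11 = _superpose_subset(
        templates.a11_b1, a11_region, host_j)

    # disambiguate chain ids in the merged graft
    a10_g = a10_fitted.copy()
    a10_g.chain_ids = np.array([f"g{c}" for c in a10_g.chain_ids], dtype=object)
    cplx_g = complex_fitted.copy()
    cplx_g.chain_ids = np.array([f"h{c}" for c in cplx_g.chain_ids], dtype=object)
    merged = StructureModel.concat(
        [a10_g, cplx_g], metadata={"host_pair": list(host_pair)})
    return JunctionModel(
        host_pair, merged,
        tuple(f"g{c}" for c in templates.a10.chains),
        tuple(f"h{c}" for c in templates.b1_chains),
        rmsd_a10, rmsd_a11)


def score_junction(jm: JunctionModel,
                   salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF,
                   clash_overlap: float = CLASH_OVERLAP) -> JunctionScore:
    """Salt bridges, clashes and minimum gap between grafted A10 and B1.

    Verdict: 'clash' if any severe overlap, 'no-bridge-gap' if clash-free
    but bridge-free, else 'compatible'.
    """
    bridges = detect_salt_bridges(jm.model, jm.a10_chains, jm.b1_chains,
                                  salt_bridge_cutoff)
    n_clashes, _ = count_clashes(jm.model, jm.a10_chains, jm.b1_chains,
                                 clash_overlap)
    a = jm.model.subset(np.isin(jm.model.chain_ids, jm.a10_chains)).heavy()
    b = jm.model.subset(np.isin(jm.model.chain_ids, jm.b1_chains)).heavy()
    from scipy.spatial import cKDTree
    d, _ = cKDTree(a.coords).query(b.coords, k=1)
    return JunctionScore(jm.host_pair, len(bridges), n_clashes, float(d.min()))


def junction_scan(doublet: StructureModel, assignment: PFAssignment,
                  salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF,
                  clash_overlap: float = CLASH_OVERLAP) -> pd.DataFrame:
    """Score a grafted outer junction on every adjacent A-tubule PF pair.

    Returns a deterministic table with the native (A10, A11) pair flagged.
    """
    templates = extract_junction_templates(doublet, assignment)
    rows = []
    for pair in assignment.adjacent_pairs("A"):
        jm = build_hypothetical_junction(doublet, assignment, pair, templates)
        score = score_junction(jm, salt_bridge_cutoff, clash_overlap)
        rows.append({
            "pf_i": pair[0], "pf_j": pair[1],
            "n_salt_bridges": score.n_salt_bridges,
            "n_clashes": score.n_clashes,
            "min_gap_A": score.min_gap,
            "verdict": score.verdict,
            "native": pair == ("A10", "A11"),
            "rmsd_a10_A": jm.rmsd_a10, "rmsd_a11_A": jm.rmsd_a11,
        })
    return pd.DataFrame(rows)
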