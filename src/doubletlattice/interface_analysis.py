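"""Chain–chain interface quantification.

Solvent-accessible surface area (SASA) by deterministic Shrake–Rupley sphere
sampling, buried surface area (BSA), salt-bridge detection, steric-clash
counting, and a simplified cutoff nonbonded score (shifted Coulomb +
switched Lennard-Jones).  The nonbonded score is a comparator for ranking
interfaces (stronger/weaker), not an energy in kcal/mol; its unit is
arbitrary.

BSA convention: the headline number is the full sum
SASA(A) + SASA(B) - SASA(AB); the halved value is also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core_io import StructureModel

__all__ = [
    "SasaResult",
    "SaltBridge",
    "ClashRecord",
    "InterfaceReport",
    "sphere_points",
    "compute_sasa",
    "buried_surface_area",
    "detect_salt_bridges",
    "count_clashes",
    "nonbonded_score",
    "interface_report",
    "outer_junction_interfaces",
]

DEFAULT_PROBE = 1.4          # A, water probe
DEFAULT_N_POINTS = 960
SALT_BRIDGE_CUTOFF = 4.0     # A, charged-group heavy-atom distance
CLASH_OVERLAP = 0.4          # A, severe vdW overlap
NB_CUTOFF = 8.5              # A, nonbonded cutoff
NB_SWITCH_ON = 6.5           # A, vdW switching starts
COULOMB_K = 332.0636         # (arbitrary-unit) * A / e^2 scale factor

# Charged-group atoms: formal charge sits on the group centroid.
# His is treated as protonated (+1): required for H283-D306 style bridges.
DONOR_GROUPS: dict[str, tuple[list[str], float]] = {
    "ARG": (["NE", "NH1", "NH2"], +1.0),
    "LYS": (["NZ"], +1.0),
    "HIS": (["ND1", "NE2"], +1.0),
}
ACCEPTOR_GROUPS: dict[str, tuple[list[str], float]] = {
    "ASP": (["OD1", "OD2"], -1.0),
    "GLU": (["OE1", "OE2"], -1.0),
}
C_TERMINAL_ATOM = "OXT"       # acceptor on any residue

# Coarse per-element Lennard-Jones parameters (epsilon, sigma in A).
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "C": (0.086, 3.40),
    "N": (0.170, 3.25),
    "O": (0.210, 2.96),
    "S": (0.250, 3.56),
    "H": (0.015, 2.42),
    "P": (0.200, 3.74),
}


@dataclass
class SasaResult:
    per_atom: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


@dataclass
class SaltBridge:
    donor_chain: str
    donor_seq: int
    donor_resname: str
    donor_atom: str
    acceptor_chain: str
    acceptor_seq: int
    acceptor_resname: str
    acceptor_atom: str
    distance: float


@dataclass
class ClashRecord:
    chain_i: str
    seq_i: int
    atom_i: str
    chain_j: str
    seq_j: int
    atom_j: str
    distance: float
    overlap: float


@dataclass
class InterfaceReport:
    chains_a: tuple[str, ...]
    chains_b: tuple[str, ...]
    bsa: float                 # full-sum convention, A^2
    bsa_half: float            # PISA-style halved value
    salt_bridges: list[SaltBridge] = field(default_factory=list)
    clashes: list[ClashRecord] = field(default_factory=list)
    eelec: float = 0.0
    evdw: float = 0.0

    @property
    def n_salt_bridges(self) -> int:
        return len(self.salt_bridges)

    @property
    def n_clashes(self) -> int:
        return len(self.clashes)


# -- SASA ---------------------------------------------------------------------------


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=np.float64) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def compute_sasa(model: StructureModel, probe_radius: float = DEFAULT_PROBE,
                 n_sphere_points: int = DEFAULT_N_POINTS,
                 include_hydrogens: bool = False) -> SasaResult:
    """Shrake–Rupley SASA with a fixed deterministic sphere point set.

    Per-atom SASA = exposed point fraction x 4 pi (r + probe)^2.  Hydrogens
    are excluded by default (heavy-atom models).
    """
    if n_sphere_points < 24:
        raise ValueError("n_sphere_points must be >= 24")
    work = model if include_hydrogens else model.heavy()
    n = len(work)
    per_atom_work = np.zeros(n)
    if n:
        pts = sphere_points(n_sphere_points)
        radii = work.radii + probe_radius
        coords = work.coords
        tree = cKDTree(coords)
        max_r = radii.max()
        neighbours = tree.query_ball_tree(tree, 2 * max_r)
        for i in range(n):
            ri = radii[i]
            nbr = []
            duplicate_buried = False
            for j in neighbours[i]:
                if j == i:
                    continue
                d2 = np.dot(coords[j] - coords[i], coords[j] - coords[i])
                if d2 < 1e-12:
                    # exact duplicates: count the shared surface once
                    if radii[j] > ri or (radii[j] == ri and j < i):
                        duplicate_buried = True
                        break
                    continue
                if d2 < (ri + radii[j]) ** 2:
                    nbr.append(j)
            if duplicate_buried:
                per_atom_work[i] = 0.0
                continue
            surface = coords[i] + ri * pts
            if nbr:
                d2 = np.sum((surface[:, None, :] - coords[nbr][None, :, :]) ** 2,
                            axis=2)
                exposed = np.all(d2 > (radii[nbr] ** 2)[None, :], axis=1)
                frac = exposed.mean()
            else:
                frac = 1.0
            per_atom_work[i] = frac * 4.0 * np.pi * ri ** 2
    if include_hydrogens or len(work) == len(model):
        per_atom = per_atom_work
    else:
        per_atom = np.zeros(len(model))
        per_atom[model.elements != "H"] = per_atom_work
    return SasaResult(per_atom, probe_radius, n_sphere_points)


def _split(model: StructureModel, chains_a, chains_b
           ) -> tuple[StructureModel, StructureModel]:
    chains_a = tuple(chains_a) if not isinstance(chains_a, str) else (chains_a,)
    chains_b = tuple(chains_b) if not isinstance(chains_b, str) else (chains_b,)
    if not chains_a or not chains_b:
        raise ValueError("empty chain set")
    if set(chains_a) & set(chains_b):
        raise ValueError("chain sets must be disjoint")
    a = model.subset(np.isin(model.chain_ids, chains_a))
    b = model.subset(np.isin(model.chain_ids, chains_b))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a chain set selected no atoms")
    return a, b


def buried_surface_area(model: StructureModel, chains_a, chains_b,
                        probe_radius: float = DEFAULT_PROBE,
                        n_sphere_points: int = DEFAULT_N_POINTS) -> float:
    """BSA = SASA(A alone) + SASA(B alone) - SASA(A u B), full-sum convention.

    Clipped at zero (with a warning) if numerically negative.
    """
    a, b = _split(model, chains_a, chains_b)
    # union in source atom order, so BSA(A,B) == BSA(B,A) bitwise
    both = np.isin(model.chain_ids, list(a.chains) + list(b.chains))
    ab = model.subset(both)
    sasa_a = compute_sasa(a, probe_radius, n_sphere_points).total
    sasa_b = compute_sasa(b, probe_radius, n_sphere_points).total
    sasa_ab = compute_sasa(ab, probe_radius, n_sphere_points).total
    bsa = min(sasa_a, sasa_b) + max(sasa_a, sasa_b) - sasa_ab
    if bsa < 0:
        if bsa < -1e-6:
            warnings.warn(f"negative BSA {bsa:.3g} clipped to 0")
        bsa = 0.0
    return float(bsa)


# -- salt bridges -------------------------------------------------------------------


def _charged_groups(model: StructureModel, which: str):
    """Yield (chain, seq, resname, atom_names, positions, charge) groups."""
    table = DONOR_GROUPS if which == "donor" else ACCEPTOR_GROUPS
    keys: dict[tuple[str, int, str], list[int]] = {}
    for i in range(len(model)):
        rname = str(model.residue_names[i]).upper()
        aname = str(model.atom_names[i]).upper()
        hit = False
        if rname in table and aname in table[rname][0]:
            hit = True
        if which == "acceptor" and aname == C_TERMINAL_ATOM:
            hit = True
        if hit:
            keys.setdefault(
                (str(model.chain_ids[i]), int(model.residue_seqs[i]), rname),
                []).append(i)
    for (chain, seq, rname), idx in sorted(keys.items()):
        charge = (table[rname][1] if rname in table
                  else (-1.0 if which == "acceptor" else +1.0))
        yield chain, seq, rname, idx, charge


def detect_salt_bridges(model: StructureModel, chains_a, chains_b,
                        cutoff: float = SALT_BRIDGE_CUTOFF) -> list[SaltBridge]:
    """Donor–acceptor pairs across the partition within the distance cutoff.

    Donors: Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 (protonated); acceptors:
    Asp OD1/OD2, Glu OE1/OE2, C-terminal OXT.  One record per residue pair
    (minimum distance kept).  Nonstandard residues are simply not matched.
    """
    a, b = _split(model, chains_a, chains_b)
    best: dict[tuple, SaltBridge] = {}
    for donors, acceptors in ((a, b), (b, a)):
        for dch, dseq, drn, didx, _ in _charged_groups(donors, "donor"):
            for ach, aseq, arn, aidx, _ in _charged_groups(acceptors, "acceptor"):
                dpos = donors.coords[didx]
                apos = acceptors.coords[aidx]
                D = np.linalg.norm(dpos[:, None, :] - apos[None, :, :], axis=2)
                k = np.unravel_index(np.argmin(D), D.shape)
                if D[k] <= cutoff:
                    key = (dch, dseq, ach, aseq)
                    sb = SaltBridge(
                        dch, dseq, drn, str(donors.atom_names[didx[k[0]]]),
                        ach, aseq, arn, str(acceptors.atom_names[aidx[k[1]]]),
                        float(D[k]))
                    if key not in best or sb.distance < best[key].distance:
                        best[key] = sb
    return [best[k] for k in sorted(best)]


# -- clashes ------------------------------------------------------------------------


def count_clashes(model: StructureModel, chains_a, chains_b,
                  overlap_threshold: float = CLASH_OVERLAP
                  ) -> tuple[int, list[ClashRecord]]:
    """Cross-partition heavy-atom pairs with vdW overlap above the threshold.

    overlap = r_i + r_j - distance.  Neighbour-list accelerated,
    deterministic ordering.
    """
    a, b = _split(model, chains_a, chains_b)
    a, b = a.heavy(), b.heavy()
    records: list[ClashRecord] = []
    if len(a) and len(b):
        max_sum = a.radii.max() + b.radii.max()
        tree_b = cKDTree(b.coords)
        pairs = cKDTree(a.coords).query_ball_tree(tree_b, max_sum)
        for i, js in enumerate(pairs):
            for j in js:
                dist = float(np.linalg.norm(a.coords[i] - b.coords[j]))
                overlap = float(a.radii[i] + b.radii[j] - dist)
                if overlap > overlap_threshold:
                    records.append(ClashRecord(
                        str(a.chain_ids[i]), int(a.residue_seqs[i]),
                        str(a.atom_names[i]),
                        str(b.chain_ids[j]), int(b.residue_seqs[j]),
                        str(b.atom_names[j]), dist, overlap))
    records.sort(key=lambda r: (r.chain_i, r.seq_i, r.atom_i,
                                r.chain_j, r.seq_j, r.atom_j))
    return len(records), records


# -- nonbonded score ----------------------------------------------------------------


def _switch(r: np.ndarray, r_on: float, r_c: float) -> np.ndarray:
    """CHARMM-style cubic switching function on r^2: 1 below r_on, 0 above r_c."""
    r2, on2, c2 = r ** 2, r_on ** 2, r_c ** 2
    s = ((c2 - r2) ** 2 * (c2 + 2 * r2 - 3 * on2)) / (c2 - on2) ** 3
    return np.where(r <= r_on, 1.0, np.where(r >= r_c, 0.0, s))


def nonbonded_score(model: StructureModel, chains_a, chains_b,
                    cutoff: float = NB_CUTOFF,
                    switch_on: float = NB_SWITCH_ON
                    ) -> tuple[float, float]:
    """Simplified cutoff nonbonded interface score: (eelec, evdw).

    Eelec sums shifted Coulomb terms q_i q_j / r * (1 - (r/r_c)^2)^2 over
    formal-charge group centroids (vanishes exactly at the cutoff); Evdw
    sums element-wise Lennard-Jones terms under a cubic switching function
    between switch_on and cutoff.  Units are arbitrary (comparator only).
    """
    a, b = _split(model, chains_a, chains_b)

    def groups(m):
        cents, qs = [], []
        for which in ("donor", "acceptor"):
            for _, _, _, idx, charge in _charged_groups(m, which):
                cents.append(m.coords[idx].mean(axis=0))
                qs.append(charge)
        return (np.array(cents).reshape(-1, 3), np.array(qs))

    ca, qa = groups(a)
    cb, qb = groups(b)
    eelec = 0.0
    if len(qa) and len(qb):
        D = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
        with np.errstate(divide="ignore"):
            shift = np.clip(1.0 - (D / cutoff) ** 2, 0.0, None) ** 2
            term = COULOMB_K * np.outer(qa, qb) / D * shift
        term[D > cutoff] = 0.0
        eelec = float(term.sum())

    a_h, b_h = a.heavy(), b.heavy()
    evdw = 0.0
    missing: set[str] = set()
    eps_a, sig_a, ok_a = _lj_arrays(a_h, missing)
    eps_b, sig_b, ok_b = _lj_arrays(b_h, missing)
    if missing:
        warnings.warn(f"no LJ parameters for elements {sorted(missing)}; "
                      "pairs skipped")
    ai = np.flatnonzero(ok_a)
    bi = np.flatnonzero(ok_b)
    if len(ai) and len(bi):
        tree_b = cKDTree(b_h.coords[bi])
        pairs = cKDTree(a_h.coords[ai]).query_ball_tree(tree_b, cutoff)
        for ii, js in enumerate(pairs):
            if not js:
                continue
            js = np.asarray(js)
            r = np.linalg.norm(b_h.coords[bi[js]] - a_h.coords[ai[ii]], axis=1)
            eps = np.sqrt(eps_a[ai[ii]] * eps_b[bi[js]])
            sig = 0.5 * (sig_a[ai[ii]] + sig_b[bi[js]])
            sr6 = (sig / r) ** 6
            lj = 4.0 * eps * (sr6 ** 2 - sr6)
            evdw += float(np.sum(lj * _switch(r, switch_on, cutoff)))
    return eelec, evdw


def _lj_arrays(m: StructureModel, missing: set[str]):
    eps = np.zeros(len(m))
    sig = np.zeros(len(m))
    ok = np.zeros(len(m), dtype=bool)
    for i, el in enumerate(m.elements):
        p = LJ_PARAMS.get(str(el))
        if p is None:
            missing.add(str(el))
        else:
            eps[i], sig[i] = p
            ok[i] = True
    return eps, sig, ok


# -- aggregate report ---------------------------------------------------------------


def interface_report(model: StructureModel, chains_a, chains_b,
                     probe_radius: float = DEFAULT_PROBE,
                     n_sphere_points: int = DEFAULT_N_POINTS,
                     salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF,
                     clash_overlap: float = CLASH_OVERLAP) -> InterfaceReport:
    """BSA, salt bridges, clashes and nonbonded score for one chain-pair
    interface.  Symmetric under swapping the two chain sets."""
    chains_a = tuple(chains_a) if not isinstance(chains_a, str) else (chains_a,)
    chains_b = tuple(chains_b) if not isinstance(chains_b, str) else (chains_b,)
    bsa = buried_surface_area(model, chains_a, chains_b,
                              probe_radius, n_sphere_points)
    bridges = detect_salt_bridges(model, chains_a, chains_b, salt_bridge_cutoff)
    _, clashes = count_clashes(model, chains_a, chains_b, clash_overlap)
    eelec, evdw = nonbonded_score(model, chains_a, chains_b)
    return InterfaceReport(chains_a, chains_b, bsa, bsa / 2.0,
                           bridges, clashes, eelec, evdw)


def outer_junction_interfaces(model: StructureModel, assignment
                              ) -> dict[str, InterfaceReport]:
    """The six outer-junction interfaces among PFs A10, A11 and B1.

    Pairs the alpha and beta subunits of the first dimer of each PF:
    A10a-A11a, A10b-A11b (canonical lateral), A10a-B1a, A10b-B1b,
    A11a-B1a, A11b-B1b.  Requires alpha/beta labels in the assignment.
    """
    ab = assignment.alpha_beta
    if not ab:
        raise ValueError("alpha/beta labels required for the junction report")

    def subunit(pf: str, which: str) -> str:
        for c in assignment.chains_of_pf[pf]:
            if ab.get(c) == which:
                return c
        raise ValueError(f"PF {pf} has no {which} subunit")

    pairs = [("A10", "A11"), ("A10", "B1"), ("A11", "B1")]
    out: dict[str, InterfaceReport] = {}
    for pf_i, pf_j in pairs:
        for which, tag in (("alpha", "a"), ("beta", "b")):
            name = f"{pf_i}{tag}-{pf_j}{tag}"
            out[name] = interface_report(
                model, subunit(pf_i, which), subunit(pf_j, which))
    return out
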