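"""Protofilament lattice geometry.

Measures the rigid transform between adjacent protofilaments (PFs), decomposes
it into a twist about the microtubule longitudinal axis plus an axial shift,
converts the twist into a theoretical PF number (360 deg / twist), groups
tubulin subunits into PFs, splits A- from B-tubule, and classifies lateral
contacts as B-lattice or seam.

Local lattice curvature is inversely related to the inter-PF rotation angle:
an ideal N-PF microtubule has an inter-PF rotation of 360/N degrees, so the
rotation angle measured between two neighbouring PFs gives the PF number of
the ideal microtubule with the same local curvature ("N-PF-like").

Sign convention: positive twist is counterclockwise viewed from the plus end
(the lattice axis direction points toward the plus end).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.transform import Rotation

from .core_io import StructureModel

__all__ = [
    "RigidTransform",
    "LatticeAxis",
    "PFPairGeometry",
    "PFAssignment",
    "LatticeContact",
    "superpose",
    "kabsch",
    "estimate_axis",
    "twist_about_axis",
    "assign_pfs",
    "pf_pair_geometry",
    "classify_lattice_contacts",
    "lattice_report",
]


@dataclass
class RigidTransform:
    """Proper rotation + translation: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


@dataclass
class LatticeAxis:
    """Microtubule longitudinal axis: unit direction (toward the plus end)
    and a point on the axis."""

    direction: np.ndarray
    point: np.ndarray

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(self.direction)
        if norm == 0:
            raise ValueError("zero axis direction")
        self.direction = self.direction / norm
        self.point = np.asarray(self.point, dtype=np.float64).reshape(3)


@dataclass
class PFPairGeometry:
    pf_i: str
    pf_j: str
    angle_deg: float
    z_shift: float
    axis_deviation_deg: float
    rmsd: float
    reliable: bool = True

    @property
    def theoretical_pf_number(self) -> float:
        return 360.0 / abs(self.angle_deg)

    @property
    def pf_class(self) -> int:
        # round half away from zero
        t = self.theoretical_pf_number
        return int(np.floor(t + 0.5))


@dataclass
class PFAssignment:
    """Grouping of chains into PFs and tubules.

    pf_of_chain maps every chain to a PF label (e.g. 'A10'); chains_of_pf
    lists each PF's chains ordered by axial position; pf_order lists PF
    labels around each tubule; closed flags whether the tubule wall is a
    full ring.
    """

    pf_of_chain: dict[str, str]
    chains_of_pf: dict[str, list[str]]
    pf_order: dict[str, list[str]]          # tubule -> ordered PF labels
    closed: dict[str, bool]                 # tubule -> ring closed?
    axis: LatticeAxis
    alpha_beta: dict[str, str] = field(default_factory=dict)  # chain -> alpha/beta

    @property
    def tubules(self) -> list[str]:
        return list(self.pf_order)

    def adjacent_pairs(self, tubule: str) -> list[tuple[str, str]]:
        labels = self.pf_order[tubule]
        pairs = [(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]
        if self.closed.get(tubule) and len(labels) > 2:
            pairs.append((labels[-1], labels[0]))
        return pairs


@dataclass
class LatticeContact:
    pf_i: str
    pf_j: str
    register: str                 # 'B-lattice' or 'seam'
    alpha_alpha_offset: float     # A, axial offset between alpha subunits


# -- superposition ------------------------------------------------------------------


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired coordinates (Kabsch/SVD).

    Returns the proper transform minimising RMSD and the post-fit RMSD.
    """
    P = np.asarray(mobile, dtype=np.float64)
    Q = np.asarray(target, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired coordinate arrays of shape (n, 3) required")
    if len(P) < 3:
        raise ValueError("need at least 3 paired atoms")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinearity check: rank of the centred cloud
    s_p = np.linalg.svd(P0, compute_uv=False)
    if s_p[1] < 1e-8 * max(s_p[0], 1.0):
        raise ValueError("degenerate (collinear) atom pairing")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def _paired_coords(mobile: StructureModel, target: StructureModel,
                   pairing: str | None):
    if pairing in (None, "order"):
        if len(mobile) != len(target):
            raise ValueError(
                f"order pairing needs equal atom counts "
                f"({len(mobile)} vs {len(target)}); use pairing='key'")
        return mobile.coords, target.coords
    if pairing == "key":
        def keys(m):
            return {(c, int(s), n): i for i, (c, s, n) in enumerate(
                zip(m.chain_ids, m.residue_seqs, m.atom_names))}
        km, kt = keys(mobile), keys(target)
        common = sorted(set(km) & set(kt))
        missing = sorted(set(km) ^ set(kt))
        if not common:
            raise ValueError(f"no matching atoms; unmatched: {missing[:10]}")
        return (mobile.coords[[km[k] for k in common]],
                target.coords[[kt[k] for k in common]])
    raise ValueError(f"unknown pairing mode {pairing!r}")


def superpose(mobile: StructureModel, target: StructureModel,
              pairing: str | None = None) -> tuple[RigidTransform, float]:
    """Superpose mobile onto target.

    pairing: None/'order' pairs atoms by file order (equal counts required);
    'key' pairs by (chain_id, residue_seq, atom_name).
    """
    P, Q = _paired_coords(mobile, target, pairing)
    return kabsch(P, Q)


# -- axis estimation ----------------------------------------------------------------


def estimate_axis(model: StructureModel, min_eigen_ratio: float = 2.0) -> LatticeAxis:
    """Longitudinal axis of a tubulin lattice.

    Estimated from the orientation tensor of nearest-neighbour difference
    vectors between monomer (chain) centroids: within a protofilament the
    nearest neighbour of a monomer is its axial neighbour (40 A monomer
    rise, against ~48 A and more laterally), so the dominant eigenvector of
    those directions is the tube axis.  This stays well-posed for short,
    wide rings where a plain principal-component axis is degenerate (axial
    and lateral variances coincide for a staggered 2-repeat ring).

    The sign is fixed so that the beta -> alpha direction within dimers (plus
    end up) has positive projection, when alpha/beta labels are available in
    the model metadata (``ground_truth`` chain annotations) — otherwise the
    sign is fixed deterministically by the largest absolute component.
    """
    coords = model.coords
    chains = model.chains
    if len(coords) < 9 or len(chains) < 4:
        raise ValueError("selection too small to define a lattice axis "
                         "(need >= 3 PFs or >= 2 axial repeats)")
    centroid = coords.mean(axis=0)
    cents = np.array([coords[model.chain_ids == c].mean(axis=0)
                      for c in chains])
    from scipy.spatial import cKDTree
    _, nn = cKDTree(cents).query(cents, k=2)
    vecs = cents[nn[:, 1]] - cents
    norms = np.linalg.norm(vecs, axis=1)
    vhat = vecs[norms > 1e-9] / norms[norms > 1e-9, None]
    tensor = vhat.T @ vhat / len(vhat)
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    if evals[2] < min_eigen_ratio * max(evals[1], 1e-12):
        raise ValueError("no dominant axial direction among neighbouring "
                         "monomers: use a longer segment")
    direction = evecs[:, 2]

    gt = model.metadata.get("ground_truth")
    labels = model.metadata.get("alpha_beta") or (
        {c: v.get("subunit") for c, v in gt.items()} if gt else None)
    oriented = False
    if labels:
        # mean beta->alpha centroid difference over chains present
        cents = {c: model.chain(c).centroid() for c in model.chains if c in labels}
        alphas = np.array([v for c, v in cents.items() if labels[c] == "alpha"])
        betas = np.array([v for c, v in cents.items() if labels[c] == "beta"])
        if len(alphas) and len(betas):
            v = alphas.mean(axis=0) - betas.mean(axis=0)
            if abs(np.dot(v, direction)) > 1e-9:
                direction = direction * np.sign(np.dot(v, direction))
                oriented = True
    if not oriented:
        k = int(np.argmax(np.abs(direction)))
        direction = direction * np.sign(direction[k])
    return LatticeAxis(direction, centroid)


# -- twist decomposition ------------------------------------------------------------


def twist_about_axis(t: RigidTransform, axis: LatticeAxis
                     ) -> tuple[float, float, float]:
    """Twist–swing decomposition of a rigid transform about a lattice axis.

    Returns (twist_deg, z_shift_A, axis_deviation_deg).  twist is the
    rotation component about axis.direction (swing removed); z_shift is the
    screw translation along the axis referred to axis.point; axis_deviation
    is the acute angle between the transform's own rotation axis and the
    lattice axis.  Rotations below 1e-6 deg report twist 0, deviation 0.
    """
    n = axis.direction
    rot = Rotation.from_matrix(t.rotation)
    quat = rot.as_quat()  # (x, y, z, w)
    v, w = quat[:3], quat[3]
    p = float(np.dot(v, n))
    twist = np.degrees(2.0 * np.arctan2(p, w))
    # map to (-180, 180]
    twist = (twist + 180.0) % 360.0 - 180.0
    if twist == -180.0:
        twist = 180.0
    rotvec = rot.as_rotvec()
    angle = np.degrees(np.linalg.norm(rotvec))
    if angle < 1e-6:
        twist_out, deviation = 0.0, 0.0
    else:
        twist_out = twist
        r_hat = rotvec / np.linalg.norm(rotvec)
        deviation = float(np.degrees(np.arccos(
            np.clip(abs(np.dot(r_hat, n)), -1.0, 1.0))))
    # screw translation along the axis, relative to axis.point
    p0 = axis.point
    z_shift = float(np.dot(n, t.rotation @ p0 + t.translation - p0))
    return float(twist_out), z_shift, deviation


# -- PF assignment ------------------------------------------------------------------


def _planar_coords(coords: np.ndarray, axis: LatticeAxis
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Return (in-plane 2-D coordinates, axial coordinate) about the axis."""
    n = axis.direction
    u = coords - axis.point
    z = u @ n
    planar3 = u - np.outer(z, n)
    # orthonormal basis in the plane
    e1 = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return np.column_stack([planar3 @ e1, planar3 @ e2]), z


def _fit_circle(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) circle fit: returns (center, radius)."""
    A = np.column_stack([2 * xy, np.ones(len(xy))])
    b = (xy ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:2]
    radius = float(np.sqrt(sol[2] + center @ center))
    return center, radius


def _robust_circle(xy: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Consensus circle through the PF centroids: (center, radius, inliers).

    Deterministic RANSAC over all point triples: the circumcircle with the
    most inliers (radial residual < 8 A, an absolute tolerance so oversized
    circles cannot graze many points) wins and is refined by a least-squares
    fit on its inliers.  The inlier ring is the
    closed tubule; outliers form the open arc of the second tubule.
    """
    n = len(xy)
    best_mask = None
    best_key = (-1, np.inf)
    from itertools import combinations
    for i, j, k in combinations(range(n), 3):
        A = np.column_stack([2 * xy[[i, j, k]], np.ones(3)])
        b = (xy[[i, j, k]] ** 2).sum(axis=1)
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        center = sol[:2]
        radius = np.sqrt(max(sol[2] + center @ center, 0.0))
        if not (20.0 < radius < 600.0):
            continue
        resid = np.abs(np.linalg.norm(xy - center, axis=1) - radius)
        mask = resid < 8.0
        key = (int(mask.sum()), float(resid[mask].sum()))
        if key[0] > best_key[0] or (key[0] == best_key[0]
                                    and key[1] < best_key[1]):
            best_key = key
            best_mask = mask
    if best_mask is None or best_mask.sum() < 3:
        center, radius = _fit_circle(xy)
        return center, radius, np.ones(n, dtype=bool)
    center, radius = _fit_circle(xy[best_mask])
    resid = np.abs(np.linalg.norm(xy - center, axis=1) - radius)
    mask = resid < 8.0
    if mask.sum() >= 3:
        center, radius = _fit_circle(xy[mask])
    else:
        mask = best_mask
    return center, radius, mask


def _silhouette(xy: np.ndarray, labels: np.ndarray) -> float:
    from scipy.spatial.distance import cdist
    uniq = np.unique(labels)
    if len(uniq) < 2 or len(uniq) == len(xy):
        return 1.0
    D = cdist(xy, xy)
    scores = []
    for i in range(len(xy)):
        same = labels == labels[i]
        same[i] = False
        if not same.any():
            continue
        a = D[i, same].mean()
        b = min(D[i, labels == lab].mean() for lab in uniq if lab != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores)) if scores else 1.0


def assign_pfs(model: StructureModel, axis: LatticeAxis | None = None,
               cluster_cutoff: float = 15.0,
               silhouette_threshold: float = 0.6) -> PFAssignment:
    """Group chains into PFs and label them around each tubule.

    Chains (tubulin monomers) are clustered into PFs by their in-plane
    centroid position about the lattice axis (single-linkage, cutoff in A).
    A trimmed circle fit separates the closed A-tubule ring from the open
    B-tubule arc.  Labels follow the doublet convention: the B-arc PF at the
    outer junction is B1 and its two A-tubule partners are A10 and A11 (A11
    on the side the B arc extends over); for a singlet, PFs are A1..An from
    an arbitrary deterministic anchor.  PF identity is always derived
    geometrically, never from chain ids.
    """
    if len(model.chains) < 4:
        raise ValueError("need at least 2 tubulin dimers (4 chains)")
    if axis is None:
        axis = estimate_axis(model)
    chains = model.chains
    cents = np.array([model.chain(c).centroid() for c in chains])
    xy, z = _planar_coords(cents, axis)

    if len(chains) > 1:
        Z = linkage(xy, method="single")
        labels = fcluster(Z, t=cluster_cutoff, criterion="distance")
    else:
        labels = np.array([1])
    n_clusters = labels.max()
    if n_clusters > 1 and n_clusters < len(chains):
        sil = _silhouette(xy, labels)
        if sil < silhouette_threshold:
            raise ValueError(
                f"ambiguous PF clustering (silhouette {sil:.2f} < "
                f"{silhouette_threshold}); inspect PF centroid geometry")

    pf_xy = np.array([xy[labels == k].mean(axis=0)
                      for k in range(1, n_clusters + 1)])

    if n_clusters >= 6:
        center, radius, inlier = _robust_circle(pf_xy)
    else:
        center, radius = _fit_circle(pf_xy) if n_clusters >= 3 else (
            pf_xy.mean(axis=0), 1.0)
        inlier = np.ones(n_clusters, dtype=bool)

    def order_ring(indices: np.ndarray, ctr: np.ndarray):
        ang = np.arctan2(pf_xy[indices, 1] - ctr[1], pf_xy[indices, 0] - ctr[0])
        order = indices[np.argsort(ang)]
        ang_sorted = np.sort(ang)
        if len(ang_sorted) > 2:
            gaps = np.diff(np.concatenate([ang_sorted,
                                           [ang_sorted[0] + 2 * np.pi]]))
            closed = gaps.max() < 1.6 * (2 * np.pi / len(indices))
            # rotate ordering so the largest gap is between last and first
            start = (int(np.argmax(gaps)) + 1) % len(order)
            order = np.concatenate([order[start:], order[:start]])
        else:
            closed = False
        return list(order), closed

    a_idx = np.flatnonzero(inlier)
    b_idx = np.flatnonzero(~inlier)
    a_order, a_closed = order_ring(a_idx, center)

    pf_label: dict[int, str] = {}
    pf_order: dict[str, list[str]] = {}
    closed: dict[str, bool] = {}

    if len(b_idx) == 0:
        for rank, k in enumerate(a_order):
            pf_label[k] = f"A{rank + 1}"
        pf_order["A"] = [f"A{r + 1}" for r in range(len(a_order))]
        closed["A"] = a_closed
    else:
        if len(b_idx) >= 3:
            b_center, _ = _fit_circle(pf_xy[b_idx])
        else:
            b_center = pf_xy[b_idx].mean(axis=0)
        b_order, b_closed = order_ring(b_idx, b_center)
        # outer-junction anchor: B1 = arc end nearest the A ring surface
        def dist_to_a(k):
            return abs(np.linalg.norm(pf_xy[k] - center) - radius)
        ends = [b_order[0], b_order[-1]]
        if dist_to_a(ends[1]) < dist_to_a(ends[0]):
            b_order = b_order[::-1]
        b1 = b_order[0]
        # two nearest A PFs are the junction partners A10/A11
        d_a = np.linalg.norm(pf_xy[a_order] - pf_xy[b1], axis=1)
        p_pos, q_pos = np.argsort(d_a)[:2]
        # A11 = partner nearer the next B PF along the arc (B2)
        nxt = b_order[1] if len(b_order) > 1 else b1
        def d(k_pos):
            return np.linalg.norm(pf_xy[a_order[k_pos]] - pf_xy[nxt])
        a11_pos, a10_pos = ((p_pos, q_pos) if d(p_pos) < d(q_pos)
                            else (q_pos, p_pos))
        n_a = len(a_order)
        step = 1 if (a10_pos + 1) % n_a == a11_pos % n_a else -1
        for offset in range(n_a):
            pos = (a10_pos + step * offset) % n_a
            num = (10 + offset - 1) % n_a + 1
            pf_label[a_order[pos]] = f"A{num}"
        pf_order["A"] = [f"A{(10 + off - 1) % n_a + 1}" for off in range(-9, n_a - 9)]
        closed["A"] = a_closed
        for rank, k in enumerate(b_order):
            pf_label[k] = f"B{rank + 1}"
        pf_order["B"] = [f"B{r + 1}" for r in range(len(b_order))]
        closed["B"] = b_closed

    pf_of_chain: dict[str, str] = {}
    chains_of_pf: dict[str, list[str]] = {}
    for i, c in enumerate(chains):
        lab = pf_label[int(labels[i]) - 1]
        pf_of_chain[c] = lab
        chains_of_pf.setdefault(lab, []).append(c)
    for lab, cs in chains_of_pf.items():
        cs.sort(key=lambda c: z[chains.index(c)])

    gt = model.metadata.get("ground_truth")
    alpha_beta = dict(model.metadata.get("alpha_beta", {}))
    if not alpha_beta and gt:
        alpha_beta = {c: v["subunit"] for c, v in gt.items() if "subunit" in v}

    return PFAssignment(pf_of_chain, chains_of_pf, pf_order, closed, axis,
                        alpha_beta)


# -- pair geometry ------------------------------------------------------------------


def _pf_unit(model: StructureModel, assignment: PFAssignment, pf: str,
             n_chains: int = 2, atom_name: str | None = "CA") -> StructureModel:
    """Equivalent-atom unit of a PF: its lowest chains (one dimer by default),
    reduced to CA atoms when present."""
    chains = assignment.chains_of_pf[pf][:n_chains]
    idx = np.flatnonzero(np.isin(model.chain_ids, chains))
    sub = model.subset(idx)
    if atom_name:
        ca = sub.subset(np.asarray([n.upper() == atom_name
                                    for n in sub.atom_names]))
        if len(ca) >= 3:
            return ca
    return sub


def pf_pair_geometry(model: StructureModel, assignment: PFAssignment,
                     pf_i: str, pf_j: str, axis: LatticeAxis | None = None,
                     n_chains: int = 2) -> PFPairGeometry:
    """Rotation angle, axial shift and PF-number class for one adjacent pair.

    The transform mapping pf_i's dimer onto pf_j's is measured by rigid
    superposition and decomposed about the lattice axis; theoretical PF
    number = 360 / |twist|.  A deviation of the transform's rotation axis
    from the lattice axis above 20 deg flags the row unreliable.
    """
    axis = axis or assignment.axis
    tubule = "A" if pf_i.startswith("A") else "B"
    pairs = assignment.adjacent_pairs(tubule)
    if (pf_i, pf_j) not in pairs and (pf_j, pf_i) not in pairs:
        raise ValueError(f"PFs {pf_i},{pf_j} are not adjacent in tubule {tubule}")
    unit_i = _pf_unit(model, assignment, pf_i, n_chains)
    unit_j = _pf_unit(model, assignment, pf_j, n_chains)
    if len(unit_i) == len(unit_j):
        t, rmsd = superpose(unit_i, unit_j)
    else:
        n = min(len(unit_i), len(unit_j))
        t, rmsd = kabsch(unit_i.coords[:n], unit_j.coords[:n])
    twist, z_shift, deviation = twist_about_axis(t, axis)
    if abs(twist) < 1e-12:
        raise ValueError(f"no rotation between PFs {pf_i} and {pf_j}")
    return PFPairGeometry(pf_i, pf_j, twist, z_shift, deviation, rmsd,
                          reliable=deviation <= 20.0)


# -- lattice contacts ----------------------------------------------------------------


def classify_lattice_contacts(model: StructureModel, assignment: PFAssignment,
                              axis: LatticeAxis | None = None
                              ) -> list[LatticeContact]:
    """Classify each adjacent PF pair as B-lattice or seam.

    For every alpha subunit the nearest lateral neighbour (minimal centroid
    distance) in the adjacent PF is found; a pair is B-lattice when alpha
    faces alpha, seam when alpha faces beta.
    """
    axis = axis or assignment.axis
    ab = assignment.alpha_beta
    if not ab:
        raise ValueError("alpha/beta labels missing: provide model metadata "
                         "'alpha_beta' or run density register assignment "
                         "(assign_alpha_beta_register)")
    cents = {c: model.chain(c).centroid() for c in model.chains}
    n = axis.direction
    z = {c: float(np.dot(cents[c], n)) for c in model.chains}

    # dimer rise inferred from within-PF alpha spacing (fallback 80 A)
    rises = []
    for pf, chains in assignment.chains_of_pf.items():
        za = sorted(z[c] for c in chains if ab.get(c) == "alpha")
        rises.extend(np.diff(za))
    rise = float(np.median(rises)) if rises else 80.0
    if not (20.0 < rise < 200.0):
        rise = 80.0

    out: list[LatticeContact] = []
    for tubule in assignment.tubules:
        for pf_i, pf_j in assignment.adjacent_pairs(tubule):
            za_i = [z[c] for c in assignment.chains_of_pf[pf_i]
                    if ab.get(c) == "alpha"]
            za_j = np.array([z[c] for c in assignment.chains_of_pf[pf_j]
                             if ab.get(c) == "alpha"])
            if not za_i or not len(za_j):
                continue
            # alpha->alpha axial offset folded into [-rise/2, rise/2): the
            # lateral register.  Near 0 -> B-lattice (alpha beside alpha);
            # near +/-rise/2 -> seam (alpha beside beta).  Folding makes the
            # classification independent of axial truncation of the wall.
            offs = []
            for zi in za_i:
                d = za_j - zi
                d = (d + rise / 2.0) % rise - rise / 2.0
                offs.append(d[np.argmin(np.abs(d))])
            # vote per subunit: offsets at the +/-rise/2 fold boundary would
            # otherwise cancel in a plain median
            seam = (np.mean([abs(o) > rise / 4.0 for o in offs]) > 0.5)
            offset = float(np.median(np.abs(offs))) * np.sign(np.median(offs))
            out.append(LatticeContact(
                pf_i, pf_j, "seam" if seam else "B-lattice", offset))
    return out


def lattice_report(model: StructureModel, assignment: PFAssignment | None = None,
                   axis: LatticeAxis | None = None) -> pd.DataFrame:
    """Per-adjacent-pair geometry table for both tubules.

    Columns: pf_i, pf_j, angle_deg, z_shift_A, axis_dev_deg, theo_pf_number,
    pf_class, register (when alpha/beta labels are available), rmsd_A.
    """
    if assignment is None:
        assignment = assign_pfs(model, axis)
    axis = axis or assignment.axis
    registers: dict[tuple[str, str], str] = {}
    if assignment.alpha_beta:
        for c in classify_lattice_contacts(model, assignment, axis):
            registers[(c.pf_i, c.pf_j)] = c.register
    rows = []
    for tubule in assignment.tubules:
        for pf_i, pf_j in assignment.adjacent_pairs(tubule):
            g = pf_pair_geometry(model, assignment, pf_i, pf_j, axis)
            rows.append({
                "tubule": tubule, "pf_i": pf_i, "pf_j": pf_j,
                "angle_deg": g.angle_deg, "z_shift_A": g.z_shift,
                "axis_dev_deg": g.axis_deviation_deg,
                "theo_pf_number": g.theoretical_pf_number,
                "pf_class": g.pf_class,
                "register": registers.get((pf_i, pf_j), ""),
                "rmsd_A": g.rmsd, "reliable": g.reliable,
            })
    return pd.DataFrame(rows)


def lattice_summary(report: pd.DataFrame) -> pd.DataFrame:
    """min/max/median pf_class per tubule."""
    return report.groupby("tubule")["pf_class"].agg(["min", "max", "median"])
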