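"""Synthetic tubulin lattices, template monomers and map perturbations.

Generates ideal singlet and doublet microtubule lattices with known twist,
rise and B-lattice stagger from a pseudo-tubulin monomer, records the ground
truth needed to score every downstream analysis, and provides planted
MIP-like densities and reproducible Gaussian noise for difference-map and
register-assignment studies.  No external coordinates are required; a real
tubulin monomer read with core_io can be substituted for the bundled
pseudo-monomer.

Default geometry follows the 8-nm tubulin repeat: monomer rise 40 A, dimer
rise 80 A, per-PF stagger 3 * 40 / n_pf (3-start monomer helix), which for a
closed ring yields the canonical single seam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import DensityGrid, StructureModel

__all__ = [
    "LatticeSpec",
    "JunctionSpec",
    "MipDescriptor",
    "make_template_monomer",
    "build_singlet",
    "build_doublet",
    "plant_mips",
    "add_noise",
]

MONOMER_RISE = 40.0   # A; half the 8-nm dimer repeat
_TEMPLATE_SEED = 715  # fixed: the bundled pseudo-monomer is a constant


@dataclass
class LatticeSpec:
    """Geometry of an ideal lattice.

    twist_deg may be a scalar (uniform) or a per-pair sequence; for a closed
    ring the sequence has n_pf entries (the last closes the ring) and must
    sum to 360.  stagger is the axial offset per PF (B-lattice 3-start by
    default); open_arc limits the wall to the first open_arc PFs.
    """

    n_pf: int = 13
    dimer_rise: float = 80.0
    twist_deg: float | list[float] | None = None
    stagger: float | None = None
    radius: float = 100.0
    n_repeats: int = 2
    open_arc: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_pf < 2:
            raise ValueError("n_pf must be >= 2")
        if self.twist_deg is None:
            self.twist_deg = 360.0 / self.n_pf
        if self.stagger is None:
            self.stagger = 3.0 * (self.dimer_rise / 2.0) / self.n_pf

    @property
    def n_walls(self) -> int:
        return self.open_arc if self.open_arc is not None else self.n_pf

    def twists(self) -> np.ndarray:
        """Per-pair twist list of length n_walls (closed) / n_walls-1 (open)."""
        n_pairs = self.n_walls if self.open_arc is None else self.n_walls - 1
        if np.isscalar(self.twist_deg):
            return np.full(n_pairs, float(self.twist_deg))
        t = np.asarray(self.twist_deg, dtype=np.float64)
        if len(t) != n_pairs:
            raise ValueError(f"need {n_pairs} per-pair twists, got {len(t)}")
        return t

    def placement_angles(self) -> np.ndarray:
        """Cumulative placement angle (deg) of each PF; checks ring closure."""
        t = self.twists()
        if self.open_arc is None:
            total = float(t.sum())
            if abs(total - 360.0) > 1e-6:
                raise ValueError(
                    f"twists sum to {total} deg, not 360: set open_arc for an "
                    "open wall or adjust the twist list")
            return np.concatenate([[0.0], np.cumsum(t[:-1])])
        return np.concatenate([[0.0], np.cumsum(t)])


@dataclass
class JunctionSpec:
    """Attachment of an open B-arc outside a closed A-ring.

    a_pf_pair indexes the two A-ring construction positions the arc sits
    between (0-based); clearance is the radial gap (A) between the A ring
    radius and the closest arc PF centroid; arc_direction +1/-1 picks which
    way the arc wraps.
    """

    a_pf_pair: tuple[int, int] = (9, 10)
    clearance: float = 48.0
    arc_direction: int = 1
    min_contact: float = 2.0


# -- template monomer ----------------------------------------------------------------


def make_template_monomer(kind: str = "alpha", n_atoms: int = 50,
                          seed: int = _TEMPLATE_SEED) -> StructureModel:
    """Bundled coarse pseudo-tubulin monomer: an asymmetric 50-atom blob.

    The blob spans roughly +/-16 A laterally and +/-17 A axially (fits the
    40 A monomer rise), mixes C/N/O/S elements, and is asymmetric so that
    rotation and register recovery are well-posed.  The beta variant
    deterministically displaces a subset of atoms and changes some elements
    so alpha and beta render distinguishably in density.  Local frame:
    +x radial (outward), +z axial (plus end).
    """
    if kind not in ("alpha", "beta"):
        raise ValueError("kind must be 'alpha' or 'beta'")
    rng = np.random.default_rng(seed)
    # anisotropic, deliberately lopsided cloud
    pts = rng.normal(size=(n_atoms, 3)) * np.array([7.0, 7.0, 9.0])
    pts = np.clip(pts, [-15, -15, -17], [15, 15, 17])
    pts[: n_atoms // 3, 0] += 5.0          # break inversion symmetry
    pts[: n_atoms // 5, 2] += 4.0
    elements = rng.choice(["C", "C", "C", "N", "O", "S"], size=n_atoms)
    if kind == "beta":
        sub = rng.choice(n_atoms, size=max(n_atoms // 4, 1), replace=False)
        pts[sub] += rng.normal(scale=4.0, size=(len(sub), 3))
        elements = elements.copy()
        elements[sub[: len(sub) // 2]] = "O"
    pts -= pts.mean(axis=0)
    n_res = max(n_atoms // 5, 1)
    res_name = "PSA" if kind == "alpha" else "PSB"
    return StructureModel(
        chain_ids=["A"] * n_atoms,
        residue_names=[res_name] * n_atoms,
        residue_seqs=[1 + i // ((n_atoms + n_res - 1) // n_res)
                      for i in range(n_atoms)],
        atom_names=[f"C{i % 5 + 1}" for i in range(n_atoms)],
        elements=elements,
        coords=pts,
        metadata={"template_kind": kind},
    )


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_CHAIN_ALPHABET = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                   "abcdefghijklmnopqrstuvwxyz0123456789")


def _chain_id(i: int) -> str:
    n = len(_CHAIN_ALPHABET)
    if i < n:
        return _CHAIN_ALPHABET[i]
    return _CHAIN_ALPHABET[i // n - 1] + _CHAIN_ALPHABET[i % n]


# -- lattice builders ----------------------------------------------------------------


def _place_monomer(template: StructureModel, angle_deg: float, radius: float,
                   z: float) -> np.ndarray:
    R = _rot_z(angle_deg)
    local = template.coords + np.array([radius, 0.0, 0.0])
    return local @ R.T + np.array([0.0, 0.0, z])


def build_singlet(spec: LatticeSpec,
                  template_alpha: StructureModel | None = None,
                  template_beta: StructureModel | None = None,
                  tubule: str = "A",
                  chain_offset: int = 0) -> StructureModel:
    """Build an ideal singlet lattice from the spec.

    PF k sits at the cumulative twist angle, axial offset k * stagger; each
    dimer places beta at the lower axial position and alpha above it
    (beta -> alpha points to the plus end).  Chain metadata records the
    ground-truth tubule/PF/repeat/subunit of every chain.
    """
    template_alpha = template_alpha or make_template_monomer("alpha")
    template_beta = template_beta or make_template_monomer("beta")
    angles = spec.placement_angles()
    monomer_rise = spec.dimer_rise / 2.0
    chain_ids, res_names, res_seqs, names, elements = [], [], [], [], []
    coords = []
    gt: dict[str, dict] = {}
    idx = chain_offset
    for k in range(spec.n_walls):
        for m in range(spec.n_repeats):
            z0 = k * spec.stagger + m * spec.dimer_rise
            for sub, tmpl, dz in (("beta", template_beta, 0.0),
                                  ("alpha", template_alpha, monomer_rise)):
                cid = _chain_id(idx)
                idx += 1
                xyz = _place_monomer(tmpl, angles[k], spec.radius, z0 + dz)
                coords.append(xyz)
                n = len(tmpl)
                chain_ids += [cid] * n
                res_names += list(tmpl.residue_names)
                res_seqs += list(tmpl.residue_seqs)
                names += list(tmpl.atom_names)
                elements += list(tmpl.elements)
                gt[cid] = {"tubule": tubule, "pf": k, "repeat": m,
                           "subunit": sub, "angle_deg": float(angles[k]),
                           "z": z0 + dz}
    model = StructureModel(
        chain_ids, res_names, res_seqs, names, elements,
        np.concatenate(coords),
        metadata={
            "ground_truth": gt,
            "lattice_spec": {
                "n_pf": spec.n_pf, "dimer_rise": spec.dimer_rise,
                "twists": spec.twists().tolist(), "stagger": spec.stagger,
                "radius": spec.radius, "n_repeats": spec.n_repeats,
                "open_arc": spec.open_arc,
            },
            "title": f"synthetic {tubule} lattice",
        },
    )
    return model


def build_doublet(spec_A: LatticeSpec, spec_B: LatticeSpec,
                  junction: JunctionSpec | None = None,
                  template_alpha: StructureModel | None = None,
                  template_beta: StructureModel | None = None
                  ) -> StructureModel:
    """Closed A-ring plus an open B-arc grafted outside it.

    The arc's first PF (ground-truth B1) is placed facing the A ring between
    the two designated A PFs at the stated radial clearance, and the arc
    wraps away from the junction.  Raises if spec_A is open, spec_B closed,
    or the graft produces atom overlaps (increase clearance).
    """
    junction = junction or JunctionSpec()
    if spec_A.open_arc is not None:
        raise ValueError("spec_A must describe a closed ring")
    a_model = build_singlet(spec_A, template_alpha, template_beta, tubule="A")
    if spec_B.open_arc is None or spec_B.open_arc <= 0:
        if spec_B.n_pf == 0 or spec_B.open_arc == 0:
            return a_model
        raise ValueError("spec_B must describe an open arc (set open_arc)")

    n_chains_a = len(a_model.chains)
    b_model = build_singlet(spec_B, template_alpha, template_beta,
                            tubule="B", chain_offset=n_chains_a)

    # radii of the two walls
    r_a, r_b = spec_A.radius, spec_B.radius
    a_angles = spec_A.placement_angles()
    i, j = junction.a_pf_pair
    u_ang = np.radians((a_angles[i] + a_angles[j]) / 2.0)
    if abs(a_angles[i] - a_angles[j]) > 180:
        u_ang += np.pi
    u = np.array([np.cos(u_ang), np.sin(u_ang), 0.0])
    center_b = u * (r_a + r_b + junction.clearance)
    # rotate B so its pf 0 (local +x direction) faces back toward the A axis,
    # then flip the wrap direction if requested
    theta = np.degrees(np.arctan2(-u[1], -u[0]))
    Rz = _rot_z(theta)
    if junction.arc_direction < 0:
        raise ValueError("arc_direction=-1 not supported (a mirror would break "
                         "chirality); build spec_B with negated twists instead")
    new_coords = b_model.coords @ Rz.T + center_b
    b_model = b_model.with_coords(new_coords)

    # graft sanity: closest approach between the walls
    from scipy.spatial import cKDTree
    d, _ = cKDTree(a_model.coords).query(b_model.coords, k=1)
    if d.min() < junction.min_contact:
        raise ValueError(
            f"overlapping atoms at graft (min distance {d.min():.2f} A); "
            "increase junction clearance")

    gt = dict(a_model.metadata["ground_truth"])
    gt.update(b_model.metadata["ground_truth"])
    meta = {
        "ground_truth": gt,
        "lattice_spec_A": a_model.metadata["lattice_spec"],
        "lattice_spec_B": b_model.metadata["lattice_spec"],
        "junction": {"a_pf_pair": list(junction.a_pf_pair),
                     "clearance": junction.clearance},
        "title": "synthetic doublet lattice",
    }
    return StructureModel.concat([a_model, b_model], metadata=meta)


# -- map perturbations ---------------------------------------------------------------


@dataclass
class MipDescriptor:
    """Planted MIP-like density: a Gaussian blob or a cylindrical filament.

    position/end are world coordinates (x, y, z) in A; periodicity (80, 160
    or 480 A, i.e. the 8/16/48-nm repeats) replicates blobs along +z within
    the grid.
    """

    kind: str = "blob"                      # 'blob' or 'filament'
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    amplitude: float = 1.0
    sigma: float = 6.0                      # blob width / filament radius, A
    end: tuple[float, float, float] | None = None   # filament only
    periodicity: float | None = None        # A, blobs only


def _grid_world(grid: DensityGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nz, ny, nx = grid.shape
    zs = grid.origin[2] + grid.voxel_size * np.arange(nz)
    ys = grid.origin[1] + grid.voxel_size * np.arange(ny)
    xs = grid.origin[0] + grid.voxel_size * np.arange(nx)
    return zs, ys, xs


def plant_mips(grid: DensityGrid, descriptors: list[MipDescriptor]
               ) -> tuple[DensityGrid, np.ndarray]:
    """Add planted densities; returns (new grid, ground-truth mask).

    The mask marks voxels where the planted density reaches at least half
    the descriptor amplitude.  Features partially outside the grid are
    clipped with a warning.
    """
    out = grid.copy()
    added = np.zeros(grid.shape, dtype=np.float64)
    mask = np.zeros(grid.shape, dtype=bool)
    zs, ys, xs = _grid_world(grid)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    lo = np.array([xs[0], ys[0], zs[0]])
    hi = np.array([xs[-1], ys[-1], zs[-1]])
    for d in descriptors:
        if d.kind == "blob":
            centers = [np.asarray(d.position, dtype=np.float64)]
            if d.periodicity:
                if d.periodicity not in (80.0, 160.0, 480.0):
                    warnings.warn(f"nonstandard periodicity {d.periodicity} A")
                c0 = centers[0]
                k = 1
                while c0[2] + k * d.periodicity <= hi[2]:
                    centers.append(c0 + [0, 0, k * d.periodicity])
                    k += 1
                k = 1
                while c0[2] - k * d.periodicity >= lo[2]:
                    centers.append(c0 - [0, 0, k * d.periodicity])
                    k += 1
            for c in centers:
                if np.any(c < lo) or np.any(c > hi):
                    warnings.warn("planted blob clipped at grid edge")
                r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
                dens = d.amplitude * np.exp(-r2 / (2 * d.sigma ** 2))
                added += dens
                mask |= dens >= 0.5 * d.amplitude
        elif d.kind == "filament":
            if d.end is None:
                raise ValueError("filament descriptor needs an end point")
            p0 = np.asarray(d.position, dtype=np.float64)
            p1 = np.asarray(d.end, dtype=np.float64)
            if (np.any(p0 < lo) or np.any(p0 > hi) or np.any(p1 < lo)
                    or np.any(p1 > hi)):
                warnings.warn("planted filament clipped at grid edge")
            axis = p1 - p0
            length = np.linalg.norm(axis)
            if length == 0:
                raise ValueError("zero-length filament")
            n = axis / length
            P = np.stack([X - p0[0], Y - p0[1], Z - p0[2]], axis=-1)
            t = P @ n
            perp2 = np.sum(P * P, axis=-1) - t ** 2
            inside = (t >= 0) & (t <= length)
            dens = np.where(inside,
                            d.amplitude * np.exp(-perp2 / (2 * d.sigma ** 2)),
                            0.0)
            added += dens
            mask |= dens >= 0.5 * d.amplitude
        else:
            raise ValueError(f"unknown MIP kind {d.kind!r}")
    out.values = (out.values + added).astype(np.float32)
    return out, mask


def add_noise(grid: DensityGrid, sigma: float, seed: int) -> DensityGrid:
    """Add i.i.d. Gaussian noise (reproducible per seed)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = grid.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        out.values = (out.values
                      + rng.normal(scale=sigma, size=grid.shape)).astype(np.float32)
    return out
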