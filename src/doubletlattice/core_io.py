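"""Coordinate and density-map I/O plus the shared spatial conventions.

All coordinates are in Angstrom.  Structures are stored column-wise in
:class:`StructureModel` (numpy arrays per field, one row per atom), density
maps in :class:`DensityGrid` with values indexed ``(z, y, x)`` and the world
position of voxel ``(i, j, k)`` equal to ``origin + voxel_size * (k, j, i)``.
Parsing and serialisation of PDB/mmCIF and MRC2014 go through gemmi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "DensityGrid",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "element_from_name",
    "read_structure",
    "write_structure",
    "read_map",
    "write_map",
    "select",
    "SelectionError",
]

# Heavy-atom van der Waals radii (Bondi-style), Angstrom.  Unknown elements
# fall back to the carbon radius with a warning.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

# Atomic numbers used as density weights (density_tools).
ATOMIC_NUMBER: dict[str, int] = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}


def element_from_name(name: str) -> str:
    """Infer an element symbol from an atom name (first alphabetic character,
    two-letter symbols recognised for common cases)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return two.capitalize()
    return stripped[0].upper()


def vdw_radius_for(element: str) -> float:
    el = element.capitalize() if len(element) > 1 else element.upper()
    if el in VDW_RADII:
        return VDW_RADII[el]
    warnings.warn(f"unknown element {element!r}: using default vdW radius "
                  f"{DEFAULT_VDW_RADIUS} A")
    return DEFAULT_VDW_RADIUS


@dataclass
class AtomRecord:
    """One atom, as read from a coordinate file."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    vdw_radius: float
    occupancy: float = 1.0
    b_factor: float = 0.0


class StructureModel:
    """Atoms grouped into chains/residues, stored column-wise.

    Selections return sub-models that share the same conventions (order and
    residue numbering preserved verbatim from the source).
    """

    def __init__(
        self,
        chain_ids: Sequence[str],
        residue_names: Sequence[str],
        residue_seqs: Sequence[int],
        atom_names: Sequence[str],
        elements: Sequence[str],
        coords: np.ndarray,
        radii: Sequence[float] | None = None,
        occupancies: Sequence[float] | None = None,
        b_factors: Sequence[float] | None = None,
        serials: Sequence[int] | None = None,
        metadata: dict | None = None,
    ):
        n = len(atom_names)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_seqs = np.asarray(residue_seqs, dtype=np.int64)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.coords = np.asarray(coords, dtype=np.float64).reshape(n, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        if radii is None:
            radii = [vdw_radius_for(e) if e else DEFAULT_VDW_RADIUS
                     for e in self.elements]
        self.radii = np.asarray(radii, dtype=np.float64)
        if np.any(self.radii <= 0):
            raise ValueError("vdW radii must be positive")
        self.occupancies = (np.ones(n) if occupancies is None
                            else np.asarray(occupancies, dtype=np.float64))
        self.b_factors = (np.zeros(n) if b_factors is None
                          else np.asarray(b_factors, dtype=np.float64))
        self.serials = (np.arange(1, n + 1, dtype=np.int64) if serials is None
                        else np.asarray(serials, dtype=np.int64))
        self.metadata: dict = metadata or {}

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atom_names)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serials[i]),
            name=str(self.atom_names[i]),
            element=str(self.elements[i]),
            residue_name=str(self.residue_names[i]),
            residue_seq=int(self.residue_seqs[i]),
            chain_id=str(self.chain_ids[i]),
            position=self.coords[i].copy(),
            vdw_radius=float(self.radii[i]),
            occupancy=float(self.occupancies[i]),
            b_factor=float(self.b_factors[i]),
        )

    @property
    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    @property
    def chain_index(self) -> dict[str, np.ndarray]:
        """chain_id -> integer indices of its atoms (source order)."""
        idx: dict[str, list[int]] = {}
        for i, c in enumerate(self.chain_ids):
            idx.setdefault(c, []).append(i)
        return {c: np.asarray(v, dtype=np.intp) for c, v in idx.items()}

    def subset(self, mask_or_indices) -> "StructureModel":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return StructureModel(
            self.chain_ids[idx], self.residue_names[idx], self.residue_seqs[idx],
            self.atom_names[idx], self.elements[idx], self.coords[idx],
            self.radii[idx], self.occupancies[idx], self.b_factors[idx],
            self.serials[idx], metadata=dict(self.metadata),
        )

    def chain(self, chain_id: str) -> "StructureModel":
        return self.subset(self.chain_ids == chain_id)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def copy(self) -> "StructureModel":
        m = self.subset(np.arange(len(self)))
        return m

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        m = self.copy()
        m.coords = np.asarray(coords, dtype=np.float64).reshape(len(self), 3)
        return m

    @staticmethod
    def concat(models: Iterable["StructureModel"],
               metadata: dict | None = None) -> "StructureModel":
        models = list(models)
        if not models:
            raise ValueError("nothing to concatenate")
        meta: dict = metadata if metadata is not None else {}
        return StructureModel(
            np.concatenate([m.chain_ids for m in models]),
            np.concatenate([m.residue_names for m in models]),
            np.concatenate([m.residue_seqs for m in models]),
            np.concatenate([m.atom_names for m in models]),
            np.concatenate([m.elements for m in models]),
            np.concatenate([m.coords for m in models]),
            np.concatenate([m.radii for m in models]),
            np.concatenate([m.occupancies for m in models]),
            np.concatenate([m.b_factors for m in models]),
            serials=None,
            metadata=meta,
        )

    def heavy(self) -> "StructureModel":
        """Sub-model with hydrogens removed (default for SASA/clash work)."""
        return self.subset(self.elements != "H")


@dataclass
class DensityGrid:
    """3-D scalar field.  values[z, y, x]; world(i,j,k) = origin + voxel*(k,j,i)."""

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_order: str = "zyx"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("density grid must be 3-D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite density values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # (nz, ny, nx)

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Map (i, j, k) = (z, y, x) voxel indices to world (x, y, z) in A."""
        ijk = np.asarray(ijk, dtype=np.float64)
        return self.origin + self.voxel_size * ijk[..., ::-1]

    def voxel_of(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest voxel index (i, j, k) for a world position (x, y, z)."""
        xyz = np.asarray(xyz, dtype=np.float64)
        return np.rint((xyz - self.origin)[..., ::-1] / self.voxel_size).astype(int)

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.values.copy(), self.voxel_size, self.origin.copy())


# -- structure I/O ------------------------------------------------------------------


def _detect_format(path: str | Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # sniff: mmCIF files start with 'data_'
    with open(path, "rb") as fh:
        head = fh.read(64)
    return "mmcif" if head.lstrip().startswith(b"data_") else "pdb"


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Every ATOM/HETATM record becomes one atom; residue numbering is preserved
    verbatim.  vdW radii are assigned from the bundled element table; unknown
    elements get the default radius with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    coor = gemmi.CoorFormat.Pdb if fmt == "pdb" else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=coor)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    chain_ids, res_names, res_seqs = [], [], []
    names, elements, coords = [], [], []
    occs, bfs, serials = [], [], []
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    for ch in st[0]:
        for res in ch:
            for at in res:
                chain_ids.append(ch.name)
                res_names.append(res.name)
                res_seqs.append(res.seqid.num)
                names.append(at.name)
                el = "H" if at.element.is_hydrogen else at.element.name
                if el in ("X", ""):
                    el = element_from_name(at.name)
                elements.append(el)
                coords.append([at.pos.x, at.pos.y, at.pos.z])
                occs.append(at.occ)
                bfs.append(at.b_iso)
                serials.append(at.serial)
    if not names:
        raise ValueError(f"{path}: no atoms found")
    return StructureModel(
        chain_ids, res_names, res_seqs, names, elements,
        np.asarray(coords), None, occs, bfs, serials,
        metadata={"source": str(path), "title": st.name},
    )


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = str(model.metadata.get("title", "doubletlattice"))
    st.cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    cur_chain = None
    cur_res_key = None
    chain_obj = None
    res_obj = None
    serial = 0
    for i in range(len(model)):
        cid = str(model.chain_ids[i])
        if cid != cur_chain:
            chain_obj = gemmi.Chain(cid)
            gm.add_chain(chain_obj)
            chain_obj = gm[-1]
            cur_chain = cid
            cur_res_key = None
        rkey = (int(model.residue_seqs[i]), str(model.residue_names[i]))
        if rkey != cur_res_key:
            res_obj = gemmi.Residue()
            res_obj.name = rkey[1]
            res_obj.seqid = gemmi.SeqId(rkey[0], " ")
            chain_obj.add_residue(res_obj)
            res_obj = chain_obj[-1]
            cur_res_key = rkey
        at = gemmi.Atom()
        at.name = str(model.atom_names[i])
        at.element = gemmi.Element(str(model.elements[i]) or "C")
        x, y, z = model.coords[i]
        at.pos = gemmi.Position(float(x), float(y), float(z))
        at.occ = float(model.occupancies[i])
        at.b_iso = float(model.b_factors[i])
        serial += 1
        at.serial = serial
        res_obj.add_atom(at)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path,
                    format: str = "auto") -> None:
    """Write a model as PDB or mmCIF (auto = by extension).

    Strict-PDB limits (serials > 99,999; wide residue numbers) are handled by
    gemmi's hybrid-36 encoding; a warning is emitted so mmCIF can be preferred.
    """
    if len(model) == 0:
        raise ValueError("refusing to write an empty model")
    path = Path(path)
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = _to_gemmi(model)
    if fmt == "pdb":
        if len(model) > 99999 or model.residue_seqs.max() > 9999 or any(
                len(str(c)) > 2 for c in model.chains):
            warnings.warn("model exceeds strict PDB limits; hybrid-36/mmCIF "
                          "conventions will be used (prefer .cif output)")
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown structure format {fmt!r}")


# -- map I/O ------------------------------------------------------------------------


def read_map(path: str | Path) -> DensityGrid:
    """Read an MRC2014/CCP4 map, normalising axis order to (z, y, x).

    The voxel size comes from the header cell/grid, the origin from the
    ORIGIN fields with fallback to nstart * voxel.  Anisotropic voxels are
    rejected (all maps this package handles are isotropic).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    m = gemmi.read_ccp4_map(str(path))
    nstart = [m.header_i32(w) for w in (5, 6, 7)]  # nxstart, nystart, nzstart
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    sp = m.grid.spacing
    if max(sp) - min(sp) > 1e-4 * max(sp):
        raise ValueError(f"{path}: anisotropic voxels {sp} not supported")
    voxel = float(np.mean(sp))
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=np.float64)
    if np.all(origin == 0.0) and any(nstart):
        origin = voxel * np.asarray(nstart, dtype=np.float64)
    values = np.array(m.grid.array, copy=True)  # (nx, ny, nz) after setup
    values = np.ascontiguousarray(values.transpose(2, 1, 0))  # -> (z, y, x)
    return DensityGrid(values, voxel, origin)


def write_map(grid: DensityGrid, path: str | Path) -> None:
    """Write a DensityGrid as an MRC2014 mode-2 (float32) map."""
    nz, ny, nx = grid.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(g.array)[...] = grid.values.transpose(2, 1, 0)
    v = grid.voxel_size
    g.set_unit_cell(gemmi.UnitCell(nx * v, ny * v, nz * v, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), grid.origin):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


# -- selection mini-language ---------------------------------------------------------


class SelectionError(ValueError):
    """Raised for a malformed selection expression (reports the position)."""


def _parse_int_list(spec: str, clause_pos: int) -> list[int]:
    out: list[int] = []
    for part in spec.split(","):
        part = part.strip()
        if "-" in part[1:]:  # allow negative start
            lo, _, hi = part.rpartition("-")
            try:
                lo_i, hi_i = int(lo), int(hi)
            except ValueError:
                raise SelectionError(
                    f"bad residue range {part!r} at position {clause_pos}")
            out.extend(range(lo_i, hi_i + 1))
        else:
            try:
                out.append(int(part))
            except ValueError:
                raise SelectionError(
                    f"bad residue number {part!r} at position {clause_pos}")
    return out


def select(model: StructureModel, expr: str) -> StructureModel:
    """Select a sub-model with a small expression language.

    Clauses joined by ``and``: ``all``, ``chain A,B``, ``resi 56-60,70``,
    ``name CA,CB``, ``element C,N``.  Empty selections are allowed.
    """
    mask = np.ones(len(model), dtype=bool)
    expr = expr.strip()
    if not expr:
        raise SelectionError("empty selection expression at position 0")
    pos = 0
    for clause in expr.split(" and "):
        clause_pos = pos
        pos += len(clause) + len(" and ")
        tokens = clause.strip().split(None, 1)
        if not tokens:
            raise SelectionError(f"empty clause at position {clause_pos}")
        key = tokens[0].lower()
        if key == "all":
            continue
        if len(tokens) != 2:
            raise SelectionError(
                f"clause {key!r} needs an argument at position {clause_pos}")
        arg = tokens[1].strip()
        if key == "chain":
            wanted = {c.strip() for c in arg.split(",")}
            mask &= np.isin(model.chain_ids, list(wanted))
        elif key == "resi":
            wanted_i = _parse_int_list(arg, clause_pos)
            mask &= np.isin(model.residue_seqs, wanted_i)
        elif key == "name":
            wanted = {c.strip().upper() for c in arg.split(",")}
            mask &= np.isin([n.upper() for n in model.atom_names], list(wanted))
        elif key == "element":
            wanted = {c.strip().capitalize() for c in arg.split(",")}
            mask &= np.isin(
                [e.capitalize() for e in model.elements], list(wanted))
        else:
            raise SelectionError(
                f"unknown selection keyword {key!r} at position {clause_pos}")
    return model.subset(mask)
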