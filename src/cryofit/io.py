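"""Density map and atomic model I/O.

Establishes the package-wide coordinate convention:

* positions are in Angstrom (Å);
* ``DensityMap.grid`` is indexed ``grid[ix, iy, iz]`` with x the first
  (slowest-varying numpy) axis, normalized regardless of the axis
  permutation recorded in an MRC header;
* voxel *centers* carry the density value, and ``origin`` is the Å
  position of the center of voxel ``(0, 0, 0)``, so voxel index ``v``
  maps to Å position ``origin + v * voxel_size``.

Every downstream module (simulation, scoring, refinement, segmentation)
uses this mapping and nothing else.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "AtomicModel",
    "DensityMap",
    "MapFormatError",
    "ModelFormatError",
    "read_map",
    "write_map",
    "read_model",
    "write_model",
]


class MapFormatError(ValueError):
    """Raised when a density-map file cannot be interpreted."""


class ModelFormatError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass(frozen=True)
class DensityMap:
    """A 3-D voxel grid of intensities with physical geometry.

    Parameters
    ----------
    grid
        Float array indexed ``[ix, iy, iz]``.
    voxel_size
        Å per voxel along (x, y, z).
    origin
        Å position of the center of voxel (0, 0, 0).
    resolution
        Nominal resolution in Å, or ``None`` when unknown.
    """

    grid: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    resolution: float | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.ndim != 3 or min(grid.shape) < 1:
            raise ValueError("grid must be a 3-D array with all dims >= 1")
        vs = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        if np.any(vs <= 0):
            raise ValueError("voxel_size components must be positive")
        org = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when set")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "origin", org)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """Å coordinates of voxel centers along one axis."""
        n = self.grid.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    def index_to_position(self, index: Sequence[float]) -> np.ndarray:
        """Map a (fractional) voxel index to its Å position."""
        return self.origin + np.asarray(index, dtype=float) * self.voxel_size

    def position_to_index(self, position: Sequence[float]) -> np.ndarray:
        """Map an Å position to fractional voxel index coordinates."""
        return (np.asarray(position, dtype=float) - self.origin) / self.voxel_size

    def with_grid(self, grid: np.ndarray) -> "DensityMap":
        """New map sharing this geometry with different voxel values."""
        return replace(self, grid=np.asarray(grid, dtype=np.float64))

    def same_geometry(self, other: "DensityMap", atol: float = 1e-6) -> bool:
        return (
            self.grid.shape == other.grid.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass(frozen=True)
class Atom:
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite position for atom {self.key}")
        object.__setattr__(self, "position", pos)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)

    @property
    def atomic_number(self) -> int:
        return gemmi.Element(self.element).atomic_number


class AtomicModel:
    """An ordered collection of atoms with chain/residue identity.

    Atom keys ``(chain_id, residue_number, atom_name)`` are unique and
    residues within a chain appear in non-decreasing residue-number
    order.
    """

    def __init__(self, atoms: Iterable[Atom]):
        self.atoms: list[Atom] = list(atoms)
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom key {a.key}")
            seen.add(a.key)
        self._check_residue_order()

    def _check_residue_order(self) -> None:
        last: dict[str, int] = {}
        for a in self.atoms:
            prev = last.get(a.chain_id)
            if prev is not None and a.residue_number < prev:
                raise ValueError(
                    f"residue order not monotone in chain {a.chain_id!r}: "
                    f"{a.residue_number} after {prev}"
                )
            last[a.chain_id] = a.residue_number

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) Å coordinate array in atom order."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.position for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "AtomicModel":
        """Same atoms with replaced coordinates (in atom order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        return AtomicModel(
            replace(a, position=coords[i]) for i, a in enumerate(self.atoms)
        )

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def chain(self, chain_id: str) -> "AtomicModel":
        atoms = [a for a in self.atoms if a.chain_id == chain_id]
        if not atoms:
            raise KeyError(f"chain {chain_id!r} not in model")
        return AtomicModel(atoms)

    def residues(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_number) pairs."""
        out: list[tuple[str, int]] = []
        for a in self.atoms:
            rid = (a.chain_id, a.residue_number)
            if not out or out[-1] != rid:
                if rid in out:
                    continue
                out.append(rid)
        return out

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]

    def atom_index(self) -> dict[tuple[str, int, str], int]:
        return {a.key: i for i, a in enumerate(self.atoms)}


# ---------------------------------------------------------------------------
# Map I/O (MRC/CCP4 2014, mode 2)
# ---------------------------------------------------------------------------

def read_map(path: str | Path, resolution: float | None = None) -> DensityMap:
    """Read an MRC/CCP4 density map.

    Axis order is normalized to the internal x-first convention
    regardless of the MAPC/MAPR/MAPS permutation in the header. The
    origin honours the ORIGIN header record when nonzero, and falls
    back to NXSTART/NYSTART/NZSTART offsets otherwise.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read map {path}: {exc}") from exc
    # normalize axis permutation without resampling
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = np.array(m.grid, copy=True, dtype=np.float64)
    cell = m.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise MapFormatError(
            f"non-orthogonal map cell not supported: {cell}"
        )
    voxel_size = np.array(
        [cell.a / grid.shape[0], cell.b / grid.shape[1], cell.c / grid.shape[2]]
    )
    hdr_origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    if np.any(hdr_origin != 0):
        origin = hdr_origin
    else:
        nstart = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = nstart * voxel_size
    return DensityMap(grid, voxel_size, origin, resolution=resolution)


def write_map(density_map: DensityMap, path: str | Path) -> None:
    """Write a density map as a standard MRC file (mode 2, float32)."""
    path = Path(path)
    grid = np.ascontiguousarray(density_map.grid, dtype=np.float32)
    g = gemmi.FloatGrid(grid)
    nx, ny, nz = grid.shape
    vs = density_map.voxel_size
    g.unit_cell = gemmi.UnitCell(nx * vs[0], ny * vs[1], nz * vs[2], 90, 90, 90)
    g.spacegroup = gemmi.SpaceGroup("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, value in zip((50, 51, 52), density_map.origin):
        m.set_header_float(w, float(value))
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write map to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Model I/O (PDB)
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_model(path: str | Path, protein_only: bool = False) -> AtomicModel:
    """Read a PDB coordinate file into an :class:`AtomicModel`.

    Alternate locations are resolved by keeping the highest-occupancy
    conformer (ties broken toward altloc ``'A'``, i.e. the earliest
    label). Insertion codes are ignored. Duplicate atom keys after
    altloc resolution keep the first occurrence with a warning.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ModelFormatError(f"cannot read model {path}: {exc}") from exc
    if len(st) == 0:
        raise ModelFormatError(f"no models in {path}")
    st.setup_entities()
    atoms: list[Atom] = []
    seen: dict[tuple[str, int, str], int] = {}
    for chain in st[0]:
        for res in chain:
            if protein_only and (
                res.name in _WATER_NAMES or res.het_flag == "H"
            ):
                continue
            # altloc resolution: best occupancy, ties to earliest altloc
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                cur = by_name.get(at.name)
                if cur is None or _altloc_pref(at) > _altloc_pref(cur):
                    by_name[at.name] = at
            for at in by_name.values():
                key = (chain.name, res.seqid.num, at.name)
                if key in seen:
                    warnings.warn(
                        f"duplicate atom {key} in {path}; keeping first",
                        stacklevel=2,
                    )
                    continue
                seen[key] = len(atoms)
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        atom_name=at.name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                        b_factor=at.b_iso,
                    )
                )
    if not atoms:
        raise ModelFormatError(f"no atoms parsed from {path}")
    return AtomicModel(atoms)


def _altloc_pref(at: gemmi.Atom) -> tuple[float, int]:
    """Higher is better: occupancy first, then earlier altloc letter."""
    return (at.occ, -ord(at.altloc) if at.altloc else 0)


def write_model(model: AtomicModel, path: str | Path) -> None:
    """Write an :class:`AtomicModel` as a PDB file."""
    st = gemmi.Structure()
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    for chain_id in model.chain_ids:
        ch = gemmi.Chain(chain_id)
        for _, resnum in AtomicModel(
            a for a in model if a.chain_id == chain_id
        ).residues():
            res_atoms = model.residue_atoms(chain_id, resnum)
            res = gemmi.Residue()
            res.name = res_atoms[0].residue_name
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "A"
            for a in res_atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.position)
                at.occ = a.occupancy
                at.b_iso = a.b_factor
                res.add_atom(at)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))
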