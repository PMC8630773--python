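"""Per-residue goodness-of-fit scores.

SMOC (segment-based Manders overlap coefficient) slides a window of
residues along each chain; for the window centered on residue *r* it
collects the voxels within a sphere radius of any window atom and
evaluates the Manders overlap ``sum(A*B)/sqrt(sum(A^2) sum(B^2))``
between the experimental and model-derived densities on that voxel
set, yielding one value per residue.

The EMRinger-style statistic sweeps the C-gamma atom of unbranched
side chains around the C-alpha–C-beta axis, records the chi1 angle at
which the interpolated map density peaks, and scores how strongly the
peak angles concentrate at the rotameric chi1 positions (60, 180,
300 degrees) via a binomial Z-statistic maximized over density
thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import dihedral, place_internal
from .io import AtomicModel, DensityMap
from .global_scores import interpolate_density
from .simulate import SimulationParams, simulate_map

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueProfile",
    "smoc_profile",
    "default_smoc_radius",
    "emringer_like",
    "EMRINGER_ELIGIBLE",
]

#: Residue types whose C-gamma is unbranched at C-beta (chi1-defining).
EMRINGER_ELIGIBLE = {"GLN", "GLU", "LYS", "ARG", "MET", "LEU", "TRP", "PHE", "TYR", "HIS", "ASP", "ASN", "PRO"}

ROTAMERIC_CHI1 = (60.0, 180.0, 300.0)
ROTAMER_TOLERANCE = 30.0  # degrees on each side of a rotameric angle


@dataclass
class ResidueProfile:
    """Per-residue score vector keyed by (chain_id, residue_number)."""

    entries: pd.DataFrame  # columns: chain, resnum, score
    window_size: int | None = None
    sphere_radius: float | None = None

    def __post_init__(self) -> None:
        required = {"chain", "resnum", "score"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"profile needs columns {sorted(required)}")

    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, int, float]],
        window_size: int | None = None,
        sphere_radius: float | None = None,
    ) -> "ResidueProfile":
        df = pd.DataFrame(records, columns=["chain", "resnum", "score"])
        return cls(df, window_size=window_size, sphere_radius=sphere_radius)

    @property
    def scores(self) -> np.ndarray:
        return self.entries["score"].to_numpy()

    def keyed(self) -> pd.Series:
        """Scores indexed by (chain, resnum) for alignment across models."""
        return self.entries.set_index(["chain", "resnum"])["score"]

    def mean(self) -> float:
        return float(np.nanmean(self.scores))

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ResidueProfile":
        return cls(pd.read_csv(path))


def default_smoc_radius(resolution: float) -> float:
    """Default sphere radius (Å) around window atoms."""
    return 3.0 + resolution / 4.0


def _sphere_union_voxels(
    coords: np.ndarray, geometry: DensityMap, radius: float
) -> np.ndarray:
    """Flat indices of voxels whose centers lie within radius of any coord."""
    shape = np.array(geometry.grid.shape)
    vs = geometry.voxel_size
    origin = geometry.origin
    lo = np.maximum(np.floor((coords.min(0) - radius - origin) / vs), 0).astype(int)
    hi = np.minimum(
        np.ceil((coords.max(0) + radius - origin) / vs), shape - 1
    ).astype(int)
    if np.any(lo > hi):
        return np.empty(0, dtype=np.intp)
    axes = [origin[d] + np.arange(lo[d], hi[d] + 1) * vs[d] for d in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    dist, _ = cKDTree(coords).query(
        centers, k=1, distance_upper_bound=radius * (1 + 1e-12)
    )
    inside = dist <= radius
    sub_shape = hi - lo + 1
    sub_idx = np.flatnonzero(inside)
    ii, jj, kk = np.unravel_index(sub_idx, sub_shape)
    return np.ravel_multi_index(
        (ii + lo[0], jj + lo[1], kk + lo[2]), tuple(shape)
    )


def smoc_profile(
    model: AtomicModel,
    map_exp: DensityMap,
    params: SimulationParams,
    window: int = 7,
    radius: float | None = None,
    backbone_only: bool = False,
    map_model: DensityMap | None = None,
) -> ResidueProfile:
    """Sliding-window Manders overlap per residue.

    The window of up to ``window`` residues centered on each residue
    (truncated at chain termini so every residue receives a value)
    defines a union of atom-centered spheres; the Manders overlap
    between experimental and model-simulated density on those voxels is
    the residue's score. The model-density channel shares ``params``
    with the global scores so the two layers are consistent.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if radius is None:
        radius = default_smoc_radius(params.resolution)
    if map_model is None:
        map_model = simulate_map(model, params, grid_template=map_exp)
    half = window // 2
    backbone_names = {"N", "CA", "C", "O"}

    a_flat = map_exp.grid.ravel()
    b_flat = map_model.grid.ravel()
    records: list[tuple[str, int, float]] = []
    for chain_id in model.chain_ids:
        chain = model.chain(chain_id)
        resnums = [rn for _, rn in chain.residues()]
        by_res = {
            rn: np.array(
                [
                    a.position
                    for a in chain.residue_atoms(chain_id, rn)
                    if not backbone_only or a.atom_name in backbone_names
                ]
            )
            for rn in resnums
        }
        for i, rn in enumerate(resnums):
            window_res = resnums[max(0, i - half) : i + half + 1]
            coords = np.concatenate(
                [by_res[r] for r in window_res if by_res[r].size], axis=0
            ) if any(by_res[r].size for r in window_res) else np.empty((0, 3))
            if coords.size == 0:
                logger.warning("residue %s:%d has no atoms; missing SMOC", chain_id, rn)
                records.append((chain_id, rn, np.nan))
                continue
            sel = _sphere_union_voxels(coords, map_exp, radius)
            if sel.size == 0:
                logger.warning(
                    "empty voxel set for residue %s:%d; missing SMOC", chain_id, rn
                )
                records.append((chain_id, rn, np.nan))
                continue
            a = a_flat[sel]
            b = b_flat[sel]
            denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
            score = float(np.dot(a, b) / denom) if denom > 0 else np.nan
            records.append((chain_id, rn, score))
    return ResidueProfile.from_records(
        records, window_size=window, sphere_radius=radius
    )


# ---------------------------------------------------------------------------
# EMRinger-style chi1 peak statistic
# ---------------------------------------------------------------------------

CB_CG_BOND = 1.52  # Å, idealized
CA_CB_CG_ANGLE = 114.0  # degrees, idealized tetrahedral-ish


def _ring_positions(
    n: np.ndarray, ca: np.ndarray, cb: np.ndarray, angles_deg: np.ndarray
) -> np.ndarray:
    """Candidate C-gamma positions for each chi1 angle in the sweep."""
    return np.array(
        [
            place_internal(n, ca, cb, CB_CG_BOND, CA_CB_CG_ANGLE, ang)
            for ang in angles_deg
        ]
    )


def emringer_like(
    model: AtomicModel,
    map_exp: DensityMap,
    angle_step: float = 5.0,
    thresholds: list[float] | None = None,
) -> tuple[float | None, pd.DataFrame]:
    """Rotameric-peak Z statistic over chi1 ring sweeps.

    For each eligible residue the C-gamma position is swept around the
    C-alpha–C-beta axis; the chi1 angle of maximum interpolated density
    is the residue's peak. For each density threshold, residues whose
    peak density exceeds it contribute to a binomial Z-score of the
    rotameric-peak count against a null probability of 0.5; the
    statistic is the maximum Z over thresholds rescaled by
    ``sqrt(n_scanned / n_at_best_threshold)``.

    Returns ``(score, per_residue_table)``; the score is None when no
    residue exceeds any positive threshold.
    """
    sweep = np.arange(0.0, 360.0, angle_step)
    peaks: list[tuple[str, int, float, float]] = []
    for chain_id, resnum in model.residues():
        atoms = {a.atom_name: a for a in model.residue_atoms(chain_id, resnum)}
        if atoms.get("CA") is None or atoms.get("CB") is None or atoms.get("N") is None:
            continue
        if atoms["CA"].residue_name not in EMRINGER_ELIGIBLE:
            continue
        n, ca, cb = atoms["N"].position, atoms["CA"].position, atoms["CB"].position
        if np.linalg.norm(cb - ca) < 1e-6:
            logger.warning("degenerate CA-CB geometry at %s:%d; skipped", chain_id, resnum)
            continue
        ring = _ring_positions(n, ca, cb, sweep)
        dens = interpolate_density(map_exp, ring)
        k = int(np.argmax(dens))
        peaks.append((chain_id, resnum, float(sweep[k]), float(dens[k])))

    table = pd.DataFrame(
        peaks, columns=["chain", "resnum", "peak_angle", "peak_density"]
    )
    if table.empty:
        logger.warning("no EMRinger-eligible residues")
        return None, table

    peak_angles = table["peak_angle"].to_numpy()
    peak_dens = table["peak_density"].to_numpy()
    rotameric = np.zeros(len(table), dtype=bool)
    for rot in ROTAMERIC_CHI1:
        delta = np.abs((peak_angles - rot + 180.0) % 360.0 - 180.0)
        rotameric |= delta <= ROTAMER_TOLERANCE
    table["rotameric"] = rotameric

    if thresholds is None:
        positive = map_exp.grid[map_exp.grid > 0]
        if positive.size == 0 or not np.any(peak_dens > 0):
            logger.warning("no positive density; EMRinger score undefined")
            return None, table
        thresholds = list(np.quantile(positive, np.linspace(0.0, 0.95, 20)))

    n_scanned = len(table)
    best: float | None = None
    p0 = 0.5
    for thr in thresholds:
        in_set = peak_dens > thr
        n = int(in_set.sum())
        if n == 0:
            continue
        k = int((rotameric & in_set).sum())
        z = (k - p0 * n) / np.sqrt(n * p0 * (1 - p0))
        z_scaled = z * np.sqrt(n_scanned / n)
        if best is None or z_scaled > best:
            best = float(z_scaled)
    if best is None:
        logger.warning("no residues above any threshold; EMRinger score undefined")
    return best, table
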