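"""Global model-to-map goodness-of-fit scores.

Two families of cross-correlation are provided, mirroring the two
conventions in wide use:

* ``ccc`` — the plain product of densities at matching voxels,
  normalized by the map norms (cosine similarity, no mean offset);
* ``real_space_cc`` — Pearson correlation after offsetting each map to
  zero mean, over a selectable voxel subset: the whole box, the N
  highest-valued voxels of the model map ("volume"), the voxels inside
  a molecular mask ("mask"), or the union of the N highest voxels of
  each map ("peaks").

The two whole-map variants are highly correlated but not identical —
they differ exactly in the mean offset. Mutual information and the
atom-inclusion fraction complete the global score set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .io import AtomicModel, DensityMap
from .simulate import SimulationParams, default_mask_radius, molecular_mask, simulate_map

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedScoreError",
    "ccc",
    "real_space_cc",
    "mutual_information",
    "atom_inclusion",
    "interpolate_density",
    "contour_by_volume",
    "score_all",
    "GLOBAL_SCORE_COLUMNS",
]

GLOBAL_SCORE_COLUMNS = [
    "ccc",
    "cc_box",
    "cc_volume",
    "cc_mask",
    "cc_peaks",
    "mutual_information",
    "atom_inclusion",
]


class UndefinedScoreError(ValueError):
    """A score is mathematically undefined for the given inputs."""


def _check_geometry(a: DensityMap, b: DensityMap) -> None:
    if not a.same_geometry(b):
        raise ValueError("maps must share grid geometry")


def ccc(map_exp: DensityMap, map_model: DensityMap) -> float:
    """Cross-correlation as the normalized product of densities.

    ``sum(A*B) / sqrt(sum(A^2) * sum(B^2))`` over all voxels, with no
    mean offset. Symmetric and scale-invariant; lies in [0, 1] for
    non-negative maps.
    """
    _check_geometry(map_exp, map_model)
    a = map_exp.grid.ravel()
    b = map_model.grid.ravel()
    na = float(np.dot(a, a))
    nb = float(np.dot(b, b))
    if na == 0.0 or nb == 0.0:
        raise UndefinedScoreError("ccc undefined for an all-zero map")
    return float(np.dot(a, b) / np.sqrt(na * nb))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = float(np.dot(a, a))
    nb = float(np.dot(b, b))
    if na == 0.0 or nb == 0.0:
        raise UndefinedScoreError("correlation undefined for constant values")
    return float(np.dot(a, b) / np.sqrt(na * nb))


def _top_n_indices(values: np.ndarray, n: int) -> np.ndarray:
    """Flat indices of the n largest values; ties broken by ascending index."""
    order = np.lexsort((np.arange(values.size), -values))
    return order[:n]


def real_space_cc(
    map_exp: DensityMap,
    map_model: DensityMap,
    mode: str = "box",
    model: AtomicModel | None = None,
    mask: np.ndarray | None = None,
    mask_radius: float | None = None,
) -> tuple[float, int]:
    """Mean-offset Pearson correlation over a selected voxel set.

    Modes
    -----
    box
        All voxels.
    volume
        The N highest-valued voxels of the model map, N being the
        voxel count of the molecular mask.
    mask
        Voxels inside the molecular mask (requires ``model`` or a
        precomputed boolean ``mask``).
    peaks
        Union of the N highest voxels of the model map and the N
        highest voxels of the experimental map.

    Returns the correlation and the size of the voxel set used.
    """
    _check_geometry(map_exp, map_model)
    a = map_exp.grid.ravel()
    b = map_model.grid.ravel()

    if mode == "box":
        sel = np.arange(a.size)
    else:
        if mask is None:
            if model is None:
                raise ValueError(f"mode {mode!r} requires a model or mask")
            radius = mask_radius
            if radius is None:
                res = map_exp.resolution or map_model.resolution
                if res is None:
                    raise ValueError("mask radius or map resolution required")
                radius = default_mask_radius(res)
            mask, _ = molecular_mask(model, map_exp, radius)
        n = int(np.asarray(mask, dtype=bool).sum())
        if mode == "mask":
            sel = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
        elif mode == "volume":
            sel = _top_n_indices(b, n)
        elif mode == "peaks":
            sel = np.union1d(_top_n_indices(b, n), _top_n_indices(a, n))
        else:
            raise ValueError(f"unknown mode {mode!r}")

    if sel.size < 2:
        raise ValueError("voxel selection smaller than 2")
    return _pearson(a[sel], b[sel]), int(sel.size)


def mutual_information(
    map_exp: DensityMap, map_model: DensityMap, n_bins: int = 20
) -> float:
    """Mutual information between binned voxel densities, in bits.

    Each map is binned over its own min-max range; MI is computed from
    the joint histogram. Non-negative and symmetric; degenerate
    single-bin histograms give 0.
    """
    _check_geometry(map_exp, map_model)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a = map_exp.grid.ravel()
    b = map_model.grid.ravel()
    if a.min() == a.max() or b.min() == b.max():
        logger.warning("constant map in mutual_information; returning 0")
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=n_bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    outer = np.outer(px, py)
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / outer[nz])))


def interpolate_density(
    density_map: DensityMap, positions: np.ndarray
) -> np.ndarray:
    """Trilinear interpolation of map values at Å positions.

    Positions outside the grid evaluate to 0.
    """
    positions = np.atleast_2d(positions)
    idx = (positions - density_map.origin) / density_map.voxel_size
    return map_coordinates(
        density_map.grid, idx.T, order=1, mode="constant", cval=0.0
    )


def atom_inclusion(
    model: AtomicModel, map_exp: DensityMap, threshold: float
) -> float:
    """Fraction of atoms lying in density at or above a contour threshold.

    Atom density is obtained by trilinear interpolation; atoms outside
    the map bounding box count as excluded.
    """
    if len(model) == 0:
        raise ValueError("atom_inclusion of an empty model")
    values = interpolate_density(map_exp, model.coords)
    return float(np.mean(values >= threshold))


def contour_by_volume(density_map: DensityMap, n_voxels: int) -> float:
    """Density threshold enclosing a volume of ``n_voxels`` voxels.

    The default atom-inclusion contour: the value such that exactly the
    n_voxels highest-valued voxels lie at or above it.
    """
    flat = density_map.grid.ravel()
    n_voxels = int(np.clip(n_voxels, 1, flat.size))
    return float(np.partition(flat, flat.size - n_voxels)[flat.size - n_voxels])


@dataclass
class ScoreParams:
    """Shared configuration for the full global score set."""

    simulation: SimulationParams
    mask_radius: float | None = None
    mi_bins: int = 20
    inclusion_threshold: float | None = None  # None -> contour-by-volume

    @property
    def radius(self) -> float:
        if self.mask_radius is not None:
            return self.mask_radius
        return default_mask_radius(self.simulation.resolution)


def score_model(
    model: AtomicModel, map_exp: DensityMap, params: ScoreParams
) -> dict[str, float]:
    """All global scores for one model against one experimental map."""
    sim = simulate_map(model, params.simulation, grid_template=map_exp)
    mask, n_mask = molecular_mask(model, map_exp, params.radius)
    out: dict[str, float] = {}
    out["ccc"] = ccc(map_exp, sim)
    for mode, col in (
        ("box", "cc_box"),
        ("volume", "cc_volume"),
        ("mask", "cc_mask"),
        ("peaks", "cc_peaks"),
    ):
        out[col], _ = real_space_cc(map_exp, sim, mode=mode, mask=mask)
    out["mutual_information"] = mutual_information(map_exp, sim, params.mi_bins)
    threshold = params.inclusion_threshold
    if threshold is None:
        threshold = contour_by_volume(map_exp, n_mask)
    out["atom_inclusion"] = atom_inclusion(model, map_exp, threshold)
    return out


def score_all(
    models: dict[str, AtomicModel] | list[AtomicModel],
    map_exp: DensityMap,
    params: ScoreParams,
) -> pd.DataFrame:
    """Score table: one row per model, one column per global score.

    Per-model failures are recorded as missing values with a logged
    reason rather than aborting the run.
    """
    if isinstance(models, list):
        models = {f"model_{i:03d}": m for i, m in enumerate(models)}
    if not models:
        raise ValueError("no models to score")
    rows = {}
    for model_id, model in models.items():
        try:
            rows[model_id] = score_model(model, map_exp, params)
        except (ValueError, UndefinedScoreError) as exc:
            logger.warning("scoring failed for %s: %s", model_id, exc)
            rows[model_id] = {c: np.nan for c in GLOBAL_SCORE_COLUMNS}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(columns=GLOBAL_SCORE_COLUMNS)
    table.index.name = "model_id"
    table.attrs["resolution"] = params.simulation.resolution
    return table
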