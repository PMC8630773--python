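"""Density-driven model refinement via a Gaussian-mixture responsibility map.

The atomic model is treated as an isotropic Gaussian mixture with one
component of width sigma per atom. For atom *i* the responsibility at
voxel *v* is

    R_i(v) = G(v - x_i; sigma) / sum_j G(v - x_j; sigma),

and the intensity-weighted expectation of the voxel positions,

    x_i_new = sum_v M(v) R_i(v) pos(v) / sum_v M(v) R_i(v),

moves each atom toward the density it is responsible for (M is the
reference map, clamped to non-negative values). This expectation step
alternates with restraint regularization to maintain stereochemistry,
for a fixed number of macro-cycles (default five).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .global_scores import ccc
from .io import AtomicModel, DensityMap
from .restraints import MinimizerHook, Topology, build_topology, regularize, stereo_report
from .simulate import SimulationParams, simulate_map

logger = logging.getLogger(__name__)

__all__ = ["RefinementConfig", "RefinementTrace", "responsibility_update", "refine"]


@dataclass(frozen=True)
class RefinementConfig:
    """Parameters of the responsibility-map refinement.

    ``sigma`` is the Gaussian width of the atom mixture in Å; when
    None it defaults to ``map resolution / pi``. ``kernel_cutoff`` is
    in multiples of sigma. ``n_cycles`` macro-cycles alternate the
    expectation step with ``inner_minimization_steps`` of restraint
    minimization. ``em_steps_per_cycle`` repeats the expectation step
    within one macro-cycle.
    """

    sigma: float | None = None
    n_cycles: int = 5
    em_steps_per_cycle: int = 1
    inner_minimization_steps: int = 40
    kernel_cutoff: float = 4.0
    weight_tolerance: float = 1e-12
    divergence_guard: float = 0.05
    w_bond: float = 100.0
    w_angle: float = 20.0
    w_repulsion: float = 10.0
    regularizer_cap: float = 1.0
    hook: MinimizerHook | None = None

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.kernel_cutoff < 2:
            raise ValueError("kernel_cutoff must be >= 2")

    def resolve_sigma(self, map_exp: DensityMap) -> float:
        if self.sigma is not None:
            return self.sigma
        if map_exp.resolution is None:
            raise ValueError("sigma unset and map has no resolution")
        return map_exp.resolution / np.pi


@dataclass
class RefinementTrace:
    """Per-cycle record of fit and geometry during refinement."""

    records: list[dict[str, float]] = field(default_factory=list)

    def append(self, **kwargs: float) -> None:
        self.records.append(dict(kwargs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _gaussian_field_and_update(
    coords: np.ndarray,
    map_exp: DensityMap,
    sigma: float,
    cutoff: float,
    weight_tolerance: float,
) -> np.ndarray:
    """One expectation step: new coordinates for all atoms."""
    shape = np.array(map_exp.grid.shape)
    vs = map_exp.voxel_size
    origin = map_exp.origin
    inv_two_sigma2 = 1.0 / (2.0 * sigma * sigma)
    cut = cutoff * sigma

    density = np.clip(map_exp.grid, 0.0, None)
    clipped_fraction = float(np.mean(map_exp.grid < 0))
    if clipped_fraction > 0:
        logger.debug("clamped %.1f%% negative voxels", 100 * clipped_fraction)

    # denominator field sum_j G_j(v), accumulated per atom on local cubes
    denom = np.zeros(map_exp.grid.shape)
    boxes: list[tuple[np.ndarray, np.ndarray, np.ndarray] | None] = []
    for pos in coords:
        lo = np.maximum(np.ceil((pos - cut - origin) / vs), 0).astype(int)
        hi = np.minimum(np.floor((pos + cut - origin) / vs), shape - 1).astype(int)
        if np.any(lo > hi):
            boxes.append(None)
            continue
        ax = [
            origin[d] + np.arange(lo[d], hi[d] + 1) * vs[d] - pos[d]
            for d in range(3)
        ]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        g = np.exp(-d2 * inv_two_sigma2)
        g[d2 > cut * cut] = 0.0
        denom[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += g
        boxes.append((lo, hi, g))

    new_coords = coords.copy()
    for i, box in enumerate(boxes):
        if box is None:
            logger.debug("atom %d outside map; kept in place", i)
            continue
        lo, hi, g = box
        local_denom = denom[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        local_map = density[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(local_denom > 0, local_map * g / local_denom, 0.0)
        total = w.sum()
        if total <= weight_tolerance:
            logger.debug("atom %d has negligible weight; kept in place", i)
            continue
        axes_pos = [
            origin[d] + np.arange(lo[d], hi[d] + 1) * vs[d] for d in range(3)
        ]
        new_coords[i] = np.array(
            [
                np.sum(w * axes_pos[0][:, None, None]) / total,
                np.sum(w * axes_pos[1][None, :, None]) / total,
                np.sum(w * axes_pos[2][None, None, :]) / total,
            ]
        )
    return new_coords


def responsibility_update(
    model: AtomicModel, map_exp: DensityMap, config: RefinementConfig
) -> AtomicModel:
    """Move every atom to its responsibility-weighted expected position.

    Atoms whose kernels see no map mass keep their position. An
    all-zero map within every kernel yields a no-movement result with
    a warning rather than an error.
    """
    sigma = config.resolve_sigma(map_exp)
    coords = model.coords
    new_coords = _gaussian_field_and_update(
        coords, map_exp, sigma, config.kernel_cutoff, config.weight_tolerance
    )
    if np.allclose(new_coords, coords):
        if not np.any(np.clip(map_exp.grid, 0, None) > 0):
            logger.warning("map carries no positive mass; model unchanged")
    return model.with_coords(new_coords)


def responsibilities_dense(
    model: AtomicModel, map_exp: DensityMap, sigma: float
) -> np.ndarray:
    """Dense per-atom responsibility grids (exact, all atoms, no cutoff).

    Small-instance reference used to validate the neighbor-list
    implementation; shape (n_atoms, *grid.shape).
    """
    axes = [map_exp.voxel_centers_axis(d) for d in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([xx, yy, zz], axis=-1)
    g = np.empty((len(model),) + map_exp.grid.shape)
    for i, a in enumerate(model):
        d2 = np.sum((centers - a.position) ** 2, axis=-1)
        g[i] = np.exp(-d2 / (2 * sigma * sigma))
    denom = g.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, g / denom, 0.0)
    return r


def refine(
    model: AtomicModel,
    map_exp: DensityMap,
    config: RefinementConfig | None = None,
    sim_params: SimulationParams | None = None,
) -> tuple[AtomicModel, RefinementTrace]:
    """Alternate expectation updates with regularization for n_cycles.

    Returns the refined model and a per-cycle trace of fit (ccc of the
    model-derived map to the target), atomic displacement, and
    stereochemistry deviations. A cycle whose ccc drops by more than
    the divergence guard stops refinement early and returns the
    best-so-far model.
    """
    if config is None:
        config = RefinementConfig()
    if sim_params is None:
        if map_exp.resolution is None:
            raise ValueError("sim_params required when map has no resolution")
        sim_params = SimulationParams(resolution=map_exp.resolution)

    topology = build_topology(model)
    trace = RefinementTrace()

    def fit(m: AtomicModel) -> float:
        return ccc(map_exp, simulate_map(m, sim_params, grid_template=map_exp))

    current = model
    best = model
    best_ccc = fit(model)
    prev_ccc = best_ccc
    for cycle in range(config.n_cycles):
        before = current.coords
        for _ in range(config.em_steps_per_cycle):
            current = responsibility_update(current, map_exp, config)
        current = regularize(
            current,
            topology,
            max_steps=config.inner_minimization_steps,
            w_bond=config.w_bond,
            w_angle=config.w_angle,
            w_repulsion=config.w_repulsion,
            displacement_cap=config.regularizer_cap,
            hook=config.hook,
        )
        disp = np.linalg.norm(current.coords - before, axis=1)
        geom = stereo_report(current, topology)
        cur_ccc = fit(current)
        trace.append(
            cycle=cycle,
            ccc=cur_ccc,
            mean_displacement=float(disp.mean()),
            max_displacement=float(disp.max()),
            bond_rmsd=geom["bond_rmsd"],
            angle_rmsd=geom["angle_rmsd"],
            clash_count=geom["clash_count"],
        )
        if cur_ccc > best_ccc:
            best, best_ccc = current, cur_ccc
        if cur_ccc < prev_ccc - config.divergence_guard:
            logger.warning(
                "ccc dropped %.4f -> %.4f at cycle %d; early stop",
                prev_ccc,
                cur_ccc,
                cycle,
            )
            return best, trace
        prev_ccc = cur_ccc
    return best, trace
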