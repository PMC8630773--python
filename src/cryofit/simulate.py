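"""Model-derived density maps and molecular masks.

Every correlation score compares the experimental map with a map
computed from the atomic model on the same voxel grid at a stated
resolution. Each atom contributes an isotropic Gaussian whose width is
tied to the resolution by ``sigma = resolution / (2 sqrt(2 ln 2))``
(FWHM equal to the resolution) scaled by a configurable blur factor,
with amplitude proportional to the atomic number and the kernel
truncated at three sigma.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import AtomicModel, DensityMap

logger = logging.getLogger(__name__)

__all__ = ["SimulationParams", "simulate_map", "molecular_mask", "default_mask_radius"]

#: FWHM-to-sigma conversion for a Gaussian.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

KERNEL_CUTOFF_SIGMAS = 3.0


@dataclass(frozen=True)
class SimulationParams:
    """Parameters controlling model-map simulation.

    ``sigma_factor`` multiplies the FWHM-derived Gaussian width; 1.0
    means the kernel FWHM equals the nominal resolution.
    """

    resolution: float
    sigma_factor: float = 1.0
    voxel_size: float = 1.0
    padding: float = 5.0
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.sigma_factor <= 0:
            raise ValueError("sigma_factor must be positive")

    @property
    def sigma(self) -> float:
        """Gaussian width in Å implied by the resolution."""
        return self.resolution * FWHM_TO_SIGMA * self.sigma_factor


def default_mask_radius(resolution: float) -> float:
    """Default molecular-mask radius in Å for a given resolution."""
    return 2.5 + resolution / 2.0


def _grid_geometry(
    model: AtomicModel, params: SimulationParams
) -> tuple[tuple[int, int, int], np.ndarray, np.ndarray]:
    coords = model.coords
    lo = coords.min(axis=0) - params.padding
    hi = coords.max(axis=0) + params.padding
    vs = np.full(3, params.voxel_size, dtype=float)
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / vs[i])) + 1 for i in range(3))
    return shape, vs, lo


def gaussian_sum_grid(
    coords: np.ndarray,
    amplitudes: np.ndarray,
    geometry: DensityMap,
    sigma: float,
    cutoff_sigmas: float = KERNEL_CUTOFF_SIGMAS,
) -> np.ndarray:
    """Sum truncated isotropic Gaussians onto a voxel grid.

    The workhorse for map simulation, refinement kernels and chain
    segmentation. Contributions beyond ``cutoff_sigmas * sigma`` are
    dropped.
    """
    grid = np.zeros(geometry.grid.shape, dtype=np.float64)
    shape = grid.shape
    vs = geometry.voxel_size
    origin = geometry.origin
    cut = cutoff_sigmas * sigma
    inv_two_sigma2 = 1.0 / (2.0 * sigma * sigma)
    for pos, amp in zip(coords, amplitudes):
        lo_idx = np.maximum(np.ceil((pos - cut - origin) / vs), 0).astype(int)
        hi_idx = np.minimum(
            np.floor((pos + cut - origin) / vs), np.array(shape) - 1
        ).astype(int)
        if np.any(lo_idx > hi_idx):
            continue
        ax = [
            origin[d] + np.arange(lo_idx[d], hi_idx[d] + 1) * vs[d] - pos[d]
            for d in range(3)
        ]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        contrib = amp * np.exp(-d2 * inv_two_sigma2)
        contrib[d2 > cut * cut] = 0.0
        grid[
            lo_idx[0] : hi_idx[0] + 1,
            lo_idx[1] : hi_idx[1] + 1,
            lo_idx[2] : hi_idx[2] + 1,
        ] += contrib
    return grid


def simulate_map(
    model: AtomicModel,
    params: SimulationParams,
    grid_template: DensityMap | None = None,
) -> DensityMap:
    """Compute a model-derived density map at the stated resolution.

    When ``grid_template`` is given the map is produced on that exact
    voxel grid (the substrate every correlation score requires);
    otherwise a new grid with ``params.padding`` Å margins is built
    around the model.
    """
    if len(model) == 0:
        raise ValueError("cannot simulate a map from an empty model")
    atoms = [
        a
        for a in model
        if params.include_hydrogens or a.element.upper() != "H"
    ]
    if not atoms:
        raise ValueError("no heavy atoms to simulate")
    coords = np.array([a.position for a in atoms])
    # mass-normalized kernel: each atom integrates to its atomic number,
    # so coarser resolution lowers the peak and widens the half-maximum
    norm = 1.0 / ((2.0 * np.pi) ** 1.5 * params.sigma**3)
    amps = norm * np.array([float(a.atomic_number) for a in atoms])

    if grid_template is None:
        shape, vs, origin = _grid_geometry(model, params)
        geometry = DensityMap(
            np.zeros(shape), vs, origin, resolution=params.resolution
        )
    else:
        geometry = grid_template
        lo = geometry.origin
        hi = geometry.index_to_position(np.array(geometry.shape) - 1)
        inside = np.all((coords >= lo - 3 * params.sigma), axis=1) & np.all(
            coords <= hi + 3 * params.sigma, axis=1
        )
        if not inside.any():
            raise ValueError("model lies entirely outside the template grid")

    grid = gaussian_sum_grid(coords, amps, geometry, params.sigma)
    return DensityMap(
        grid, geometry.voxel_size, geometry.origin, resolution=params.resolution
    )


def molecular_mask(
    model: AtomicModel,
    geometry: DensityMap,
    radius: float,
) -> tuple[np.ndarray, int]:
    """Binary mask of voxels whose centers lie within ``radius`` of any atom.

    Returns the boolean grid and N, the number of voxels inside the
    mask (the voxel count that defines the top-N selections of the
    volume and peaks correlation modes).
    """
    if radius <= 0:
        raise ValueError("mask radius must be positive")
    if len(model) == 0:
        warnings.warn("molecular_mask of empty model is all-false", stacklevel=2)
        return np.zeros(geometry.grid.shape, dtype=bool), 0
    coords = model.coords
    tree = cKDTree(coords)
    shape = geometry.grid.shape
    axes = [geometry.voxel_centers_axis(d) for d in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    dist, _ = tree.query(centers, k=1, distance_upper_bound=radius * (1 + 1e-12))
    mask = (dist <= radius).reshape(shape)
    return mask, int(mask.sum())
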