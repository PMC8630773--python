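"""Synthetic ground truths, simulated "experimental" maps, and model ensembles.

Everything the pipeline needs to be exercised end-to-end without
external data: protein-like multi-chain backbones built from ideal
internal coordinates (helices at 3.6 residues/turn, extended strands,
clash-rejected random-walk loops), simulated maps at a stated nominal
resolution with optional locally degraded (extra-blurred, noisy)
regions standing in for flexible parts of a structure, and ensembles
of perturbed models carrying the three characteristic prediction
error classes: displaced loops, shifted or rotated secondary-structure
elements, and mis-oriented domains.

All randomness flows from a single seed through named sub-streams
(structure, perturbation, noise), so each stage is independently
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import place_internal, rotation_about_axis
from .io import Atom, AtomicModel, DensityMap
from .restraints import build_topology, regularize
from .simulate import SimulationParams, gaussian_sum_grid, simulate_map

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "Perturbation",
    "FixtureSpec",
    "make_toy_structure",
    "perturb_model",
    "simulate_experimental_map",
    "make_ensemble",
]

# Ideal backbone internal coordinates
PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
}
OMEGA = 180.0
N_CA, CA_C, C_O, C_N, CA_CB, CB_CG = 1.458, 1.525, 1.231, 1.329, 1.530, 1.520
# torsion C-N-CA-CB making both N-CA-CB (110.5) and C-CA-CB (110.1)
# exactly match the restraint templates, L-configuration
CB_TORSION = -122.44690915359305

#: residue types used for synthetic chains (all chi1-sweep eligible)
RESIDUE_CYCLE = ("GLN", "GLU", "LEU", "LYS", "MET", "ARG")


@dataclass(frozen=True)
class Segment:
    kind: str  # helix | strand | loop
    length: int

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "strand", "loop"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("segment length must be >= 1")


@dataclass(frozen=True)
class Perturbation:
    """A structural error recipe applied to a residue range."""

    kind: str  # loop_shift | sse_shift | sse_rotate | domain_reorient
    chain_id: str
    start: int
    end: int  # inclusive residue range
    magnitude: float  # Å for shifts, degrees for rotations

    def __post_init__(self) -> None:
        kinds = ("loop_shift", "sse_shift", "sse_rotate", "domain_reorient")
        if self.kind not in kinds:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.end < self.start:
            raise ValueError("empty residue range")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for a synthetic benchmark instance."""

    chains: tuple[tuple[Segment, ...], ...] = (
        (Segment("helix", 12), Segment("loop", 6), Segment("strand", 8)),
    )
    resolution: float = 3.0
    noise_sd: float = 0.05  # fraction of the map peak
    flexible_regions: tuple[tuple[str, int, int], ...] = ()  # (chain, start, end)
    chi1: float = 180.0
    seed: int = 0

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAMS[stream]])
        )


_STREAMS = {"structure": 0, "perturbation": 1, "noise": 2}


# ---------------------------------------------------------------------------
# Structure construction
# ---------------------------------------------------------------------------

def _loop_phi_psi(rng: np.random.Generator) -> tuple[float, float]:
    # coil-like torsions: broad left half of the Ramachandran plane
    return float(rng.uniform(-160.0, -50.0)), float(rng.uniform(-60.0, 160.0))


def _build_chain(
    chain_id: str,
    segments: tuple[Segment, ...],
    chi1: float,
    rng: np.random.Generator,
    max_retries: int = 30,
) -> list[Atom]:
    torsions: list[tuple[float, float]] = []
    kinds: list[str] = []
    for seg in segments:
        for _ in range(seg.length):
            kinds.append(seg.kind)
            torsions.append(PHI_PSI.get(seg.kind, (0.0, 0.0)))

    n_res = len(torsions)
    for attempt in range(max_retries):
        atoms = _extend_backbone(chain_id, kinds, torsions, chi1, rng)
        if atoms is not None:
            return atoms
        logger.debug("chain %s build attempt %d clashed; retrying", chain_id, attempt)
    raise RuntimeError(
        f"could not build a clash-free chain of {n_res} residues "
        f"after {max_retries} retries (seed-dependent geometry)"
    )


def _extend_backbone(
    chain_id: str,
    kinds: list[str],
    torsions: list[tuple[float, float]],
    chi1: float,
    rng: np.random.Generator,
) -> list[Atom] | None:
    atoms: list[Atom] = []
    ca_trace: list[np.ndarray] = []
    # seed atoms of residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([N_CA, 0.0, 0.0])
    c0 = place_internal(
        n0 + np.array([0.0, 1.0, 0.0]), n0, ca0, CA_C, 111.0, 60.0
    )
    prev = {"N": n0, "CA": ca0, "C": c0}
    psi_prev = None
    for i, kind in enumerate(kinds):
        resnum = i + 1
        resname = RESIDUE_CYCLE[i % len(RESIDUE_CYCLE)]
        phi, psi = torsions[i]
        if kind == "loop":
            phi, psi = _loop_phi_psi(rng)
        if i == 0:
            n, ca, c = prev["N"], prev["CA"], prev["C"]
        else:
            n = place_internal(
                prev["N"], prev["CA"], prev["C"], C_N, 116.2, psi_prev
            )
            ca = place_internal(prev["CA"], prev["C"], n, N_CA, 121.7, OMEGA)
            c = place_internal(prev["C"], n, ca, CA_C, 111.0, phi)
        # clash rejection on the CA trace (skip adjacent residues)
        if any(
            np.linalg.norm(ca - other) < 3.2 for other in ca_trace[:-2]
        ):
            return None
        o = place_internal(n, ca, c, C_O, 120.8, psi + 180.0)
        cb = place_internal(c, n, ca, CA_CB, 110.5, CB_TORSION)
        cg = place_internal(n, ca, cb, CB_CG, 114.0, chi1)
        for name, el, pos in (
            ("N", "N", n),
            ("CA", "C", ca),
            ("C", "C", c),
            ("O", "O", o),
            ("CB", "C", cb),
            ("CG", "C", cg),
        ):
            atoms.append(
                Atom(chain_id, resnum, resname, name, el, pos.copy())
            )
        ca_trace.append(ca)
        prev = {"N": n, "CA": ca, "C": c}
        psi_prev = psi
    return atoms


def make_toy_structure(spec: FixtureSpec) -> AtomicModel:
    """Build a deterministic multi-chain protein-like backbone.

    Each chain carries N, CA, C, O plus CB and an unbranched CG (so
    chi1 statistics are computable); chains are laid out side by side
    with clear separation.
    """
    rng = spec.rng("structure")
    chain_ids = [chr(ord("A") + i) for i in range(len(spec.chains))]
    all_atoms: list[Atom] = []
    x_offset = 0.0
    for chain_id, segments in zip(chain_ids, spec.chains):
        atoms = _build_chain(chain_id, segments, spec.chi1, rng)
        coords = np.array([a.position for a in atoms])
        coords -= coords.min(axis=0)  # non-negative local frame
        coords[:, 0] += x_offset
        x_offset = coords[:, 0].max() + 8.0  # >= 8 Å inter-chain gap
        all_atoms.extend(
            replace(a, position=coords[k]) for k, a in enumerate(atoms)
        )
    return AtomicModel(all_atoms)


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def _segment_mask(model: AtomicModel, p: Perturbation) -> np.ndarray:
    return np.array(
        [
            a.chain_id == p.chain_id and p.start <= a.residue_number <= p.end
            for a in model
        ]
    )


def _relax_junction(
    model: AtomicModel, mask: np.ndarray, width: int, p: Perturbation
) -> AtomicModel:
    """Locally regularize residues flanking a rigid perturbation.

    Perturbed atoms are frozen so the stated magnitude is preserved
    exactly; only the flanking residues relax, with a tight movement
    cap, to heal the junction bonds.
    """
    flank = np.array(
        [
            a.chain_id == p.chain_id
            and (
                p.start - width <= a.residue_number < p.start
                or p.end < a.residue_number <= p.end + width
            )
            for a in model
        ]
    )
    if not flank.any():
        return model
    frozen = ~flank
    return regularize(
        model, max_steps=20, displacement_cap=0.15, frozen=frozen
    )


def perturb_model(
    model: AtomicModel, recipe: Perturbation, seed: int = 0
) -> AtomicModel:
    """Apply one structural error class to a model.

    loop_shift: bounded random per-residue displacement (RMS equal to
    the magnitude) of loop residues. sse_shift: rigid translation of
    the residue range by exactly the magnitude. sse_rotate: rigid
    rotation about the segment's principal axis. domain_reorient:
    rigid rotation of the range about a pivot at its first residue's
    CA. Rigid perturbations re-regularize the junction residues only.
    """
    mask = _segment_mask(model, recipe)
    if not mask.any():
        raise ValueError(
            f"residue range {recipe.start}-{recipe.end} not in chain "
            f"{recipe.chain_id!r}"
        )
    chain_res = {rn for _, rn in model.chain(recipe.chain_id).residues()}
    if not set(range(recipe.start, recipe.end + 1)) <= chain_res:
        raise ValueError("perturbation range crosses a chain break")
    if recipe.magnitude == 0:
        return model  # identity: nothing to apply, no junction to heal
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    coords = model.coords.copy()
    seg = coords[mask]

    if recipe.kind == "loop_shift":
        # one random direction per residue, fixed length = magnitude
        resnums = np.array([a.residue_number for a in model])[mask]
        for rn in np.unique(resnums):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords[mask & (np.array([a.residue_number for a in model]) == rn)] += (
                recipe.magnitude * direction
            )
        out = model.with_coords(coords)
    elif recipe.kind == "sse_shift":
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[mask] = seg + recipe.magnitude * direction
        out = model.with_coords(coords)
    elif recipe.kind == "sse_rotate":
        center = seg.mean(axis=0)
        centered = seg - center
        # principal axis of the segment
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        rot = rotation_about_axis(vt[0], recipe.magnitude)
        coords[mask] = centered @ rot.T + center
        out = model.with_coords(coords)
    elif recipe.kind == "domain_reorient":
        idx = model.atom_index()
        pivot_key = (recipe.chain_id, recipe.start, "CA")
        pivot = coords[idx[pivot_key]] if pivot_key in idx else seg[0]
        axis = rng.normal(size=3)
        rot = rotation_about_axis(axis, recipe.magnitude)
        coords[mask] = (seg - pivot) @ rot.T + pivot
        out = model.with_coords(coords)
    else:  # pragma: no cover - guarded by Perturbation validation
        raise ValueError(recipe.kind)

    if recipe.kind in ("sse_shift", "sse_rotate", "domain_reorient"):
        out = _relax_junction(out, mask, width=2, p=recipe)
    return out


# ---------------------------------------------------------------------------
# Simulated experimental maps
# ---------------------------------------------------------------------------

def simulate_experimental_map(
    model: AtomicModel,
    spec: FixtureSpec,
    grid_template: DensityMap | None = None,
) -> DensityMap:
    """Model-derived map with locally degraded regions and noise.

    Atoms inside ``spec.flexible_regions`` are blurred with twice the
    nominal Gaussian width (locally lower resolution); Gaussian noise
    with SD ``noise_sd`` times the map peak is added; the result is
    clamped to non-negative values. With no noise and no flexible
    regions this reduces exactly to the plain simulated map.
    """
    params = SimulationParams(resolution=spec.resolution)
    base = simulate_map(model, params, grid_template=grid_template)
    if spec.flexible_regions:
        flexible = np.array(
            [
                any(
                    a.chain_id == c and lo <= a.residue_number <= hi
                    for (c, lo, hi) in spec.flexible_regions
                )
                for a in model
            ]
        )
        if flexible.any():
            rigid_atoms = [a for a, f in zip(model, flexible) if not f]
            flex_atoms = [a for a, f in zip(model, flexible) if f]
            norm = 1.0 / ((2.0 * np.pi) ** 1.5 * params.sigma**3)
            grid = np.zeros_like(base.grid)
            if rigid_atoms:
                grid += gaussian_sum_grid(
                    np.array([a.position for a in rigid_atoms]),
                    norm * np.array([float(a.atomic_number) for a in rigid_atoms]),
                    base,
                    params.sigma,
                )
            if flex_atoms:
                # mass-preserving 3-D blur at 2x sigma: peak drops 8-fold
                grid += gaussian_sum_grid(
                    np.array([a.position for a in flex_atoms]),
                    norm / 8.0 * np.array([float(a.atomic_number) for a in flex_atoms]),
                    base,
                    2.0 * params.sigma,
                )
            base = base.with_grid(grid)
    if spec.noise_sd > 0:
        rng = spec.rng("noise")
        peak = float(base.grid.max())
        noisy = base.grid + rng.normal(
            scale=spec.noise_sd * peak, size=base.grid.shape
        )
        base = base.with_grid(np.clip(noisy, 0.0, None))
    return base


# ---------------------------------------------------------------------------
# Model ensembles
# ---------------------------------------------------------------------------

def make_ensemble(
    ground_truth: AtomicModel,
    n_models: int,
    seed: int = 0,
    rigid_jitter: float = 0.3,
    flexible_jitter: float = 1.5,
    flexible_regions: tuple[tuple[str, int, int], ...] = (),
) -> list[AtomicModel]:
    """Ensemble of perturbed copies of the ground truth.

    Each model receives smooth residue-correlated coordinate noise:
    RMS ``rigid_jitter`` Å everywhere, ``flexible_jitter`` Å inside
    the designated flexible regions, so the ensemble's per-residue
    coordinate SD is elevated exactly where the map is degraded — the
    statistical structure the variability analysis detects.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    resnums = np.array([a.residue_number for a in ground_truth])
    chain_arr = np.array([a.chain_id for a in ground_truth])
    flexible = np.zeros(len(ground_truth), dtype=bool)
    for c, lo, hi in flexible_regions:
        flexible |= (chain_arr == c) & (resnums >= lo) & (resnums <= hi)
    scale = np.where(flexible, flexible_jitter, rigid_jitter)

    models = []
    for k in range(n_models):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 23, k]))
        coords = ground_truth.coords.copy()
        # residue-level displacement (shared within a residue) keeps bonds intact
        for chain_id in ground_truth.chain_ids:
            chain_mask = chain_arr == chain_id
            for rn in np.unique(resnums[chain_mask]):
                m = chain_mask & (resnums == rn)
                coords[m] += rng.normal(size=3) * scale[m][0] / np.sqrt(3)
        models.append(ground_truth.with_coords(coords))
    return models
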