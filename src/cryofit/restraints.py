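"""Stereochemistry restraints and regularization.

A generic restraint regularizer maintains correct covalent geometry
during density-driven refinement: harmonic bond and angle terms toward
idealized template values per residue type, plus a soft-core repulsion
between non-bonded atom pairs. A hook interface
(:class:`MinimizerHook`) lets callers substitute an external
force-field minimizer.

The same topology and templates back the stereochemistry report used
to track geometry quality across refinement cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .geometry import bond_angle
from .io import AtomicModel

logger = logging.getLogger(__name__)

__all__ = [
    "Topology",
    "build_topology",
    "regularize",
    "stereo_report",
    "MinimizerHook",
]

# Idealized covalent geometry (Å, degrees) for the backbone + CB/CG
# representation used throughout the package.
BOND_TEMPLATES: dict[tuple[str, str], float] = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.530,
    ("CB", "CG"): 1.520,
    ("C", "N+"): 1.329,  # peptide bond to next residue
}

ANGLE_TEMPLATES: dict[tuple[str, str, str], float] = {
    ("N", "CA", "C"): 111.0,
    ("CA", "C", "O"): 120.8,
    ("CA", "C", "N+"): 116.2,
    ("O", "C", "N+"): 123.0,
    ("C", "N+", "CA+"): 121.7,
    ("N", "CA", "CB"): 110.5,
    ("C", "CA", "CB"): 110.1,
    ("CA", "CB", "CG"): 114.0,
}

CONTACT_DISTANCE = 2.5  # Å, soft-core repulsion onset for non-bonded pairs
CLASH_MARGIN = 0.4  # Å below contact distance that counts as a clash


@dataclass
class Topology:
    """Bonded topology with idealized reference values.

    ``bonds``: (i, j, d0) index pairs with target length;
    ``angles``: (i, j, k, theta0) triplets with target angle (degrees);
    ``excluded``: set of atom index pairs excluded from repulsion
    (bonded 1-2 and 1-3 pairs).
    """

    n_atoms: int
    bonds: np.ndarray
    bond_targets: np.ndarray
    angles: np.ndarray
    angle_targets: np.ndarray
    excluded: set[tuple[int, int]]
    chain_codes: np.ndarray  # integer chain label per atom
    resnums: np.ndarray  # residue number per atom


def build_topology(model: AtomicModel) -> Topology:
    """Derive bonds and angles from residue connectivity templates."""
    index = model.atom_index()
    bonds: list[tuple[int, int]] = []
    bond_targets: list[float] = []
    angles: list[tuple[int, int, int]] = []
    angle_targets: list[float] = []

    def get(chain: str, resnum: int, name: str) -> int | None:
        return index.get((chain, resnum, name))

    for chain_id in model.chain_ids:
        resnums = [rn for _, rn in model.chain(chain_id).residues()]
        for pos, rn in enumerate(resnums):
            here = lambda n: get(chain_id, rn, n)  # noqa: E731
            nxt = resnums[pos + 1] if pos + 1 < len(resnums) else None
            # peptide continuity only for consecutive numbering (chain breaks split)
            has_next = nxt is not None and nxt == rn + 1
            for (a, b), d0 in BOND_TEMPLATES.items():
                if b == "N+":
                    if has_next:
                        i, j = here(a), get(chain_id, nxt, "N")
                    else:
                        continue
                else:
                    i, j = here(a), here(b)
                if i is not None and j is not None:
                    bonds.append((i, j))
                    bond_targets.append(d0)
            for (a, b, c), t0 in ANGLE_TEMPLATES.items():
                names = []
                ok = True
                for n in (a, b, c):
                    if n.endswith("+"):
                        if not has_next:
                            ok = False
                            break
                        names.append(get(chain_id, nxt, n[:-1]))
                    else:
                        names.append(here(n))
                if not ok:
                    continue
                i, j, k = names
                if i is not None and j is not None and k is not None:
                    angles.append((i, j, k))
                    angle_targets.append(t0)

    excluded: set[tuple[int, int]] = set()
    for i, j in bonds:
        excluded.add((min(i, j), max(i, j)))
    for i, j, k in angles:
        excluded.add((min(i, k), max(i, k)))
        excluded.add((min(i, j), max(i, j)))
        excluded.add((min(j, k), max(j, k)))

    chain_order = {c: i for i, c in enumerate(model.chain_ids)}
    return Topology(
        n_atoms=len(model),
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
        bond_targets=np.array(bond_targets),
        angles=np.array(angles, dtype=int).reshape(-1, 3),
        angle_targets=np.array(angle_targets),
        excluded=excluded,
        chain_codes=np.array([chain_order[a.chain_id] for a in model]),
        resnums=np.array([a.residue_number for a in model]),
    )


def _restraint_energy_grad(
    x: np.ndarray,
    topo: Topology,
    w_bond: float,
    w_angle: float,
    w_repulsion: float,
    repulsion_pairs: np.ndarray,
) -> tuple[float, np.ndarray]:
    coords = x.reshape(-1, 3)
    energy = 0.0
    grad = np.zeros_like(coords)

    if len(topo.bonds):
        vi = coords[topo.bonds[:, 0]]
        vj = coords[topo.bonds[:, 1]]
        d = vi - vj
        r = np.linalg.norm(d, axis=1)
        dev = r - topo.bond_targets
        energy += w_bond * np.sum(dev**2)
        g = (2 * w_bond * dev / np.maximum(r, 1e-9))[:, None] * d
        np.add.at(grad, topo.bonds[:, 0], g)
        np.add.at(grad, topo.bonds[:, 1], -g)

    if len(topo.angles):
        a = coords[topo.angles[:, 0]]
        b = coords[topo.angles[:, 1]]
        c = coords[topo.angles[:, 2]]
        u = a - b
        v = c - b
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1 + 1e-9, 1 - 1e-9)
        theta = np.arccos(cosang)
        dev = theta - np.deg2rad(topo.angle_targets)
        energy += w_angle * np.sum(dev**2)
        sin_t = np.sqrt(1 - cosang**2)
        pref = (2 * w_angle * dev) / np.maximum(sin_t, 1e-9)
        # d(theta)/da etc. via standard angle gradient
        ga = (pref / nu)[:, None] * (
            (cosang[:, None] * u / nu[:, None]) - v / nv[:, None]
        )
        gc = (pref / nv)[:, None] * (
            (cosang[:, None] * v / nv[:, None]) - u / nu[:, None]
        )
        np.add.at(grad, topo.angles[:, 0], ga)
        np.add.at(grad, topo.angles[:, 2], gc)
        np.add.at(grad, topo.angles[:, 1], -(ga + gc))

    if len(repulsion_pairs):
        pi = coords[repulsion_pairs[:, 0]]
        pj = coords[repulsion_pairs[:, 1]]
        d = pi - pj
        r = np.linalg.norm(d, axis=1)
        close = r < CONTACT_DISTANCE
        if close.any():
            dev = CONTACT_DISTANCE - r[close]
            energy += w_repulsion * np.sum(dev**2)
            g = (-2 * w_repulsion * dev / np.maximum(r[close], 1e-9))[:, None] * d[close]
            np.add.at(grad, repulsion_pairs[close, 0], g)
            np.add.at(grad, repulsion_pairs[close, 1], -g)

    return energy, grad.ravel()


def _repulsion_pairs(coords: np.ndarray, topo: Topology) -> np.ndarray:
    """Non-bonded candidate pairs: different chains or >= 2 residues apart.

    Local geometry (same and adjacent residues) is governed by the bond
    and angle restraints, not by repulsion.
    """
    pairs = cKDTree(coords).query_pairs(CONTACT_DISTANCE, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(-1, 2)
    i, j = pairs[:, 0], pairs[:, 1]
    nonlocal_mask = (topo.chain_codes[i] != topo.chain_codes[j]) | (
        np.abs(topo.resnums[i] - topo.resnums[j]) >= 2
    )
    keep = [
        (a, b)
        for a, b in pairs[nonlocal_mask]
        if (min(a, b), max(a, b)) not in topo.excluded
    ]
    return np.array(keep, dtype=int).reshape(-1, 2)


class MinimizerHook(Protocol):
    """Signature for an external minimizer replacing the built-in one."""

    def __call__(
        self, model: AtomicModel, topology: Topology, max_steps: int
    ) -> AtomicModel: ...


def regularize(
    model: AtomicModel,
    topology: Topology | None = None,
    max_steps: int = 50,
    w_bond: float = 100.0,
    w_angle: float = 20.0,
    w_repulsion: float = 10.0,
    displacement_cap: float | None = 1.0,
    frozen: np.ndarray | None = None,
    hook: MinimizerHook | None = None,
) -> AtomicModel:
    """Minimize restraint energy to restore idealized stereochemistry.

    L-BFGS minimization of harmonic bond + angle restraints plus a
    soft-core non-bonded repulsion. ``displacement_cap`` bounds the
    per-atom movement of a single call; ``frozen`` marks atoms held
    fixed. A ``hook`` replaces the built-in minimizer entirely.
    """
    if topology is None:
        topology = build_topology(model)
    if topology.n_atoms != len(model):
        raise ValueError("topology does not match model atom count")
    if hook is not None:
        return hook(model, topology, max_steps)

    x0 = model.coords
    rep_pairs = _repulsion_pairs(x0, topology)
    frozen_mask = (
        np.zeros(len(model), dtype=bool) if frozen is None else np.asarray(frozen)
    )

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        e, g = _restraint_energy_grad(
            x, topology, w_bond, w_angle, w_repulsion, rep_pairs
        )
        g = g.reshape(-1, 3)
        g[frozen_mask] = 0.0
        return e, g.ravel()

    result = minimize(
        fun,
        x0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "ftol": 1e-12, "gtol": 1e-10},
    )
    coords = result.x.reshape(-1, 3)
    coords[frozen_mask] = x0[frozen_mask]
    if displacement_cap is not None:
        disp = coords - x0
        norms = np.linalg.norm(disp, axis=1)
        over = norms > displacement_cap
        if over.any():
            coords[over] = (
                x0[over] + disp[over] * (displacement_cap / norms[over])[:, None]
            )
    return model.with_coords(coords)


def stereo_report(
    model: AtomicModel, topology: Topology | None = None
) -> dict[str, float]:
    """Bond/angle RMS deviations vs idealized templates and clash count.

    A clash is a non-bonded (and non-1-3) atom pair closer than
    ``CONTACT_DISTANCE - CLASH_MARGIN``.
    """
    if topology is None:
        topology = build_topology(model)
    coords = model.coords
    out = {"bond_rmsd": 0.0, "angle_rmsd": 0.0, "clash_count": 0}
    if len(topology.bonds):
        r = np.linalg.norm(
            coords[topology.bonds[:, 0]] - coords[topology.bonds[:, 1]], axis=1
        )
        out["bond_rmsd"] = float(np.sqrt(np.mean((r - topology.bond_targets) ** 2)))
    if len(topology.angles):
        thetas = np.array(
            [
                bond_angle(coords[i], coords[j], coords[k])
                for i, j, k in topology.angles
            ]
        )
        out["angle_rmsd"] = float(
            np.sqrt(np.mean((thetas - topology.angle_targets) ** 2))
        )
    pairs = _repulsion_pairs(coords, topology)
    if len(pairs):
        r = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        out["clash_count"] = int(np.sum(r < CONTACT_DISTANCE - CLASH_MARGIN))
    return out
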