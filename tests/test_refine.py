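"""Responsibility-map refinement and restraint regularization."""

import numpy as np
import pytest

from cryofit.fixtures import (
    FixtureSpec,
    Perturbation,
    Segment,
    make_toy_structure,
    perturb_model,
    simulate_experimental_map,
)
from cryofit.geometry import rmsd
from cryofit.global_scores import ccc
from cryofit.io import Atom, AtomicModel, DensityMap
from cryofit.refine import (
    RefinementConfig,
    refine,
    responsibilities_dense,
    responsibility_update,
)
from cryofit.restraints import build_topology, regularize, stereo_report
from cryofit.simulate import SimulationParams, simulate_map


def gaussian_blob_map(center, sigma, shape=(16, 16, 16), voxel=1.0):
    axes = [np.arange(s) * voxel for s in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    return DensityMap(
        np.exp(-d2 / (2 * sigma**2)), [voxel] * 3, [0, 0, 0], resolution=3.0
    )


def atom_at(pos, resnum=1, chain="A"):
    return Atom(chain, resnum, "ALA", "CA", "C", pos)


class TestResponsibilityUpdate:
    def test_atom_moves_toward_density_peak(self):
        blob = gaussian_blob_map([8.0, 8.0, 8.0], sigma=2.0)
        model = AtomicModel([atom_at([7.0, 8.0, 8.0])])
        config = RefinementConfig(sigma=1.0)
        moved = responsibility_update(model, blob, config)
        d_before = np.linalg.norm(model.coords[0] - [8, 8, 8])
        d_after = np.linalg.norm(moved.coords[0] - [8, 8, 8])
        assert d_after < d_before

    def test_atom_at_centroid_is_fixed_point(self):
        blob = gaussian_blob_map([8.0, 8.0, 8.0], sigma=2.0)
        model = AtomicModel([atom_at([8.0, 8.0, 8.0])])
        moved = responsibility_update(model, blob, RefinementConfig(sigma=1.0))
        assert np.linalg.norm(moved.coords[0] - [8, 8, 8]) < 1e-6

    def test_responsibility_partition_sums_to_one(self):
        rng = np.random.default_rng(0)
        for trial in range(3):
            coords = 6.0 + 4.0 * rng.random((3, 3))
            model = AtomicModel(
                [atom_at(coords[i], resnum=i + 1) for i in range(3)]
            )
            blob = gaussian_blob_map([8.0, 8.0, 8.0], sigma=3.0)
            r = responsibilities_dense(model, blob, sigma=1.5)
            total = r.sum(axis=0)
            covered = total > 0
            np.testing.assert_allclose(total[covered], 1.0, atol=1e-8)
            assert covered.any()

    def test_neighbor_list_matches_dense_oracle(self):
        """Local-cube update equals a dense whole-grid evaluation."""
        blob = gaussian_blob_map([8.0, 8.0, 8.0], sigma=2.5)
        coords = np.array([[7.0, 8.0, 8.5], [9.0, 7.5, 8.0]])
        model = AtomicModel([atom_at(coords[i], resnum=i + 1) for i in range(2)])
        sigma, cutoff = 1.2, 8.0
        axes = [blob.voxel_centers_axis(d) for d in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        pos = np.stack([xx, yy, zz], axis=-1)
        density = np.clip(blob.grid, 0, None)
        # dense oracle with the same per-atom kernel truncation
        g = []
        for i in range(2):
            d2 = np.sum((pos - model.coords[i]) ** 2, axis=-1)
            gi = np.exp(-d2 / (2 * sigma**2))
            gi[d2 > (cutoff * sigma) ** 2] = 0.0
            g.append(gi)
        denom = g[0] + g[1]
        expected = []
        for i in range(2):
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(denom > 0, density * g[i] / denom, 0.0)
            expected.append((w[..., None] * pos).sum(axis=(0, 1, 2)) / w.sum())
        config = RefinementConfig(sigma=sigma, kernel_cutoff=cutoff)
        moved = responsibility_update(model, blob, config)
        np.testing.assert_allclose(moved.coords, np.array(expected), atol=1e-8)

    def test_all_zero_map_leaves_model_unchanged(self):
        zero = DensityMap(np.zeros((8, 8, 8)), [1, 1, 1], [0, 0, 0], resolution=3.0)
        model = AtomicModel([atom_at([4.0, 4.0, 4.0])])
        moved = responsibility_update(model, zero, RefinementConfig(sigma=1.0))
        np.testing.assert_allclose(moved.coords, model.coords)

    def test_single_blob_converges_to_centroid(self):
        """Five expectation steps reach the blob's weighted mean position."""
        center = np.array([8.3, 7.6, 8.1])
        blob = gaussian_blob_map(center, sigma=2.0)
        model = AtomicModel([atom_at([6.5, 8.5, 9.0])])
        config = RefinementConfig(sigma=1.0, kernel_cutoff=6.0)
        current = model
        for _ in range(5):
            current = responsibility_update(current, blob, config)
        # single atom: responsibility is 1, fixed point = local weighted mean
        axes = [blob.voxel_centers_axis(d) for d in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        pos = np.stack([xx, yy, zz], axis=-1)
        x = current.coords[0]
        d2 = np.sum((pos - x) ** 2, axis=-1)
        w = np.where(d2 <= (6.0 * 1.0) ** 2, blob.grid, 0.0)
        fixed_point = (w[..., None] * pos).sum(axis=(0, 1, 2)) / w.sum()
        assert np.linalg.norm(x - fixed_point) < 1e-3
        # and the limit sits at the blob center (symmetric density)
        assert np.linalg.norm(x - center) < 0.1


class TestRegularize:
    def ideal_helix(self, n=8, seed=0):
        spec = FixtureSpec(chains=((Segment("helix", n),),), seed=seed)
        return make_toy_structure(spec)

    def test_ideal_geometry_is_fixed_point(self):
        model = self.ideal_helix()
        out = regularize(model)
        disp = np.linalg.norm(out.coords - model.coords, axis=1)
        assert disp.max() < 1e-4

    def test_stretched_bond_restored(self):
        model = self.ideal_helix()
        topo = build_topology(model)
        idx = model.atom_index()
        i = idx[("A", 4, "CA")]
        j = idx[("A", 4, "CB")]
        coords = model.coords.copy()
        direction = coords[j] - coords[i]
        direction /= np.linalg.norm(direction)
        coords[j] += 0.5 * direction
        stretched = model.with_coords(coords)
        before = stereo_report(stretched, topo)["bond_rmsd"]
        relaxed = regularize(stretched, topo, max_steps=200)
        r = np.linalg.norm(relaxed.coords[i] - relaxed.coords[j])
        assert abs(r - 1.530) < 0.05
        assert stereo_report(relaxed, topo)["bond_rmsd"] < before

    def test_overlapping_atoms_pushed_apart(self):
        # two free atoms on different chains, overlapping at 0.5 A
        model = AtomicModel(
            [
                atom_at([5.0, 5.0, 5.0], chain="A"),
                atom_at([5.5, 5.0, 5.0], chain="B"),
            ]
        )
        out = regularize(model, max_steps=200, displacement_cap=2.0)
        sep = np.linalg.norm(out.coords[0] - out.coords[1])
        assert sep > 2.2  # beyond the clash threshold

    def test_topology_mismatch_rejected(self):
        model = self.ideal_helix(n=4)
        other = self.ideal_helix(n=5)
        with pytest.raises(ValueError, match="topology"):
            regularize(model, build_topology(other))


class TestStereoReport:
    def test_ideal_fixture_clean(self):
        spec = FixtureSpec(chains=((Segment("helix", 10),),), seed=0)
        model = make_toy_structure(spec)
        rep = stereo_report(model)
        assert rep["bond_rmsd"] < 1e-6
        assert rep["angle_rmsd"] < 1e-6
        assert rep["clash_count"] == 0

    def test_single_stretched_bond_closed_form(self):
        spec = FixtureSpec(chains=((Segment("helix", 6),),), seed=0)
        model = make_toy_structure(spec)
        topo = build_topology(model)
        n_bonds = len(topo.bonds)
        idx = model.atom_index()
        i, j = idx[("A", 3, "C")], idx[("A", 3, "O")]
        coords = model.coords.copy()
        direction = coords[j] - coords[i]
        direction /= np.linalg.norm(direction)
        coords[j] += 0.2 * direction
        rep = stereo_report(model.with_coords(coords), topo)
        assert rep["bond_rmsd"] == pytest.approx(0.2 / np.sqrt(n_bonds), abs=1e-9)

    def test_overlapping_pair_counts_one_clash(self):
        model = AtomicModel(
            [
                atom_at([5.0, 5.0, 5.0], chain="A"),
                atom_at([5.5, 5.0, 5.0], chain="B"),
            ]
        )
        assert stereo_report(model)["clash_count"] == 1


class TestRefine:
    def shift_case(self, seed):
        spec = FixtureSpec(
            chains=(
                (Segment("helix", 12), Segment("loop", 6), Segment("strand", 8)),
            ),
            seed=seed,
        )
        truth = make_toy_structure(spec)
        mapx = simulate_experimental_map(truth, spec)
        shifted = perturb_model(
            truth, Perturbation("sse_shift", "A", 3, 10, 2.0), seed=seed
        )
        return truth, mapx, shifted

    def test_helix_shift_recovered(self):
        truth, mapx, shifted = self.shift_case(seed=1)
        sim = SimulationParams(resolution=3.0)
        mask = np.array(
            [a.chain_id == "A" and 3 <= a.residue_number <= 10 for a in truth]
        )
        cc_before = ccc(mapx, simulate_map(shifted, sim, grid_template=mapx))
        refined, trace = refine(shifted, mapx, RefinementConfig(), sim)
        cc_after = ccc(mapx, simulate_map(refined, sim, grid_template=mapx))
        r_before = rmsd(shifted.coords[mask], truth.coords[mask])
        r_after = rmsd(refined.coords[mask], truth.coords[mask])
        assert r_after <= 0.5 * r_before
        assert cc_after > cc_before
        frame = trace.to_frame()
        assert len(frame) == 5
        assert frame["bond_rmsd"].iloc[-1] < 0.05

    def test_ground_truth_is_near_fixed_point(self):
        spec = FixtureSpec(
            chains=((Segment("helix", 10), Segment("strand", 6)),), seed=3
        )
        truth = make_toy_structure(spec)
        mapx = simulate_experimental_map(truth, spec)
        sim = SimulationParams(resolution=3.0)
        cc_before = ccc(mapx, simulate_map(truth, sim, grid_template=mapx))
        refined, _ = refine(truth, mapx, RefinementConfig(), sim)
        cc_after = ccc(mapx, simulate_map(refined, sim, grid_template=mapx))
        assert rmsd(refined.coords, truth.coords) < 0.3
        assert cc_after >= cc_before - 1e-3

    def test_domain_reorientation_corrected(self):
        spec = FixtureSpec(
            chains=((Segment("helix", 10), Segment("loop", 4), Segment("helix", 10)),),
            seed=5,
            noise_sd=0.02,
        )
        truth = make_toy_structure(spec)
        mapx = simulate_experimental_map(truth, spec)
        wrong = perturb_model(
            truth, Perturbation("domain_reorient", "A", 15, 24, 12.0), seed=5
        )
        sim = SimulationParams(resolution=3.0)
        dom = np.array(
            [a.chain_id == "A" and 15 <= a.residue_number <= 24 for a in truth]
        )
        r_before = rmsd(wrong.coords[dom], truth.coords[dom])
        refined, _ = refine(wrong, mapx, RefinementConfig(), sim)
        r_after = rmsd(refined.coords[dom], truth.coords[dom])
        assert r_after < r_before  # mis-oriented domain pulled back

    def test_refinement_is_deterministic(self):
        truth, mapx, shifted = self.shift_case(seed=7)
        sim = SimulationParams(resolution=3.0)
        a, _ = refine(shifted, mapx, RefinementConfig(), sim)
        b, _ = refine(shifted, mapx, RefinementConfig(), sim)
        np.testing.assert_array_equal(a.coords, b.coords)
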