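"""Synthetic structures, perturbations, degraded maps, and ensembles."""

import numpy as np
import pytest

from cryofit.fixtures import (
    FixtureSpec,
    Perturbation,
    Segment,
    make_ensemble,
    make_toy_structure,
    perturb_model,
    simulate_experimental_map,
)
from cryofit.geometry import rmsd
from cryofit.restraints import stereo_report
from cryofit.simulate import SimulationParams, simulate_map


def ca_coords(model, chain="A"):
    return np.array(
        [a.position for a in model if a.chain_id == chain and a.atom_name == "CA"]
    )


class TestMakeToyStructure:
    def test_helix_ca_geometry(self):
        spec = FixtureSpec(chains=((Segment("helix", 12),),), seed=0)
        ca = ca_coords(make_toy_structure(spec))
        steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        np.testing.assert_allclose(steps, 3.8, atol=0.1)
        # i -> i+3 distance characteristic of an alpha helix
        d3 = np.linalg.norm(ca[3:] - ca[:-3], axis=1)
        assert np.all((d3 > 4.7) & (d3 < 5.6))

    def test_strand_is_extended(self):
        spec = FixtureSpec(chains=((Segment("strand", 10),),), seed=0)
        ca = ca_coords(make_toy_structure(spec))
        d3 = np.linalg.norm(ca[3:] - ca[:-3], axis=1)
        assert np.all(d3 > 9.0)  # extended: ~3.3 A rise per residue

    def test_expected_atoms_per_residue(self, standard_truth):
        for (chain, rn) in standard_truth.residues():
            names = {a.atom_name for a in standard_truth.residue_atoms(chain, rn)}
            assert names == {"N", "CA", "C", "O", "CB", "CG"}

    def test_ideal_stereochemistry(self, standard_truth):
        rep = stereo_report(standard_truth)
        assert rep["bond_rmsd"] < 1e-6
        assert rep["angle_rmsd"] < 1e-6

    def test_secondary_structure_chains_clash_free(self):
        # loops only clash-check the CA trace, so the clash-free
        # guarantee is asserted on pure secondary-structure chains
        spec = FixtureSpec(
            chains=((Segment("helix", 12), Segment("strand", 8)),), seed=1
        )
        rep = stereo_report(make_toy_structure(spec))
        assert rep["clash_count"] == 0

    def test_deterministic_for_fixed_seed(self):
        spec = FixtureSpec(seed=42)
        a = make_toy_structure(spec)
        b = make_toy_structure(spec)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_loops_vary_with_seed(self):
        spec1 = FixtureSpec(
            chains=((Segment("loop", 8),),), seed=1
        )
        spec2 = FixtureSpec(
            chains=((Segment("loop", 8),),), seed=2
        )
        a, b = make_toy_structure(spec1), make_toy_structure(spec2)
        assert not np.allclose(a.coords, b.coords)

    def test_two_chains_separated(self):
        spec = FixtureSpec(
            chains=((Segment("helix", 8),), (Segment("strand", 6),)), seed=0
        )
        model = make_toy_structure(spec)
        assert model.chain_ids == ["A", "B"]
        a = np.array([at.position for at in model.chain("A")])
        b = np.array([at.position for at in model.chain("B")])
        min_gap = min(
            np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1).min(), np.inf
        )
        assert min_gap > 2.0

    def test_no_ca_clashes(self):
        spec = FixtureSpec(
            chains=((Segment("loop", 12), Segment("helix", 6)),), seed=3
        )
        ca = ca_coords(make_toy_structure(spec))
        d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
        sep = np.abs(np.subtract.outer(range(len(ca)), range(len(ca))))
        assert d[(sep >= 3)].min() >= 3.2


class TestPerturbModel:
    def test_sse_shift_magnitude_exact(self, standard_truth):
        recipe = Perturbation("sse_shift", "A", 3, 10, 2.0)
        pert = perturb_model(standard_truth, recipe, seed=0)
        mask = np.array(
            [a.chain_id == "A" and 3 <= a.residue_number <= 10 for a in standard_truth]
        )
        disp = np.linalg.norm(pert.coords[mask] - standard_truth.coords[mask], axis=1)
        np.testing.assert_allclose(disp, 2.0, atol=1e-9)  # frozen, rigid
        # residues outside segment + flank are untouched
        far = np.array(
            [
                a.chain_id != "A" or not (1 <= a.residue_number <= 12)
                for a in standard_truth
            ]
        )
        np.testing.assert_allclose(
            pert.coords[far], standard_truth.coords[far], atol=1e-12
        )

    def test_zero_magnitude_is_identity(self, standard_truth):
        for kind in ("loop_shift", "sse_shift", "sse_rotate", "domain_reorient"):
            pert = perturb_model(
                standard_truth, Perturbation(kind, "A", 14, 18, 0.0), seed=5
            )
            np.testing.assert_allclose(
                pert.coords, standard_truth.coords, atol=1e-9
            )

    def test_loop_shift_rms_matches_magnitude(self, standard_truth):
        recipe = Perturbation("loop_shift", "A", 13, 18, 1.5)
        pert = perturb_model(standard_truth, recipe, seed=2)
        mask = np.array(
            [a.chain_id == "A" and 13 <= a.residue_number <= 18 for a in standard_truth]
        )
        disp = np.linalg.norm(pert.coords[mask] - standard_truth.coords[mask], axis=1)
        np.testing.assert_allclose(disp, 1.5, atol=1e-9)  # fixed length per residue

    def test_rigid_kinds_preserve_internal_geometry(self, standard_truth):
        for kind, mag in (("sse_rotate", 25.0), ("domain_reorient", 20.0)):
            pert = perturb_model(
                standard_truth, Perturbation(kind, "A", 3, 10, mag), seed=1
            )
            mask = np.array(
                [
                    a.chain_id == "A" and 3 <= a.residue_number <= 10
                    for a in standard_truth
                ]
            )
            # rigid motion: all internal pairwise distances preserved
            orig = standard_truth.coords[mask]
            new = pert.coords[mask]
            d_orig = np.linalg.norm(orig[:, None] - orig[None, :], axis=-1)
            d_new = np.linalg.norm(new[:, None] - new[None, :], axis=-1)
            np.testing.assert_allclose(d_new, d_orig, atol=1e-9)
            assert rmsd(new, orig) > 0.5

    def test_junction_relaxation_bounded(self, standard_truth):
        pert = perturb_model(
            standard_truth, Perturbation("sse_shift", "A", 3, 10, 2.0), seed=0
        )
        flank = np.array(
            [
                a.chain_id == "A" and a.residue_number in (1, 2, 11, 12)
                for a in standard_truth
            ]
        )
        disp = np.linalg.norm(
            pert.coords[flank] - standard_truth.coords[flank], axis=1
        )
        assert disp.max() <= 0.15 + 1e-9

    def test_determinism(self, standard_truth):
        r = Perturbation("domain_reorient", "A", 13, 26, 15.0)
        a = perturb_model(standard_truth, r, seed=9)
        b = perturb_model(standard_truth, r, seed=9)
        np.testing.assert_array_equal(a.coords, b.coords)
        c = perturb_model(standard_truth, r, seed=10)
        assert not np.allclose(a.coords, c.coords)

    def test_bad_range_rejected(self, standard_truth):
        with pytest.raises(ValueError):
            perturb_model(
                standard_truth, Perturbation("sse_shift", "A", 100, 110, 1.0)
            )
        with pytest.raises(ValueError):
            perturb_model(
                standard_truth, Perturbation("sse_shift", "Z", 1, 5, 1.0)
            )


class TestSimulateExperimentalMap:
    def test_reduces_to_clean_map_without_noise(self, standard_truth):
        spec = FixtureSpec(noise_sd=0.0, seed=1)
        mapx = simulate_experimental_map(standard_truth, spec)
        clean = simulate_map(standard_truth, SimulationParams(resolution=3.0))
        np.testing.assert_allclose(mapx.grid, clean.grid, atol=1e-12)

    def test_noise_is_seed_deterministic(self, standard_truth):
        spec = FixtureSpec(noise_sd=0.05, seed=4)
        a = simulate_experimental_map(standard_truth, spec)
        b = simulate_experimental_map(standard_truth, spec)
        np.testing.assert_array_equal(a.grid, b.grid)
        c = simulate_experimental_map(
            standard_truth, FixtureSpec(noise_sd=0.05, seed=5)
        )
        assert not np.array_equal(a.grid, c.grid)

    def test_map_is_nonnegative(self, standard_truth):
        spec = FixtureSpec(noise_sd=0.2, seed=0)
        mapx = simulate_experimental_map(standard_truth, spec)
        assert mapx.grid.min() >= 0.0

    def test_flexible_region_locally_degraded(self, standard_truth):
        flex = (("A", 13, 18),)
        spec = FixtureSpec(noise_sd=0.0, flexible_regions=flex, seed=1)
        degraded = simulate_experimental_map(standard_truth, spec)
        clean = simulate_experimental_map(
            standard_truth, FixtureSpec(noise_sd=0.0, seed=1)
        )
        flex_atoms = np.array(
            [
                a.position
                for a in standard_truth
                if a.chain_id == "A" and 13 <= a.residue_number <= 18
            ]
        )
        rigid_atoms = np.array(
            [
                a.position
                for a in standard_truth
                if not (a.chain_id == "A" and 13 <= a.residue_number <= 18)
            ]
        )
        def local_peak(mapx, pts):
            idx = np.array([mapx.position_to_index(p).round().astype(int) for p in pts])
            return np.array([mapx.grid[tuple(i)] for i in idx])

        # density at flexible atoms drops substantially; rigid region barely moves
        flex_ratio = local_peak(degraded, flex_atoms) / local_peak(clean, flex_atoms)
        rigid_ratio = local_peak(degraded, rigid_atoms) / local_peak(clean, rigid_atoms)
        assert np.median(flex_ratio) < 0.5
        assert np.median(rigid_ratio) > 0.9


class TestMakeEnsemble:
    def test_flexible_regions_vary_more(self, standard_truth):
        flex = (("A", 13, 18),)
        models = make_ensemble(
            standard_truth, n_models=12, seed=3, flexible_regions=flex
        )
        coords = np.stack([m.coords for m in models])
        sd = coords.std(axis=0, ddof=1).mean(axis=1)
        in_flex = np.array(
            [a.chain_id == "A" and 13 <= a.residue_number <= 18 for a in standard_truth]
        )
        assert sd[in_flex].mean() > 2.0 * sd[~in_flex].mean()

    def test_rigid_jitter_rms_scale(self, standard_truth):
        models = make_ensemble(standard_truth, n_models=40, seed=7, rigid_jitter=0.3)
        disp = np.stack(
            [np.linalg.norm(m.coords - standard_truth.coords, axis=1) for m in models]
        )
        rms = np.sqrt((disp**2).mean())
        assert rms == pytest.approx(0.3, rel=0.15)

    def test_residue_level_rigidity(self, standard_truth):
        # atoms of one residue move together: bonds within a residue intact
        model = make_ensemble(standard_truth, n_models=1, seed=0)[0]
        for (chain, rn) in standard_truth.residues():
            orig = np.array(
                [a.position for a in standard_truth.residue_atoms(chain, rn)]
            )
            new = np.array([a.position for a in model.residue_atoms(chain, rn)])
            shifts = new - orig
            np.testing.assert_allclose(shifts - shifts[0], 0.0, atol=1e-12)

    def test_seed_contract(self, standard_truth):
        a = make_ensemble(standard_truth, 3, seed=1)
        b = make_ensemble(standard_truth, 3, seed=1)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.coords, mb.coords)
        # prefix property: first k models identical regardless of n_models
        c = make_ensemble(standard_truth, 5, seed=1)
        np.testing.assert_array_equal(a[2].coords, c[2].coords)

    def test_invalid_count_rejected(self, standard_truth):
        with pytest.raises(ValueError):
            make_ensemble(standard_truth, 0)
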