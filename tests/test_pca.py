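import numpy as np
import pytest

from confensemble.pca import (
    build_aligned_ensemble,
    export_mode_trajectory,
    find_invariant_core,
    pairwise_rmsd_and_cluster,
    pca_cartesian,
    pca_report,
    sequence_identity,
    superpose_ensemble,
)
from confensemble.structio import Structure
from confensemble.synthetic import gen_structure_ensemble

from oracles import random_rotation


class TestSequenceIdentity:
    def test_identical_sequences(self):
        frac, mism = sequence_identity("MKTAYIAKQR", "MKTAYIAKQR")
        assert frac == 1.0 and mism == []

    def test_single_substitution_in_hundred(self):
        a = "A" * 100
        b = "A" * 49 + "G" + "A" * 50
        frac, mism = sequence_identity(a, b)
        assert frac == pytest.approx(0.99)
        assert mism == [50]

    def test_region_restriction_and_numbering(self):
        a = "MKTAYIAKQR"
        b = "MKTGYIAKQR"  # mismatch at position 4
        frac, mism = sequence_identity(a, b, region=(5, 10))
        assert frac == 1.0 and mism == []
        frac, mism = sequence_identity(a, b, region=(1, 5), a_start=1)
        assert mism == [4]
        # shifted numbering moves the reported position
        _, mism66 = sequence_identity(a, b, a_start=66)
        assert mism66 == [69]

    def test_gapped_alignment_counts_aligned_columns_only(self):
        frac, _ = sequence_identity("MKTAYIAKQR", "MKTIAKQR")  # 2-residue deletion
        assert frac == 1.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            sequence_identity("MKT", "MKT", region=(5, 4))


def make_ca(coords, resnums=None, title="s"):
    n = len(coords)
    return Structure(
        elements=["C"] * n,
        coords=coords,
        atom_names=["CA"] * n,
        res_names=["ALA"] * n,
        res_numbers=np.asarray(resnums if resnums is not None else range(1, n + 1)),
        title=title,
    )


class TestAlignedEnsemble:
    def test_gap_positions_removed(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(-5, 5, (20, 3))
        full = make_ca(base)
        # second structure missing residues 5..7 (deletion)
        keep = [i for i in range(20) if i not in (4, 5, 6)]
        partial = Structure(
            elements=["C"] * 17,
            coords=base[keep],
            atom_names=["CA"] * 17,
            res_names=[["ALA", "GLY", "SER", "THR"][i % 4] for i in keep],
            res_numbers=np.arange(1, 18),
        )
        # give both real varied sequences so alignment is nontrivial
        full.res_names = [["ALA", "GLY", "SER", "THR"][i % 4] for i in range(20)]
        ens = build_aligned_ensemble([full, partial])
        assert ens.n_positions == 17
        assert ens.n_structures == 2
        np.testing.assert_allclose(ens.coords[:, 0, :], base[keep])
        np.testing.assert_allclose(ens.coords[:, 1, :], base[keep])

    def test_too_few_structures_rejected(self):
        with pytest.raises(ValueError):
            build_aligned_ensemble([make_ca(np.zeros((4, 3)))])


class TestInvariantCore:
    def test_identical_structures_keep_all_positions(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(-5, 5, (15, 3))
        ens = build_aligned_ensemble([make_ca(base) for _ in range(4)])
        core = find_invariant_core(ens, min_core=5)
        assert core.indices.size == 15
        assert core.n_dropped == 0

    def test_planted_noisy_positions_excluded(self):
        rng = np.random.default_rng(2)
        structures, _ = gen_structure_ensemble(
            7, n_positions=25, n_structures=10, mode_variances=[1e-8],
            noise_sigma=0.0, rigid_motions=True,
        )
        noisy = {3, 9, 14, 18, 22}
        jittered = []
        for s in structures:
            c = s.coords.copy()
            for p in noisy:
                c[p] += rng.normal(0, 3.0, 3)
            jittered.append(s.with_coords(c))
        ens = build_aligned_ensemble(jittered)
        core = find_invariant_core(ens, volume_cutoff=0.5, min_core=5)
        assert set(range(25)) - set(core.indices) == noisy

    def test_invariant_to_rigid_motion_of_one_member(self):
        structures, _ = gen_structure_ensemble(
            8, n_positions=20, n_structures=6, mode_variances=[0.5],
            noise_sigma=0.02, rigid_motions=False,
        )
        ens1 = build_aligned_ensemble(structures)
        rng = np.random.default_rng(5)
        moved = list(structures)
        moved[2] = moved[2].with_coords(
            moved[2].coords @ random_rotation(rng).T + np.array([30.0, -12.0, 4.0])
        )
        ens2 = build_aligned_ensemble(moved)
        c1 = find_invariant_core(ens1, volume_cutoff=0.01, min_core=5)
        c2 = find_invariant_core(ens2, volume_cutoff=0.01, min_core=5)
        np.testing.assert_array_equal(c1.indices, c2.indices)


class TestClustering:
    def test_planted_two_groups_recovered_exactly(self):
        structures, truth = gen_structure_ensemble(
            13, n_positions=40, n_structures=12, mode_variances=[0.04],
            n_groups=2, group_offset=5.0, noise_sigma=0.2,
        )
        ens = superpose_ensemble(build_aligned_ensemble(structures))
        tree = pairwise_rmsd_and_cluster(ens, k=2)
        planted = np.array(truth["group_labels"])
        # same partition up to label names
        mapping = {}
        for got, want in zip(tree.groups, planted):
            mapping.setdefault(got, want)
            assert mapping[got] == want
        assert len(set(mapping.values())) == 2

    def test_matrix_symmetry_and_zero_diagonal(self):
        structures, _ = gen_structure_ensemble(3, n_positions=15, n_structures=5)
        ens = superpose_ensemble(build_aligned_ensemble(structures))
        tree = pairwise_rmsd_and_cluster(ens, k=2)
        d = tree.rmsd_matrix
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-12)
        assert np.all(d >= 0)

    def test_identical_ensemble_stable_labels(self):
        base = np.random.default_rng(4).uniform(-5, 5, (12, 3))
        ens = superpose_ensemble(
            build_aligned_ensemble([make_ca(base, title=f"s{i}") for i in range(5)])
        )
        tree = pairwise_rmsd_and_cluster(ens, k=3)
        assert tree.groups[0] == 1  # first-appearance renumbering
        assert set(tree.groups) <= {1, 2, 3}

    def test_too_many_groups_rejected(self):
        structures, _ = gen_structure_ensemble(3, n_positions=10, n_structures=4)
        ens = build_aligned_ensemble(structures)
        with pytest.raises(ValueError):
            pairwise_rmsd_and_cluster(ens, k=5)

    def test_newick_export_contains_all_labels(self):
        structures, _ = gen_structure_ensemble(6, n_positions=12, n_structures=5)
        ens = superpose_ensemble(build_aligned_ensemble(structures))
        nwk = pairwise_rmsd_and_cluster(ens, k=2).to_newick()
        assert nwk.endswith(";")
        for s in structures:
            assert s.title in nwk


class TestCartesianPCA:
    def test_identical_structures_flagged_degenerate(self):
        base = np.random.default_rng(9).uniform(-5, 5, (10, 3))
        ens = build_aligned_ensemble([make_ca(base) for _ in range(4)])
        pca = pca_cartesian(ens)
        assert pca.degenerate
        assert not np.any(np.isnan(pca.variance_proportions))
        np.testing.assert_allclose(pca.eigenvalues, 0.0, atol=1e-12)

    def test_single_planted_mode_is_everything(self):
        structures, _ = gen_structure_ensemble(
            10, n_positions=30, n_structures=10, mode_variances=[2.0],
            noise_sigma=0.0, rigid_motions=False,
        )
        pca = pca_cartesian(build_aligned_ensemble(structures))
        assert pca.variance_proportions[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_mode_four_to_one_proportions(self):
        # low noise: mode fractions 80/20 recovered within 3 points
        structures, _ = gen_structure_ensemble(
            20, n_positions=40, n_structures=50, mode_variances=[4.0, 1.0],
            noise_sigma=0.01,
        )
        ens = superpose_ensemble(build_aligned_ensemble(structures))
        pca = pca_cartesian(ens)
        assert 100 * pca.variance_proportions[0] == pytest.approx(80.0, abs=3.0)
        assert 100 * pca.variance_proportions[1] == pytest.approx(20.0, abs=3.0)

    def test_eigenvalue_count_and_trace_identity(self):
        structures, _ = gen_structure_ensemble(21, n_positions=25, n_structures=8)
        ens = superpose_ensemble(build_aligned_ensemble(structures))
        pca = pca_cartesian(ens)
        assert pca.eigenvalues.size == 3 * 25
        x = ens.coords.transpose(1, 0, 2).reshape(8, -1)
        total_var = np.sum((x - x.mean(axis=0)) ** 2) / (8 - 1)
        assert pca.eigenvalues.sum() == pytest.approx(total_var, rel=1e-6)
        assert pca.variance_proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_from_all_components(self):
        structures, _ = gen_structure_ensemble(22, n_positions=12, n_structures=6)
        ens = superpose_ensemble(build_aligned_ensemble(structures))
        pca = pca_cartesian(ens)
        x = ens.coords.transpose(1, 0, 2).reshape(6, -1)
        xc = x - x.mean(axis=0)
        np.testing.assert_allclose(pca.projections @ pca.mode_vectors, xc, atol=1e-6)

    def test_proportions_invariant_to_input_order(self):
        structures, _ = gen_structure_ensemble(23, n_positions=20, n_structures=7)
        e1 = superpose_ensemble(build_aligned_ensemble(structures))
        e2 = superpose_ensemble(build_aligned_ensemble(structures[::-1]))
        np.testing.assert_allclose(
            pca_cartesian(e1).variance_proportions,
            pca_cartesian(e2).variance_proportions,
            atol=1e-9,
        )

    def test_report_table_shape(self):
        structures, _ = gen_structure_ensemble(24, n_positions=10, n_structures=5)
        pca = pca_cartesian(superpose_ensemble(build_aligned_ensemble(structures)))
        rep = pca_report(pca, n_components=4)
        assert list(rep.columns) == [
            "component", "eigenvalue_A2", "variance_pct", "cumulative_pct",
        ]
        assert len(rep) == 4


class TestModeTrajectory:
    def make_pca(self):
        structures, _ = gen_structure_ensemble(30, n_positions=15, n_structures=8)
        return pca_cartesian(superpose_ensemble(build_aligned_ensemble(structures)))

    def test_zero_amplitude_gives_mean_everywhere(self):
        pca = self.make_pca()
        frames = export_mode_trajectory(pca, 0, amplitude=0.0, n_frames=5)
        for f in frames:
            np.testing.assert_allclose(f.coords, pca.mean_coords, atol=1e-12)

    def test_extremes_differ_by_twice_amplitude_along_mode(self):
        pca = self.make_pca()
        frames = export_mode_trajectory(pca, 0, amplitude=1.5, n_frames=7)
        diff = (frames[-1].coords - frames[0].coords).ravel()
        assert np.linalg.norm(diff) == pytest.approx(3.0, abs=1e-9)
        unit = diff / np.linalg.norm(diff)
        assert abs(float(unit @ pca.mode_vectors[0])) == pytest.approx(1.0, abs=1e-9)

    def test_pca_of_trajectory_recovers_mode_direction(self):
        pca = self.make_pca()
        frames = export_mode_trajectory(pca, 1, amplitude=2.0, n_frames=9)
        ens = build_aligned_ensemble(frames)
        pca2 = pca_cartesian(ens)
        dot = float(pca2.mode_vectors[0] @ pca.mode_vectors[1])
        assert abs(dot) > 0.999

    def test_out_of_range_component_rejected(self):
        pca = self.make_pca()
        with pytest.raises(ValueError):
            export_mode_trajectory(pca, 3 * 15, amplitude=1.0)
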