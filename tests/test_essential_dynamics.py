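import numpy as np
import pytest

from conftest import make_atoms
from ensdyn import SyntheticEnsembleSpec, generate_two_domain_ensemble
from ensdyn.ensemble_io import StructuralEnsemble
from ensdyn.essential_dynamics import (
    ConformationMatrix,
    Scaling,
    build_matrix,
    classify_conformers,
    compute_modes,
    mode_overlap,
    project,
    residue_mode_amplitude,
    to_nmd_document,
    variance_fractions,
)
from ensdyn.superpose import superpose_ensemble
from oracle_utils import dense_covariance_modes


def matrix_from_rows(rows, n_atoms):
    rows = np.asarray(rows, dtype=float)
    centred = rows - rows.mean(axis=0)
    return ConformationMatrix(
        data=centred,
        atom_index=[("A", i + 1) for i in range(n_atoms)],
        col_mean=rows.mean(axis=0),
    )


class TestBuildMatrix:
    def test_identical_models_give_zero_matrix(self, rng):
        base = rng.normal(size=(4, 3))
        ens = StructuralEnsemble(coords=np.repeat(base[None], 2, axis=0), atoms=make_atoms(4))
        mat = build_matrix(superpose_ensemble(ens))
        np.testing.assert_allclose(mat.data, 0.0, atol=1e-12)

    def test_single_moving_coordinate_closed_form(self):
        d = 0.25
        # Models already superposed (identity transforms): atom 0 moves only
        # along x by (-d, 0, +d).
        coords = np.zeros((3, 5, 3))
        anchors = np.array(
            [[10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0], [10.0, 10.0, 0]]
        )
        coords[:, 1:, :] = anchors
        coords[0, 0, 0] = -d
        coords[2, 0, 0] = d
        ens = StructuralEnsemble(coords=coords, atoms=make_atoms(5))
        from ensdyn.superpose import RigidTransform, SuperposedEnsemble

        sup = SuperposedEnsemble(
            ensemble=ens,
            transforms=[RigidTransform.identity()] * 3,
            reference_index=0,
            rmsd_to_reference=np.zeros(3),
        )
        mat = build_matrix(sup)
        col_x = mat.data[:, 0]
        np.testing.assert_allclose(col_x, [-d, 0.0, d], atol=1e-9)
        others = np.delete(mat.data, 0, axis=1)
        np.testing.assert_allclose(others, 0.0, atol=1e-9)

    def test_columns_centred(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        mat = build_matrix(superpose_ensemble(ens))
        assert np.max(np.abs(mat.data.mean(axis=0))) <= 1e-10

    def test_unit_variance_scaling(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        mat = build_matrix(superpose_ensemble(ens), scaling="unit_variance")
        sds = mat.data.std(axis=0, ddof=1)
        nonzero = sds > 0
        np.testing.assert_allclose(sds[nonzero], 1.0, atol=1e-8)

    def test_single_model_error(self, rng):
        ens = StructuralEnsemble(coords=rng.normal(size=(1, 4, 3)), atoms=make_atoms(4))
        with pytest.raises(ValueError):
            build_matrix(superpose_ensemble(ens))


class TestComputeModes:
    def test_rank_one_recovers_direction(self, rng):
        v = rng.normal(size=12)
        v /= np.linalg.norm(v)
        c = rng.normal(0, 2.0, size=6)
        mat = matrix_from_rows(np.outer(c, v), n_atoms=4)
        modes = compute_modes(mat, k=1)
        assert mode_overlap(modes.vectors[0], v) == pytest.approx(1.0, abs=1e-10)
        assert modes.eigenvalues[0] == pytest.approx(np.var(c, ddof=1), rel=1e-10)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_dense_covariance_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        rows = rng.normal(size=(6, 12))
        mat = matrix_from_rows(rows, n_atoms=4)
        k = 5
        modes = compute_modes(mat, k=k)
        ev_o, vec_o = dense_covariance_modes(mat.data, k)
        np.testing.assert_allclose(modes.eigenvalues, ev_o, atol=1e-8)
        for ours, theirs in zip(modes.vectors, vec_o):
            assert min(
                np.max(np.abs(ours - theirs)), np.max(np.abs(ours + theirs))
            ) <= 1e-8

    def test_sign_convention(self, rng):
        rows = rng.normal(size=(5, 9))
        modes = compute_modes(matrix_from_rows(rows, n_atoms=3))
        for v in modes.vectors:
            assert v[np.argmax(np.abs(v))] > 0

    def test_k_out_of_range(self, rng):
        mat = matrix_from_rows(rng.normal(size=(4, 9)), n_atoms=3)
        with pytest.raises(ValueError):
            compute_modes(mat, k=0)
        with pytest.raises(ValueError):
            compute_modes(mat, k=4)  # kmax = M-1 = 3

    def test_orthonormal_and_sorted(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        mat = build_matrix(superpose_ensemble(ens))
        modes = compute_modes(mat, k=8)
        gram = modes.vectors @ modes.vectors.T
        np.testing.assert_allclose(gram, np.eye(8), atol=1e-8)
        assert np.all(np.diff(modes.eigenvalues) <= 1e-10)
        assert np.all(modes.eigenvalues >= 0)

    def test_trace_conservation(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        mat = build_matrix(superpose_ensemble(ens))
        modes = compute_modes(mat, k=2)
        total = mat.data.var(axis=0, ddof=1).sum()
        assert modes.total_variance == pytest.approx(total, abs=1e-8)

    def test_planted_mode_recovery(self):
        spec = SyntheticEnsembleSpec(seed=42)  # twist 0.15, bend 0.08, noise 0.1
        ens, truth = generate_two_domain_ensemble(spec)
        sup = superpose_ensemble(ens, iterate_to_mean=True)
        modes = compute_modes(build_matrix(sup), k=2)
        planted = truth.aligned_mode_vectors(modes.mean_coords.reshape(-1, 3))
        for i in range(2):
            best = max(mode_overlap(planted[i], modes.vectors[j]) for j in range(2))
            assert best >= 0.8


class TestVarianceFractions:
    def test_rank_one_fraction_is_one(self, rng):
        v = rng.normal(size=6)
        mat = matrix_from_rows(np.outer(rng.normal(size=4), v), n_atoms=2)
        modes = compute_modes(mat, k=1)
        assert variance_fractions(modes)[0] == pytest.approx(1.0, abs=1e-10)

    def test_two_to_one_amplitude_gives_four_to_one_variance(self):
        # Orthogonal planted directions with displacement scales 2d and d.
        rng = np.random.default_rng(7)
        v1 = rng.normal(size=12)
        v1 /= np.linalg.norm(v1)
        v2 = rng.normal(size=12)
        v2 -= (v2 @ v1) * v1
        v2 /= np.linalg.norm(v2)
        d = 0.9
        rows = []
        for a, b in [(2 * d, d), (-2 * d, -d), (2 * d, -d), (-2 * d, d)]:
            rows.append(a * v1 + b * v2)
        modes = compute_modes(matrix_from_rows(rows, n_atoms=4), k=2)
        frac = variance_fractions(modes)
        assert frac[0] / frac[1] == pytest.approx(4.0, rel=1e-8)

    def test_matches_oracle_normalisation(self, rng):
        rows = rng.normal(size=(7, 15))
        mat = matrix_from_rows(rows, n_atoms=5)
        modes = compute_modes(mat, k=6)
        ev_o, _ = dense_covariance_modes(mat.data, 6)
        trace = np.trace((mat.data.T @ mat.data) / 6)
        np.testing.assert_allclose(variance_fractions(modes), ev_o / trace, atol=1e-8)

    def test_full_decomposition_sums_to_one(self, rng):
        rows = rng.normal(size=(5, 9))
        modes = compute_modes(matrix_from_rows(rows, n_atoms=3), k=4)
        assert variance_fractions(modes).sum() == pytest.approx(1.0, abs=1e-8)

    def test_zero_variance_error(self):
        mat = matrix_from_rows(np.zeros((3, 6)), n_atoms=2)
        modes = compute_modes(mat, k=1)
        with pytest.raises(ValueError):
            variance_fractions(modes)


class TestProject:
    def test_zero_row_projects_to_zero(self, rng):
        rows = rng.normal(size=(4, 9))
        rows[2] = rows.mean(axis=0)  # row equal to the mean -> centred zero? no:
        mat = matrix_from_rows(rows, n_atoms=3)
        modes = compute_modes(mat, k=2)
        p = project(mat, modes)
        # A centred zero row projects to zero: append one explicitly.
        zero_mat = ConformationMatrix(
            data=np.zeros((1, 9)), atom_index=mat.atom_index, col_mean=mat.col_mean
        )
        np.testing.assert_allclose(project(zero_mat, modes), 0.0, atol=1e-12)
        assert p.shape == (4, 2)

    def test_rank_one_projections_recover_coefficients(self, rng):
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        c = np.array([1.5, -0.5, -1.0])  # zero-mean coefficients
        mat = matrix_from_rows(np.outer(c, v), n_atoms=2)
        modes = compute_modes(mat, k=1)
        p = project(mat, modes)[:, 0]
        sign = np.sign(p[0] / c[0])
        np.testing.assert_allclose(sign * p, c, atol=1e-10)

    def test_projection_variance_equals_eigenvalue(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        mat = build_matrix(superpose_ensemble(ens))
        modes = compute_modes(mat, k=5)
        p = project(mat, modes)
        np.testing.assert_allclose(
            p.var(axis=0, ddof=1), modes.eigenvalues, atol=1e-8
        )

    def test_dimension_mismatch(self, rng):
        mat = matrix_from_rows(rng.normal(size=(4, 9)), n_atoms=3)
        other = compute_modes(matrix_from_rows(rng.normal(size=(4, 6)), n_atoms=2), k=1)
        with pytest.raises(ValueError):
            project(mat, other)


class TestModeOverlap:
    def test_identical(self, rng):
        v = rng.normal(size=9)
        assert mode_overlap(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert mode_overlap([1, 0, 0], [0, 1, 0]) == 0.0

    def test_matches_hand_cosine(self, rng):
        v1 = rng.normal(size=7)
        v2 = rng.normal(size=7)
        num = sum(a * b for a, b in zip(v1, v2))
        den = (sum(a * a for a in v1) ** 0.5) * (sum(b * b for b in v2) ** 0.5)
        assert mode_overlap(v1, v2) == pytest.approx(abs(num) / den, abs=1e-12)

    def test_zero_vector_error(self):
        with pytest.raises(ValueError):
            mode_overlap(np.zeros(3), np.ones(3))


class TestResidueModeAmplitude:
    def test_single_triplet_closed_form(self):
        from ensdyn.essential_dynamics import ModeSet

        vec = np.zeros(9)
        vec[3:6] = (0.6, 0.8, 0.0)
        modes = ModeSet(
            mean_coords=np.zeros(9),
            vectors=vec[None],
            eigenvalues=np.array([4.0]),
            total_variance=4.0,
        )
        amp = residue_mode_amplitude(modes, 0)
        np.testing.assert_allclose(amp, [0.0, 2.0, 0.0], atol=1e-12)

    def test_sum_of_squares_equals_eigenvalue(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        modes = compute_modes(build_matrix(superpose_ensemble(ens)), k=3)
        for i in range(3):
            amp = residue_mode_amplitude(modes, i)
            assert np.sum(amp**2) == pytest.approx(modes.eigenvalues[i], rel=1e-8)

    def test_hinge_bend_amplitude_grows_with_distance(self):
        spec = SyntheticEnsembleSpec(
            twist_amplitude_sd=0.0, bend_amplitude_sd=0.08, noise_sd=0.0, seed=5
        )
        ens, truth = generate_two_domain_ensemble(spec)
        # Align on the fixed domain so the mode expresses pure motion of the
        # mobile domain about the hinge.
        sup = superpose_ensemble(ens, align_span=(1, spec.n_res_domain1))
        modes = compute_modes(build_matrix(sup), k=1)
        amp = residue_mode_amplitude(modes, 0)
        dom2 = amp[spec.n_res_domain1 :]
        dist = np.abs(np.arange(spec.n_res_domain2))
        r = np.corrcoef(dom2, dist)[0, 1]
        assert r > 0.95
        assert dom2[-1] > dom2[0]

    def test_index_out_of_range(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        modes = compute_modes(build_matrix(superpose_ensemble(ens)), k=1)
        with pytest.raises(IndexError):
            residue_mode_amplitude(modes, 1)


class TestClassifyConformers:
    def _two_domain_ensemble(self, distances):
        # Domain 1: residues 1-3 fixed around origin; domain 2: residues 4-6
        # at a per-model distance along x.
        m = len(distances)
        coords = np.zeros((m, 6, 3))
        d1 = np.array([[0.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        d2 = np.array([[0.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        for mi, dist in enumerate(distances):
            coords[mi, :3] = d1
            coords[mi, 3:] = d2 + np.array([dist, 0, 0])
        ens = StructuralEnsemble(coords=coords, atoms=make_atoms(6))
        from ensdyn.superpose import SuperposedEnsemble, RigidTransform

        return SuperposedEnsemble(
            ensemble=ens,
            transforms=[RigidTransform.identity()] * m,
            reference_index=0,
            rmsd_to_reference=np.zeros(m),
        )

    def test_two_models_split(self):
        sup = self._two_domain_ensemble([10.0, 20.0])
        labels = classify_conformers(sup, domain_split=3)
        assert labels.labels == ["closed", "open"]

    def test_median_threshold_definition(self):
        sup = self._two_domain_ensemble([1.0, 2.0, 3.0, 4.0])
        labels = classify_conformers(sup, domain_split=3)
        assert labels.threshold == pytest.approx(2.5)
        assert labels.labels == ["closed", "closed", "open", "open"]

    def test_identical_values_warn_all_open(self):
        sup = self._two_domain_ensemble([5.0, 5.0, 5.0])
        labels = classify_conformers(sup, domain_split=3)
        assert labels.labels == ["open"] * 3
        assert labels.warning is not None

    def test_bimodal_recovery(self):
        for seed in (1, 5, 9):
            spec = SyntheticEnsembleSpec(
                n_models=20,
                twist_amplitude_sd=0.05,
                bend_amplitude_sd=0.25,
                noise_sd=0.1,
                bimodal_bend=True,
                seed=seed,
            )
            ens, truth = generate_two_domain_ensemble(spec)
            labels = classify_conformers(
                superpose_ensemble(ens), domain_split=spec.n_res_domain1
            )
            agree = np.mean([a == b for a, b in zip(labels.labels, truth.labels)])
            assert max(agree, 1 - agree) >= 0.9

    def test_mode_projection_criterion(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        sup = superpose_ensemble(ens)
        labels = classify_conformers(sup, domain_split=60, criterion="mode_projection")
        assert set(labels.labels) == {"open", "closed"}

    def test_domain_split_outside_range(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        sup = superpose_ensemble(ens)
        with pytest.raises(ValueError):
            classify_conformers(sup, domain_split=500)


class TestGlobalMotionInvariance:
    def test_eigenvalues_and_labels_invariant(self, synthetic_ensemble):
        import math

        ens, _ = synthetic_ensemble
        t = math.radians(63.0)
        r = np.array(
            [
                [math.cos(t), 0, math.sin(t)],
                [0, 1, 0],
                [-math.sin(t), 0, math.cos(t)],
            ]
        )
        moved = ens.copy()
        moved.coords = moved.coords @ r.T + np.array([11.0, -4.0, 2.5])

        m1 = compute_modes(build_matrix(superpose_ensemble(ens)), k=4)
        m2 = compute_modes(build_matrix(superpose_ensemble(moved)), k=4)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-8)
        l1 = classify_conformers(superpose_ensemble(ens), domain_split=60)
        l2 = classify_conformers(superpose_ensemble(moved), domain_split=60)
        assert l1.labels == l2.labels


class TestNmdExport:
    def test_document_from_modes(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        sup = superpose_ensemble(ens)
        modes = compute_modes(build_matrix(sup), k=3)
        doc = to_nmd_document(modes, sup.ensemble, title="t")
        assert doc.n_atoms == ens.n_atoms
        assert len(doc.modes) == 3
        assert doc.modes[0][1] == pytest.approx(float(np.sqrt(modes.eigenvalues[0])))
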