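"""PCA, metastate clustering, sub-state decomposition and population accounting."""

import numpy as np
import pytest

from esiptkit.errors import DegenerateGeometryError, ParameterError, ValidationError
from esiptkit.geometry import DescriptorMatrix, evaluate_descriptors
from esiptkit.metastates import (
    MetastateModel,
    assign_frames,
    cluster_metastates,
    decompose_substates,
    fit_pca,
    population_report,
)
from esiptkit.synthetic import (
    LandscapeState,
    TorsionalLandscape,
    sample_landscape,
)


def _matrix(values, kinds=None, names=None):
    values = np.asarray(values, dtype=float)
    n_desc = values.shape[1]
    names = names or [f"x{i}" for i in range(n_desc)]
    kinds = kinds or ["distance"] * n_desc
    return DescriptorMatrix(
        frame_indices=np.arange(values.shape[0]),
        descriptor_names=names,
        kinds=kinds,
        values=values,
    )


def _torsion_matrix(torsions):
    return _matrix(torsions, kinds=["torsion", "torsion"], names=["dihedral_1", "dihedral_2"])


class TestFitPca:
    def test_single_varying_descriptor_gets_all_variance(self, rng):
        vals = np.column_stack([rng.uniform(-40, 40, 50), np.full(50, 7.0)])
        pca = fit_pca(_torsion_matrix(vals))
        assert pca.explained_variance_percent[0] == pytest.approx(100.0, abs=1e-9)

    def test_toy_eigenvalues_by_hand(self):
        # covariance eigenvalues of {(1,0),(−1,0),(0,.5),(0,−.5)} are 2/3 and 1/6
        pca = fit_pca(_matrix([[1, 0], [-1, 0], [0, 0.5], [0, -0.5]]))
        np.testing.assert_allclose(pca.explained_variance_percent, [80.0, 20.0], atol=1e-9)

    def test_loadings_orthonormal(self, rng):
        pca = fit_pca(_torsion_matrix(rng.uniform(-170, 170, size=(40, 2))))
        gram = pca.component_loadings.T @ pca.component_loadings
        np.testing.assert_allclose(gram, np.eye(pca.n_components), atol=1e-10)

    def test_explained_variance_sums_to_100_and_descends(self, rng):
        pca = fit_pca(_torsion_matrix(rng.uniform(-170, 170, size=(30, 2))))
        ev = pca.explained_variance_percent
        assert ev.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(ev) <= 1e-12)

    def test_reconstruction_from_all_components(self, rng):
        matrix = _torsion_matrix(rng.uniform(-90, 90, size=(25, 2)))
        pca = fit_pca(matrix)
        embedded = pca._embed(matrix)
        rebuilt = (
            pca.scores @ pca.component_loadings.T * pca.descriptor_scales
            + pca.descriptor_means
        )
        np.testing.assert_allclose(rebuilt, embedded, atol=1e-8)

    def test_sign_convention_fixes_largest_loading_positive(self, rng):
        pca = fit_pca(_torsion_matrix(rng.uniform(-170, 170, size=(30, 2))))
        for j in range(pca.n_components):
            col = pca.component_loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_sincos_embedding_expands_torsions(self, rng):
        pca = fit_pca(_torsion_matrix(rng.uniform(-170, 170, size=(30, 2))), embedding="sincos")
        assert pca.feature_names == [
            "dihedral_1_sin", "dihedral_1_cos", "dihedral_2_sin", "dihedral_2_cos",
        ]

    def test_seam_straddling_basin_is_not_torn(self, rng):
        # one basin centred exactly on ±180
        vals = np.column_stack(
            [
                np.where(rng.random(400) < 0.5, 1, -1) * 180 + rng.normal(0, 5, 400),
                rng.normal(0, 5, 400),
            ]
        )
        matrix = _torsion_matrix(vals)
        pca = fit_pca(matrix)
        embedded = pca._embed(matrix)[:, 0]
        assert embedded.max() - embedded.min() < 60  # one contiguous basin

    def test_zero_variance_matrix_raises(self):
        with pytest.raises(DegenerateGeometryError):
            fit_pca(_matrix(np.ones((10, 2))))

    def test_single_frame_raises(self):
        with pytest.raises(ValidationError):
            fit_pca(_matrix(np.ones((1, 2))))

    def test_mixed_kinds_scaled_to_unit_variance(self, rng):
        vals = np.column_stack([rng.uniform(-170, 170, 60), rng.uniform(2, 5, 60)])
        pca = fit_pca(
            _matrix(vals, kinds=["torsion", "distance"], names=["dihedral_1", "d_N_HO"])
        )
        assert not np.allclose(pca.descriptor_scales, 1.0)


def _three_state_matrix(n=300, seed=4, separation=110.0):
    landscape = TorsionalLandscape(
        states=[
            LandscapeState("a", 0.5, -separation, 0.0, 2000.0, 2000.0),
            LandscapeState("b", 0.3, 0.0, 0.0, 2000.0, 2000.0),
            LandscapeState("c", 0.2, separation, 0.0, 2000.0, 2000.0),
        ],
        n_frames=n,
        seed=seed,
    )
    torsions, labels = sample_landscape(landscape)
    return _torsion_matrix(torsions), labels


class TestClusterMetastates:
    def test_recovers_well_separated_populations_exactly(self):
        matrix, labels = _three_state_matrix()
        model = cluster_metastates(fit_pca(matrix), k=3, seed=0)
        import collections

        truth = collections.Counter(labels)
        assert sorted(model.populations.values()) == sorted(truth.values())

    def test_k1_gives_single_full_metastate(self, rng):
        model = cluster_metastates(
            fit_pca(_torsion_matrix(rng.uniform(-170, 170, size=(20, 2)))), k=1
        )
        assert model.population_fractions == {"1": pytest.approx(100.0)}

    def test_same_seed_reproduces_labels(self):
        matrix, _ = _three_state_matrix()
        pca = fit_pca(matrix)
        a = cluster_metastates(pca, k=3, seed=9)
        b = cluster_metastates(pca, k=3, seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_k_larger_than_frames_raises(self, rng):
        pca = fit_pca(_torsion_matrix(rng.uniform(-170, 170, size=(5, 2))))
        with pytest.raises(ParameterError):
            cluster_metastates(pca, k=6)

    def test_ids_ordered_by_descending_population(self):
        matrix, _ = _three_state_matrix()
        model = cluster_metastates(fit_pca(matrix), k=3, seed=0)
        pops = [model.populations[m] for m in ["1", "2", "3"]]
        assert pops == sorted(pops, reverse=True)

    def test_density_method_finds_separated_states(self):
        matrix, labels = _three_state_matrix()
        model = cluster_metastates(fit_pca(matrix), method="density")
        assert len(model.metastate_ids) == 3

    def test_fractions_sum_to_100(self):
        matrix, _ = _three_state_matrix()
        model = cluster_metastates(fit_pca(matrix), k=3, seed=0)
        assert sum(model.population_fractions.values()) == pytest.approx(100.0, abs=1e-9)

    def test_torsion_means_are_circular(self):
        # basin straddling the seam: arithmetic mean would be ~0, circular ±180
        vals = np.column_stack(
            [
                np.where(np.arange(100) % 2 == 0, 175.0, -175.0),
                np.full(100, 10.0),
            ]
        )
        model = cluster_metastates(fit_pca(_torsion_matrix(vals)), k=1)
        assert abs(model.descriptor_means["1"]["dihedral_1"]) == pytest.approx(180.0, abs=1e-6)

    def test_assign_frames_maps_new_data_to_nearest_metastate(self):
        matrix, labels = _three_state_matrix()
        pca = fit_pca(matrix)
        model = cluster_metastates(pca, k=3, seed=0)
        reassigned = assign_frames(model, pca, matrix)
        assert np.array_equal(reassigned, model.labels)


class TestDecomposeSubstates:
    def test_symmetric_bimodal_parent_splits_in_half(self):
        rng = np.random.default_rng(8)
        d1 = np.concatenate([rng.normal(-40, 4, 150), rng.normal(40, 4, 150)])
        vals = np.column_stack([d1, rng.normal(0, 4, 300)])
        # parent axis is PC1 here (only one metastate); decompose along it
        pca = fit_pca(_torsion_matrix(vals))
        model = cluster_metastates(pca, k=1)
        sub = decompose_substates(model, pca, axis=0)
        assert sub.populations["1A"] == 150
        assert sub.populations["1B"] == 150
        assert sub.hierarchy == {"1A": "1", "1B": "1"}

    def test_sub_ids_a_below_b_on_axis(self):
        rng = np.random.default_rng(8)
        vals = np.column_stack(
            [np.concatenate([rng.normal(-40, 4, 80), rng.normal(40, 4, 80)]),
             rng.normal(0, 4, 160)]
        )
        pca = fit_pca(_torsion_matrix(vals))
        sub = decompose_substates(cluster_metastates(pca, k=1), pca, axis=0)
        a = pca.scores[sub.labels == "1A", 0].mean()
        b = pca.scores[sub.labels == "1B", 0].mean()
        assert a < b

    def test_unimodal_parent_splits_near_median(self):
        rng = np.random.default_rng(3)
        vals = np.column_stack([rng.normal(0, 10, 201), rng.normal(0, 10, 201)])
        pca = fit_pca(_torsion_matrix(vals))
        sub = decompose_substates(cluster_metastates(pca, k=1), pca, axis=0)
        frac = sub.populations["1A"] / 201
        assert 0.35 < frac < 0.65

    def test_single_frame_parent_left_undivided_with_warning(self):
        vals = np.array([[0.0, 0.0], [1.0, 0.5], [120.0, 90.0]])
        pca = fit_pca(_torsion_matrix(vals))
        model = cluster_metastates(pca, k=2, seed=0)
        singleton = [m for m, c in model.populations.items() if c == 1][0]
        sub = decompose_substates(model, pca, axis=1)
        assert singleton in sub.populations
        assert any(singleton in w for w in sub.warnings)


class TestPopulationReport:
    @staticmethod
    def _model_from_counts(counts):
        labels = np.concatenate(
            [np.full(c, str(i + 1), dtype=object) for i, c in enumerate(counts)]
        )
        total = sum(counts)
        return MetastateModel(
            labels=labels,
            populations={str(i + 1): c for i, c in enumerate(counts)},
            population_fractions={str(i + 1): 100 * c / total for i, c in enumerate(counts)},
            descriptor_means={},
            centroids={},
        )

    def test_protein_system_counts(self):
        report = population_report(self._model_from_counts([6294, 1916, 1791]))
        assert list(report["percent"]) == [62.93, 19.16, 17.91]
        assert list(report["display_percent"]) == [63, 19, 18]
        ends = report["percent"][1] + report["percent"][2]
        assert ends == pytest.approx(37.07)
        assert round(ends) == 37

    def test_vacuum_system_counts(self):
        report = population_report(self._model_from_counts([5012, 4989]))
        assert list(report["percent"]) == [50.11, 49.89]

    def test_single_metastate_is_100(self):
        report = population_report(self._model_from_counts([77]))
        assert list(report["percent"]) == [100.0]

    def test_fractions_invariant_under_relabeling(self):
        a = population_report(self._model_from_counts([30, 20, 10]))
        b = population_report(self._model_from_counts([10, 30, 20]))
        assert sorted(a["percent"]) == sorted(b["percent"])
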