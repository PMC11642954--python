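import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccp import (
    ClusterScale,
    ExpressionMatrix,
    compute_eta,
    compute_rc,
    embed_new,
    fit_ccp,
    kernel,
    load_model,
    pairwise_cell_distances,
    project_cluster,
    save_model,
)
from conftest import random_expression

TAU1 = dict(tau=1.0, kappa=2.0)


def brute_force_supergene(x, ref, genes, scale):
    """Independent oracle: explicit double loop over cells and reference cells."""
    out = np.zeros(x.shape[0])
    for i in range(x.shape[0]):
        for m in range(ref.shape[0]):
            if scale.metric == "euclidean":
                d = np.sqrt(((x[i, genes] - ref[m, genes]) ** 2).sum())
            elif scale.metric == "manhattan":
                d = np.abs(x[i, genes] - ref[m, genes]).sum()
            else:
                d = np.abs(
                    np.sort(x[i, genes]) - np.sort(ref[m, genes])
                ).sum() / len(genes)
            if d == 0:
                out[i] += 1.0
            elif d < scale.r_c:
                out[i] += np.exp(-((d / (scale.eta * scale.tau)) ** scale.kappa))
    return out


class TestCellDistances:
    def test_one_gene_cluster(self, fixture3):
        d = pairwise_cell_distances(fixture3, np.array([0]))
        expected = np.array([[0.0, 1, 3], [1, 0, 2], [3, 2, 0]])
        np.testing.assert_allclose(d, expected)

    def test_manhattan_equals_euclidean_in_1d(self, fixture3):
        g = np.array([0])
        np.testing.assert_allclose(
            pairwise_cell_distances(fixture3, g, "euclidean"),
            pairwise_cell_distances(fixture3, g, "manhattan"),
        )

    def test_identical_cells_at_zero_distance(self):
        x = ExpressionMatrix(np.ones((4, 3)), stage="log_normalized")
        d = pairwise_cell_distances(x, np.arange(3))
        np.testing.assert_allclose(d, 0.0)

    def test_wasserstein_is_sorted_mean_absolute_difference(self):
        x = ExpressionMatrix(
            np.array([[3.0, 1.0], [2.0, 4.0]]), stage="log_normalized"
        )
        d = pairwise_cell_distances(x, np.arange(2), "wasserstein")
        # sorted cells (1,3) vs (2,4): W1 = (|1-2| + |3-4|)/2 = 1
        assert d[0, 1] == pytest.approx(1.0)

    def test_empty_gene_set_rejected(self, fixture3):
        with pytest.raises(ValueError, match="empty"):
            pairwise_cell_distances(fixture3, np.array([], dtype=int))


class TestScales:
    def test_eta_excludes_self_term(self, fixture3):
        d = pairwise_cell_distances(fixture3, np.array([0]))
        assert compute_eta(d) == pytest.approx(4.0 / 3.0)

    def test_eta_with_duplicate_cells(self):
        d = np.array([[0.0, 0.0, 5.0], [0.0, 0.0, 5.0], [5.0, 5.0, 0.0]])
        assert compute_eta(d) == pytest.approx(5.0 / 3.0)  # minima 0, 0, 5

    def test_rc_three_population_sigmas(self, fixture3):
        d = pairwise_cell_distances(fixture3, np.array([0]))
        assert compute_rc(d) == pytest.approx(3.0 * np.sqrt(2.0 / 3.0))

    def test_rc_zero_for_equidistant_cells(self):
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0.0)
        assert compute_rc(d) == 0.0

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_homogeneity_under_distance_scaling(self, fixture3, c):
        d = pairwise_cell_distances(fixture3, np.array([0]))
        assert compute_eta(c * d) == pytest.approx(c * compute_eta(d))
        assert compute_rc(c * d) == pytest.approx(c * compute_rc(d))


class TestKernel:
    scale = ClusterScale(eta=4.0 / 3.0, r_c=2.449489742783178, **TAU1)

    def test_limits(self):
        assert kernel(0.0, self.scale) == 1.0
        assert kernel(3.0, self.scale) == 0.0  # beyond cutoff
        assert kernel(self.scale.r_c, self.scale) == 0.0  # boundary is outside

    def test_closed_form(self):
        assert kernel(1.0, self.scale) == pytest.approx(np.exp(-0.5625), abs=1e-15)

    def test_strictly_decreasing_below_cutoff(self):
        d = np.linspace(0, self.scale.r_c - 1e-9, 200)
        phi = kernel(d, self.scale)
        assert (np.diff(phi) < 0).all()
        assert ((phi >= 0) & (phi <= 1)).all()

    def test_degenerate_scale_rejected(self):
        bad = ClusterScale(eta=0.0, r_c=1.0, **TAU1)
        with pytest.raises(ValueError, match="degenerate"):
            kernel(0.5, bad)

    @settings(derandomize=True, max_examples=50)
    @given(
        d=st.floats(0, 100, allow_nan=False),
        eta=st.floats(0.01, 10),
        tau=st.floats(0.1, 10),
        kappa=st.floats(0.2, 5),
        r_c=st.floats(0.01, 100),
    )
    def test_range_property(self, d, eta, tau, kappa, r_c):
        phi = kernel(d, ClusterScale(eta=eta, r_c=r_c, tau=tau, kappa=kappa))
        assert 0.0 <= phi <= 1.0
        if d >= r_c and d > 0:
            assert phi == 0.0


class TestProjectCluster:
    def test_worked_fixture_supergene(self, fixture3):
        scale = ClusterScale(eta=4.0 / 3.0, r_c=2.449489742783178, **TAU1)
        sg = project_cluster(fixture3, np.array([0]), scale)
        np.testing.assert_allclose(sg, [1.5698, 1.6752, 1.1054], atol=1e-4)

    def test_cell_beyond_cutoff_of_every_reference_is_zero(self):
        ref = np.array([[0.0], [1.0], [3.0]])
        scale = ClusterScale(eta=4.0 / 3.0, r_c=2.449489742783178, **TAU1)
        far = np.array([[100.0]])
        assert project_cluster(far, np.array([0]), scale, reference=ref) == 0.0

    def test_identical_cells_sum_to_cell_count(self):
        x = ExpressionMatrix(np.ones((5, 2)), stage="log_normalized")
        scale = ClusterScale(eta=1e-8, r_c=0.0, **TAU1)
        sg = project_cluster(x, np.arange(2), scale)
        np.testing.assert_allclose(sg, 5.0)


class TestFitAndEmbed:
    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "wasserstein"])
    def test_vectorized_matches_bruteforce(self, rng, metric):
        x = random_expression(rng, 20, 50)
        model, sg = fit_ccp(
            x, n_clusters=4, v_c=0.8, tau=2.0, kappa=2.0, metric=metric, seed=0
        )
        for n, (genes, scale) in enumerate(zip(model.partition.clusters, model.scales)):
            oracle = brute_force_supergene(x.values, x.values, genes, scale)
            np.testing.assert_allclose(sg.values[:, n], oracle, rtol=1e-10)

    def test_out_of_sample_matches_bruteforce(self, rng):
        x = random_expression(rng, 15, 30)
        y = random_expression(rng, 6, 30)
        model, _ = fit_ccp(x, n_clusters=3, v_c=0.9, seed=1)
        out = embed_new(model, y)
        for n, (genes, scale) in enumerate(zip(model.partition.clusters, model.scales)):
            oracle = brute_force_supergene(y.values, x.values, genes, scale)
            np.testing.assert_allclose(out.values[:, n], oracle, rtol=1e-10)

    def test_column_layout_with_and_without_lv(self, rng):
        x = random_expression(rng, 12, 20)
        _, sg = fit_ccp(x, n_clusters=3, v_c=0.8, seed=0)
        assert sg.column_labels[-1] == "LV" and len(sg.column_labels) == 4
        _, sg2 = fit_ccp(x, n_clusters=3, v_c=1.0, seed=0)
        assert len(sg2.column_labels) == 3 and "LV" not in sg2.column_labels

    def test_fit_is_deterministic(self, rng):
        x = random_expression(rng, 15, 25)
        _, a = fit_ccp(x, n_clusters=3, seed=5)
        _, b = fit_ccp(x, n_clusters=3, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_training_data_round_trip_is_bitwise(self, rng):
        x = random_expression(rng, 18, 30)
        model, sg = fit_ccp(x, n_clusters=3, v_c=0.8, seed=2)
        again = embed_new(model, x)
        assert np.array_equal(sg.values, again.values)

    def test_new_cell_identical_to_reference_scores_at_least_one(self, rng):
        x = random_expression(rng, 12, 20)
        model, _ = fit_ccp(x, n_clusters=2, v_c=0.9, seed=0)
        clone = ExpressionMatrix(
            x.values[[3]], cell_ids=["clone"], gene_ids=x.gene_ids, stage=x.stage
        )
        out = embed_new(model, clone)
        assert (out.values >= 1.0).all()  # the matching reference term is Phi(0)=1

    def test_fixture_out_of_sample_matches_training_twin(self, fixture3):
        model, sg = fit_ccp(
            fixture3, n_clusters=1, v_c=1.0 / 3.0, tau=1.0, kappa=2.0, seed=0
        )
        new = ExpressionMatrix(
            np.array([[1.0, 1.0, 1.0]]),
            cell_ids=["new"],
            gene_ids=fixture3.gene_ids,
            stage="log_normalized",
        )
        out = embed_new(model, new)
        # identical to training cell 2 -> same super-gene value
        assert out.values[0, 0] == pytest.approx(sg.values[1, 0])
        assert out.values[0, 0] == pytest.approx(1.6752, abs=1e-4)

    def test_missing_genes_are_reported(self, rng):
        x = random_expression(rng, 10, 8)
        model, _ = fit_ccp(x, n_clusters=2, v_c=1.0, seed=0)
        y = ExpressionMatrix(
            x.values[:, :5], gene_ids=x.gene_ids[:5], stage=x.stage
        )
        with pytest.raises(ValueError, match="missing"):
            embed_new(model, y)

    def test_raw_stage_refused_without_override(self, rng):
        x = random_expression(rng, 10, 8, stage="raw")
        with pytest.raises(ValueError, match="log-normalized"):
            fit_ccp(x, n_clusters=2)
        fit_ccp(x, n_clusters=2, v_c=1.0, require_log_stage=False)

    def test_permutation_equivariance(self, rng):
        x = random_expression(rng, 14, 20)
        model, sg = fit_ccp(x, n_clusters=3, v_c=0.8, seed=0)
        perm = rng.permutation(14)
        y = ExpressionMatrix(
            x.values[perm],
            cell_ids=[x.cell_ids[i] for i in perm],
            gene_ids=x.gene_ids,
            stage=x.stage,
        )
        out = embed_new(model, y)
        np.testing.assert_allclose(out.values, sg.values[perm], rtol=1e-12)

    def test_supergenes_nonnegative_and_bounded(self, rng):
        for _ in range(5):
            x = random_expression(rng, 15, 30)
            _, sg = fit_ccp(x, n_clusters=3, v_c=0.8, seed=0)
            assert (sg.values >= 0).all() and (sg.values <= x.n_cells).all()


def test_model_archive_round_trip(tmp_path, rng):
    x = random_expression(rng, 12, 18)
    model, sg = fit_ccp(x, n_clusters=2, v_c=0.8, seed=0)
    save_model(model, tmp_path / "model.zip")
    back = load_model(tmp_path / "model.zip")
    out = embed_new(back, x)
    np.testing.assert_allclose(out.values, sg.values, rtol=1e-12)
    assert back.gene_ids == model.gene_ids
    assert [s.eta for s in back.scales] == [s.eta for s in model.scales]
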