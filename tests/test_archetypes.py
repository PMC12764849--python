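import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from archetrack import (
    ConfigError,
    ConsensusConfig,
    ValidationError,
    archetype_proportions,
    cluster_to_k,
    consensus_select_k,
    dpe_wilcoxon,
    kmeans_cna_subclones,
    pac_from_consensus,
    reduce_svd,
    remove_batch_component,
)


def _frame(X):
    return pd.DataFrame(
        np.asarray(X, dtype=float), index=[f"c{i}" for i in range(len(X))]
    )


def _blobs(centers, n_per, scale=0.1, seed=0, dim=None):
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    dim = dim or centers.shape[1]
    X = np.vstack(
        [c + scale * rng.normal(size=(n_per, dim)) for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    return _frame(X), labels


class TestReduceSvd:
    def test_rank_one_data_keeps_single_component(self):
        t = np.linspace(-1, 1, 20)
        X = np.outer(t, [1.0, 2.0, -0.5])
        emb = reduce_svd(_frame(X), target=0.99)
        assert emb.coordinates.shape[1] == 1
        assert emb.variance_explained[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_needs_all_components(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(600, 3))
        emb = reduce_svd(_frame(X), target=0.90)
        # eigenvalue oracle: equal population variances => ~1/3 each, so two
        # components cannot reach 90%
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        assert np.cumsum(eigvals)[1] / eigvals.sum() < 0.90
        assert emb.coordinates.shape[1] == 3

    def test_full_retention_reconstructs_centered_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        emb = reduce_svd(_frame(X), target=1.0)
        recon = emb.coordinates.to_numpy() @ emb.loadings.to_numpy().T
        np.testing.assert_allclose(recon, X - X.mean(axis=0), atol=1e-8)

    def test_identical_rows_rejected(self):
        with pytest.raises(ValidationError):
            reduce_svd(_frame(np.ones((5, 3))))


class TestBatchRemoval:
    def _emb(self, X):
        return reduce_svd(_frame(X), target=1.0)

    def test_constructed_separation_removes_offset_component(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 4))
        batch = np.repeat(["a", "b"], 100)
        X[batch == "b", 1] += 4.0  # separation along one axis only
        emb = self._emb(X)
        # identify the embedding component aligned with axis 1
        align = np.abs(emb.loadings.to_numpy()[1])
        expected_comp = int(np.argmax(align))
        out = remove_batch_component(emb, batch)
        assert out.removed_component_index == expected_comp
        assert out.coordinates.shape[1] == emb.coordinates.shape[1] - 1

    def test_tie_breaks_to_lowest_index_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2000, 3))
        batch = np.repeat(["a", "b"], 1000)
        emb = self._emb(X)
        with caplog.at_level("WARNING"):
            out = remove_batch_component(emb, batch)
        assert out.removed_component_index is not None
        assert any("negligible" in r.message for r in caplog.records)

    def test_single_batch_is_noop_with_warning(self, caplog):
        emb = self._emb(np.random.default_rng(4).normal(size=(50, 3)))
        with caplog.at_level("WARNING"):
            out = remove_batch_component(emb, ["a"] * 50)
        assert out.removed_component_index is None
        assert out.coordinates.shape == emb.coordinates.shape

    def test_between_batch_distance_decreases(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 5))
        batch = np.repeat(["a", "b"], 150)
        X[batch == "b"] += np.array([0.1, 2.0, 0.0, 0.0, 0.1])
        emb = self._emb(X)
        out = remove_batch_component(emb, batch)

        def dist(e):
            Z = e.coordinates.to_numpy()
            return np.linalg.norm(
                Z[batch == "a"].mean(axis=0) - Z[batch == "b"].mean(axis=0)
            )

        assert dist(out) < dist(emb)


class TestConsensus:
    def test_pac_definition(self):
        assert pac_from_consensus([0, 0.05, 0.5, 0.95, 1]) == pytest.approx(0.2)

    def test_binary_consensus_has_zero_pac(self):
        rng = np.random.default_rng(0)
        assert pac_from_consensus(rng.integers(0, 2, 50)) == 0.0

    def test_two_point_masses_select_k2(self):
        X, _ = _blobs([[0, 0], [10, 10]], 60, scale=0.05, seed=1)
        res = consensus_select_k(
            X, ConsensusConfig(k_range=(2, 5), n_iterations=30, seed=0)
        )
        assert res.selected_k == 2
        assert res.pac[2] == pytest.approx(0.0)
        assert res.stability[2] == pytest.approx(1.0)

    def test_three_separated_gaussians_select_k3(self):
        X, _ = _blobs([[0, 0], [6, 0], [3, 6]], 200, scale=0.5, seed=2)
        res = consensus_select_k(
            X, ConsensusConfig(k_range=(2, 6), n_iterations=50, seed=0)
        )
        assert res.selected_k == 3
        assert res.pac[3] < min(v for k, v in res.pac.items() if k != 3)

    def test_k_range_validation(self):
        X, _ = _blobs([[0, 0]], 20, seed=3)
        with pytest.raises(ConfigError):
            consensus_select_k(X, ConsensusConfig(k_range=(2, 25)))

    def test_seed_determinism(self):
        X, _ = _blobs([[0, 0], [5, 5]], 40, seed=4)
        cfg = ConsensusConfig(k_range=(2, 4), n_iterations=20, seed=9)
        r1 = consensus_select_k(X, cfg)
        r2 = consensus_select_k(X, cfg)
        assert r1.pac == r2.pac and r1.selected_k == r2.selected_k


class TestClusterToK:
    def test_separable_masses_recovered_exactly(self):
        X, truth = _blobs([[0, 0], [8, 8]], 100, scale=0.3, seed=5)
        out = cluster_to_k(X, 2)
        assert adjusted_rand_score(truth, out.labels.to_numpy()) == 1.0

    def test_planted_three_clusters_high_ari(self):
        X, truth = _blobs([[0, 0, 0], [5, 0, 0], [0, 5, 0]], 120, scale=0.5, seed=6)
        out = cluster_to_k(X, 3)
        assert adjusted_rand_score(truth, out.labels.to_numpy()) >= 0.9

    def test_target_one_skips_graph(self):
        X, _ = _blobs([[0, 0]], 30, seed=7)
        out = cluster_to_k(X, 1)
        assert set(out.labels) == {0}
        assert out.resolution is None

    def test_target_above_n_rejected(self):
        X, _ = _blobs([[0, 0]], 5, seed=8)
        with pytest.raises(ValidationError):
            cluster_to_k(X, 10)


def exact_rank_sum_p(x, y):
    """Two-sided rank-sum p by full enumeration (tiny n only)."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    observed = ranks[: len(x)].sum()
    n = len(pooled)
    stats = [
        ranks[list(comb)].sum()
        for comb in itertools.combinations(range(n), len(x))
    ]
    stats = np.asarray(stats)
    center = len(x) * (n + 1) / 2
    return np.mean(np.abs(stats - center) >= np.abs(observed - center) - 1e-12)


class TestDpe:
    def _scores(self, shift):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(40, 6))
        base[:20, 0] += shift  # pathway 0 enriched in archetype 0
        frame = pd.DataFrame(
            base, index=[f"c{i}" for i in range(40)],
            columns=[f"pw{j}" for j in range(6)],
        )
        labels = pd.Series(np.repeat([0, 1], 20), index=frame.index)
        return frame, labels

    def test_shifted_pathway_ranks_first(self):
        frame, labels = self._scores(1.0)
        prof = dpe_wilcoxon(frame, labels)
        top0 = prof[prof["archetype"] == 0].iloc[0]
        assert top0["pathway"] == "pw0"
        assert top0["effect"] > 0.5

    def test_identical_pathway_never_profiled(self):
        frame, labels = self._scores(1.0)
        frame["flat"] = 1.0
        prof = dpe_wilcoxon(frame, labels)
        assert "flat" not in set(prof["pathway"])

    def test_top_n_truncation(self):
        frame, labels = self._scores(1.0)
        prof = dpe_wilcoxon(frame, labels, top_n=100)
        assert (prof.groupby("archetype").size() <= 6).all()
        assert (prof["effect"] > 0).all()

    def test_small_archetype_excluded(self, caplog):
        frame, labels = self._scores(1.0)
        labels.iloc[:2] = 7  # a 2-cell archetype
        with caplog.at_level("WARNING"):
            prof = dpe_wilcoxon(frame, labels)
        assert 7 not in set(prof["archetype"])

    def test_p_matches_enumeration_oracle_at_tiny_n(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=5) + 1.5
        y = rng.normal(size=5)
        frame = pd.DataFrame(
            {"pw": np.concatenate([x, y]), "other": rng.normal(size=10)},
            index=[f"c{i}" for i in range(10)],
        )
        labels = pd.Series(np.repeat([0, 1], 5), index=frame.index)
        prof = dpe_wilcoxon(frame, labels, top_n=10)
        got = prof[(prof["archetype"] == 0) & (prof["pathway"] == "pw")]["p"].iloc[0]
        assert got == pytest.approx(exact_rank_sum_p(x, y), abs=1e-9)


class TestProportions:
    def _meta(self, patients, cycles):
        n = len(patients)
        return pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "patient": patients,
                "cycle": cycles,
                "biopsy_site": ["s"] * n,
                "cell_type": ["epithelial"] * n,
                "ploidy": ["aneuploid"] * n,
                "n_features": [500] * n,
                "pct_mt": [1.0] * n,
            }
        )

    def test_single_archetype_is_always_one(self):
        meta = self._meta(["P1"] * 6, [1, 1, 2, 2, 3, 3])
        labels = pd.Series([0] * 6, index=meta["cell_id"])
        prop = archetype_proportions(labels, meta)
        assert (prop["proportion"] == 1.0).all()

    def test_fractions_sum_to_one_per_cycle(self):
        rng = np.random.default_rng(11)
        meta = self._meta(["P1"] * 300, list(np.repeat([1, 2, 3], 100)))
        labels = pd.Series(rng.integers(0, 3, 300), index=meta["cell_id"])
        prop = archetype_proportions(labels, meta)
        sums = prop.groupby(["patient", "cycle"])["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_uncovered_labels_rejected(self):
        meta = self._meta(["P1"] * 2, [1, 1])
        labels = pd.Series([0, 1, 0], index=["c0", "c1", "missing"])
        with pytest.raises(ValidationError):
            archetype_proportions(labels, meta)


class TestSubclones:
    def test_planted_profiles_recovered(self):
        rng = np.random.default_rng(12)
        prof_a = np.tile([2.0, 1.0], 10)
        prof_b = np.tile([1.0, 2.0], 10)
        X = np.vstack(
            [prof_a + 0.05 * rng.normal(size=20) for _ in range(30)]
            + [prof_b + 0.05 * rng.normal(size=20) for _ in range(30)]
        )
        labels = kmeans_cna_subclones(_frame(X), k=2, seed=0)
        truth = np.repeat([0, 1], 30)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_identical_profiles_seed_stable(self, caplog):
        X = _frame(np.ones((10, 4)))
        with caplog.at_level("WARNING"):
            l1 = kmeans_cna_subclones(X, k=2, seed=3)
        l2 = kmeans_cna_subclones(X, k=2, seed=3)
        pd.testing.assert_series_equal(l1, l2)

    def test_k_not_below_n(self):
        with pytest.raises(ValidationError):
            kmeans_cna_subclones(_frame(np.ones((3, 2))), k=3)

    def test_synthetic_cohort_subclones_recovered(self):
        """Binned expression of two planted CNA subclones clusters cleanly."""
        from archetrack import SimConfig, generate_cohort, lognormalize

        cfg = SimConfig(
            n_patients=1, cycles_per_patient=(2,), cells_per_cycle=150,
            n_genes=800, n_archetypes=2,
            mixing_schedule={"P1": [[0.5, 0.5]] * 2}, trend_slopes={},
            aneuploid_fraction=1.0, undefined_fraction=0.0,
            low_quality_fraction=0.0, high_mt_fraction=0.0, batch_shift=0.0,
            cna_segments=((400, 50, 3.0), (500, 50, 0.2)),
            subclone_cna_segments=((600, 50, 3.0), (700, 50, 0.2)),
            seed=21,
        )
        expr, meta, _, truth = generate_cohort(cfg)
        dense = lognormalize(expr).to_dense()
        # crude CNA proxy: mean log-expression over 50-gene bins
        bins = dense[:, : 790 // 50 * 50].reshape(dense.shape[0], -1, 50).mean(axis=2)
        labels = kmeans_cna_subclones(
            pd.DataFrame(bins, index=expr.cell_ids), k=2, seed=0
        )
        truth_codes = truth.subclone.map({"S1": 0, "S2": 1}).to_numpy()
        assert adjusted_rand_score(truth_codes, labels.to_numpy()) >= 0.9


def test_exchangeable_cells_never_look_stable():
    """A one-archetype cohort offers no structure: every k stays ambiguous
    (high PAC), unlike the near-zero PAC of a true planted K."""
    from archetrack import SimConfig, generate_cohort, lognormalize, ssgsea_scores

    cfg = SimConfig(
        n_patients=1, cycles_per_patient=(1,), cells_per_cycle=200,
        n_genes=800, n_archetypes=1, mixing_schedule={"P1": [[1.0]]},
        trend_slopes={}, aneuploid_fraction=1.0, undefined_fraction=0.0,
        low_quality_fraction=0.0, high_mt_fraction=0.0, batch_shift=0.0,
        seed=31,
    )
    expr, meta, sets, _ = generate_cohort(cfg)
    emb = reduce_svd(ssgsea_scores(lognormalize(expr), sets))
    res = consensus_select_k(
        emb, ConsensusConfig(k_range=(2, 5), n_iterations=40, seed=0)
    )
    assert min(res.pac.values()) > 0.3
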