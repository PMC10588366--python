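"""Cell filtering boundaries, PCA embedding determinism, SNN clustering
and the paired clustering evaluation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import dashbench as db


def _matrix(counts, feature_ids=None, barcodes=None):
    counts = np.asarray(counts)
    g = counts.shape[1]
    ids = feature_ids or [f"g{j}" for j in range(g)]
    feats = pd.DataFrame({"id": ids, "name": ids})
    bcs = np.array(barcodes or [f"b{i}" for i in range(counts.shape[0])],
                   dtype=object)
    return db.UMIMatrix(sp.csr_matrix(counts), bcs, feats)


def _cell(marker_count, n_genes_expressed, total=10_000, n_features=300):
    """One row with a given marker count and number of expressed genes."""
    row = np.zeros(n_features, dtype=int)
    row[0] = marker_count
    rest = total - marker_count
    k = n_genes_expressed - (1 if marker_count else 0)
    row[1:1 + k] = rest // k if k else 0
    row[1] += rest - (rest // k) * k if k else 0
    return row


class TestFilterCells:
    def _m(self, rows, barcodes=None):
        ids = ["piwi-1"] + [f"g{j}" for j in range(1, 300)]
        return _matrix(np.vstack(rows), feature_ids=ids, barcodes=barcodes)

    def test_exactly_200_genes_removed(self):
        # strictly "more than 200": a 200-gene cell fails
        m = self._m([_cell(400, 200), _cell(400, 201)])
        assert db.filter_cells(m, "piwi-1") == {"b1"}

    def test_marker_threshold_boundary_inclusive(self):
        # marker cp10k 315.2 -> log10(316.2) ~ 2.500: kept ('>= 2.5')
        hi = _cell(316, 250)
        lo = _cell(100, 250)   # log10(101) ~ 2.00: removed
        m = self._m([hi, lo])
        assert db.filter_cells(m, "piwi-1") == {"b0"}

    def test_paired_union_of_failures(self):
        good, bad = _cell(400, 250), _cell(400, 150)
        mu = self._m([good, bad], barcodes=["x", "y"])
        md = self._m([good, good], barcodes=["x", "y"])
        # y fails only in the untreated arm but is removed from both
        assert db.filter_cells(mu, "piwi-1", paired=md) == {"x"}
        assert db.filter_cells(md, "piwi-1", paired=mu) == {"x"}

    def test_missing_marker_is_error(self):
        with pytest.raises(KeyError):
            db.filter_cells(_matrix([[1, 2]]), "piwi-1")


class TestEmbed:
    def test_planted_axis_dominates_component_one(self):
        rng = np.random.default_rng(0)
        axis = np.repeat([0.0, 1.0], 50)
        counts = rng.poisson(5, size=(100, 60))
        counts[:, :20] += (axis[:, None] * 30).astype(int)
        emb = db.embed(_matrix(counts + 1), n_components=10)
        r = np.corrcoef(emb[:, 0], axis)[0, 1]
        assert abs(r) > 0.9

    def test_duplicated_rows_identical_embeddings(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(30, 40)) + 1
        dup = np.vstack([counts, counts[:5]])
        emb = db.embed(_matrix(dup), n_components=5)
        assert np.allclose(emb[:5], emb[30:], atol=1e-8)

    def test_zero_components_rejected(self):
        with pytest.raises(ValueError):
            db.embed(_matrix([[1, 2], [3, 4], [5, 6]]), n_components=0)

    def test_component_cap_warns_and_reduces(self, caplog):
        rng = np.random.default_rng(2)
        m = _matrix(rng.poisson(5, size=(6, 40)) + 1)
        with caplog.at_level("WARNING", logger="dashbench"):
            emb = db.embed(m, n_components=50)
        assert emb.shape[1] == 5
        assert "reducing" in caplog.text

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.poisson(5, size=(40, 30)) + 1)
        assert np.array_equal(db.embed(m, 10), db.embed(m, 10))


def _blobs(rng, centers, n_per, sd=0.3, dim=10):
    pts, labels = [], []
    for i, c in enumerate(centers):
        mu = np.zeros(dim)
        mu[: len(c)] = c
        pts.append(rng.normal(mu, sd, size=(n_per, dim)))
        labels += [i] * n_per
    return np.vstack(pts), np.array(labels)


class TestSNNCluster:
    def test_two_blobs_recovered_perfectly(self):
        rng = np.random.default_rng(4)
        emb, truth = _blobs(rng, [(0, 0), (8, 8)], 80)
        res = db.snn_cluster(emb, n_use=10, k=15, seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, res.labels) == 1.0
        assert res.n_clusters == 2

    def test_single_blob_one_cluster(self):
        rng = np.random.default_rng(5)
        emb, _ = _blobs(rng, [(0, 0)], 120)
        res = db.snn_cluster(emb, n_use=10, k=20, resolution=0.5, seed=0)
        assert res.n_clusters == 1

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(6)
        emb, _ = _blobs(rng, [(0, 0), (6, 0), (0, 6)], 50)
        a = db.snn_cluster(emb, n_use=10, k=15, seed=3)
        b = db.snn_cluster(emb, n_use=10, k=15, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_labels_size_ordered(self):
        rng = np.random.default_rng(7)
        emb, _ = _blobs(rng, [(0, 0), (9, 9)], 60)
        emb = np.vstack([emb, rng.normal((9, 9, 0, 0, 0, 0, 0, 0, 0, 0), 0.3,
                                         size=(30, 10))])
        res = db.snn_cluster(emb, n_use=10, k=15, seed=0)
        sizes = [int((res.labels == c).sum()) for c in range(res.n_clusters)]
        assert sizes == sorted(sizes, reverse=True)

    def test_k_must_be_below_cell_count(self):
        rng = np.random.default_rng(8)
        emb, _ = _blobs(rng, [(0, 0)], 10)
        with pytest.raises(ValueError):
            db.snn_cluster(emb, n_use=10, k=10, seed=0)

    def test_n_use_bounded_by_embedding(self):
        rng = np.random.default_rng(9)
        emb, _ = _blobs(rng, [(0, 0)], 50, dim=5)
        with pytest.raises(ValueError):
            db.snn_cluster(emb, n_use=20, k=10, seed=0)

    def test_cluster_count_nondecreasing_in_resolution(self):
        rng = np.random.default_rng(10)
        emb, _ = _blobs(rng, [(0, 0), (5, 0), (0, 5), (5, 5)], 40, sd=0.8)
        counts = [db.snn_cluster(emb, n_use=10, k=15, resolution=r,
                                 seed=0).n_clusters
                  for r in (0.1, 0.5, 1.0, 2.0)]
        assert counts == sorted(counts)


class TestCompareClusterings:
    def _result(self, labels, barcodes=None):
        n = len(labels)
        bcs = np.array(barcodes or [f"b{i}" for i in range(n)], dtype=object)
        return db.ClusterResult(bcs, np.asarray(labels), 10, 15, 0.5)

    def test_identical_labelings_ari_one(self):
        labels = np.array([0] * 10 + [1] * 10)
        truth = pd.Series(labels, index=[f"b{i}" for i in range(20)])
        rep = db.compare_clusterings(self._result(labels),
                                     self._result(labels), truth)
        assert rep["ari_untreated_vs_truth"] == 1.0
        assert rep["ari_untreated_vs_dashed"] == 1.0
        assert rep["n_types_recovered_untreated"] == 2

    def test_random_labels_near_zero_ari(self):
        rng = np.random.default_rng(11)
        truth_labels = rng.integers(0, 4, size=400)
        random_labels = rng.integers(0, 4, size=400)
        truth = pd.Series(truth_labels, index=[f"b{i}" for i in range(400)])
        rep = db.compare_clusterings(self._result(random_labels),
                                     self._result(truth_labels), truth)
        assert abs(rep["ari_untreated_vs_truth"]) < 0.05
        assert rep["ari_dashed_vs_truth"] == 1.0


@pytest.fixture(scope="module")
def bench_filtered_cells(bench_pair):
    """Shared stem cells passing the paired filter on the full-depth,
    contaminant-removed matrices."""
    cfg = bench_pair["cfg"]
    shared = bench_pair["shared"]
    mu = bench_pair["matrix_u"].subset_barcodes(shared) \
        .drop_feature(cfg.contaminant_name)
    md = bench_pair["matrix_d"].subset_barcodes(shared) \
        .drop_feature(cfg.contaminant_name)
    return sorted(db.filter_cells(mu, cfg.stem_marker_name, paired=md))


class TestBenchClustering:
    """Paired clustering on the bench-default simulation.

    The cell set is fixed at full depth; the arms are compared at a
    matched, deliberately limited read depth, where library complexity —
    not cell identity — is the binding constraint on cluster resolution.
    """

    def test_filter_keeps_only_stem_cells(self, bench_filtered_cells, bench_pair):
        truth = bench_pair["truth"]
        tl = pd.Series(truth.cell_types, index=truth.cell_barcodes)
        kept_types = tl.loc[[b for b in bench_filtered_cells if b in tl.index]]
        assert len(kept_types) == len(bench_filtered_cells)
        assert truth.type_is_stem[kept_types.to_numpy()].all()

    def test_depleted_arm_recovers_truth_at_least_as_well(
            self, bench_pair, bench_filtered_cells):
        cfg = bench_pair["cfg"]
        truth = bench_pair["truth"]
        feats = truth.features_frame()
        depth = 1_000_000
        results = []
        for arm, seed in (("untreated", 5), ("dashed", 6)):
            sub = db.downsample_reads(bench_pair[arm], depth, seed=seed)
            m = db.collapse_umis(sub, feats) \
                .subset_barcodes(bench_filtered_cells) \
                .drop_feature(cfg.contaminant_name)
            results.append(db.snn_cluster(db.embed(m), seed=0,
                                          barcodes=m.barcodes))
        tl = pd.Series(truth.cell_types, index=truth.cell_barcodes)
        rep = db.compare_clusterings(results[0], results[1], tl)
        assert rep["ari_dashed_vs_truth"] >= rep["ari_untreated_vs_truth"]
        assert rep["n_types_recovered_dashed"] >= rep["n_types_recovered_untreated"]
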