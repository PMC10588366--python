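"""Downsampling, UMI collapse, per-cell metrics, rarefaction, regression
and binned fold changes."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats as sps

import dashbench as db
from dashbench.containers import MoleculeTable


def _mols(rows):
    """rows: list of (barcode, feature, molecule, reads)."""
    df = pd.DataFrame(rows, columns=["barcode", "feature", "molecule", "reads"])
    df["barcode"] = df["barcode"].astype("category")
    df["feature"] = df["feature"].astype("category")
    return MoleculeTable(df).validate()


class TestDownsample:
    def test_full_depth_is_identity(self):
        m = _mols([("b1", "g1", 0, 5), ("b1", "g2", 1, 3)])
        out = db.downsample_reads(m, 8, seed=0)
        assert out.df[["molecule", "reads"]].equals(m.df[["molecule", "reads"]])

    def test_zero_depth_empty(self):
        m = _mols([("b1", "g1", 0, 5)])
        assert len(db.downsample_reads(m, 0, seed=0)) == 0

    def test_single_molecule_partial(self):
        m = _mols([("b1", "g1", 0, 5)])
        out = db.downsample_reads(m, 1, seed=0)
        assert len(out) == 1 and out.df.loc[0, "reads"] == 1

    def test_depth_above_total_is_error(self):
        with pytest.raises(ValueError):
            db.downsample_reads(_mols([("b1", "g1", 0, 5)]), 6)

    def test_reads_conserved_exactly(self):
        rng = np.random.default_rng(0)
        m = _mols([("b1", f"g{i}", i, int(r))
                   for i, r in enumerate(rng.integers(1, 20, size=200))])
        out = db.downsample_reads(m, 500, seed=1)
        assert out.total_reads == 500

    def test_two_step_equals_one_step_in_distribution(self):
        """Hypergeometric consistency on an exhaustively checkable table:
        chaining 8->5->3 reads must give the same molecule-level
        distribution as a single 8->3 draw (exact pmf from scipy)."""
        colors = np.array([4, 3, 1])
        n_rep = 4000
        rng = np.random.default_rng(42)
        two_step = np.zeros((n_rep, 3), dtype=int)
        for r in range(n_rep):
            mid = rng.multivariate_hypergeometric(colors, 5)
            two_step[r] = rng.multivariate_hypergeometric(mid, 3)
        outcomes, counts = np.unique(two_step, axis=0, return_counts=True)
        freq = counts / n_rep
        pmf = sps.multivariate_hypergeom(m=colors, n=3).pmf(outcomes)
        # each outcome's frequency within 4 binomial SEs of the exact pmf
        se = np.sqrt(pmf * (1 - pmf) / n_rep)
        assert (np.abs(freq - pmf) < 4 * se + 1e-12).all()


class TestCollapse:
    def test_two_molecules_one_gene(self):
        m = _mols([("b1", "g1", 0, 7), ("b1", "g1", 1, 1)])
        mat = db.collapse_umis(m)
        assert mat.counts.toarray().tolist() == [[2]]

    def test_empty_table(self):
        m = _mols([])
        assert db.collapse_umis(m).counts.nnz == 0

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(1)
        rows = [(f"b{rng.integers(4)}", f"g{rng.integers(6)}", i, 1)
                for i in range(300)]
        m = _mols(rows)
        mat = db.collapse_umis(m)
        oracle = m.df.groupby(["barcode", "feature"], observed=False)[
            "molecule"].nunique().unstack(fill_value=0)
        got = pd.DataFrame(mat.counts.toarray(), index=mat.barcodes,
                           columns=mat.features["id"])
        assert np.array_equal(got.loc[oracle.index, oracle.columns].to_numpy(),
                              oracle.to_numpy())

    def test_zero_count_features_keep_columns(self):
        df = pd.DataFrame({"barcode": pd.Categorical(["b1"]),
                           "feature": pd.Categorical(["g1"],
                                                     categories=["g1", "g2"]),
                           "molecule": [0], "reads": [1]})
        mat = db.collapse_umis(MoleculeTable(df))
        assert list(mat.features["id"]) == ["g1", "g2"]
        assert mat.counts.toarray().tolist() == [[1, 0]]


class TestPerCellMetrics:
    def _matrix(self):
        counts = np.array([[6, 2, 2],    # 60% contaminant, 3 genes
                           [10, 0, 0],   # pure contaminant
                           [0, 0, 0]])   # zero-UMI barcode
        feats = pd.DataFrame({"id": ["16S", "A", "B"],
                              "name": ["16S", "A", "B"]})
        return db.UMIMatrix(sp.csr_matrix(counts),
                            np.array(["b1", "b2", "b3"], dtype=object), feats)

    def test_hand_example(self):
        m = db.per_cell_metrics(self._matrix(), "16S")
        row = m.loc["b1"]
        assert (row["total_umis"], row["genes_detected"]) == (10, 3)
        assert row["pct_contaminant"] == pytest.approx(60.0)
        assert row["noncontaminant_umis"] == 4

    def test_pure_contaminant_barcode(self):
        row = db.per_cell_metrics(self._matrix(), "16S").loc["b2"]
        assert row["pct_contaminant"] == pytest.approx(100.0)
        assert row["noncontaminant_umis"] == 0

    def test_zero_umi_barcode_percentage_zero(self):
        row = db.per_cell_metrics(self._matrix(), "16S").loc["b3"]
        assert row["total_umis"] == 0 and row["pct_contaminant"] == 0.0

    def test_missing_barcode_flagged_with_zeros(self):
        m = db.per_cell_metrics(self._matrix(), "16S", ["b1", "nope"])
        assert bool(m.loc["nope", "missing"])
        assert m.loc["nope", "total_umis"] == 0

    def test_parts_sum_to_total(self, bench_pair):
        mu = bench_pair["metrics_u"]
        assert (mu["contaminant_umis"] + mu["noncontaminant_umis"]
                == mu["total_umis"]).all()
        assert (mu["genes_detected"]
                <= bench_pair["matrix_u"].n_features).all()


class TestRegression:
    def _metrics(self, values):
        return pd.DataFrame({"genes_detected": values},
                            index=[f"b{i}" for i in range(len(values))])

    def test_identity_line(self):
        x = self._metrics([1.0, 2, 3, 4])
        slope, intercept, r2 = db.paired_regression(x, x)
        assert (slope, r2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_affine_line(self):
        x = self._metrics([1.0, 2, 3, 4])
        y = self._metrics([5.0, 7, 9, 11])  # y = 2x + 3
        slope, intercept, r2 = db.paired_regression(x, y)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(3.0)
        assert r2 == pytest.approx(1.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(8)
        xv = rng.uniform(10, 100, size=50)
        yv = 1.3 * xv + rng.normal(0, 5, size=50)
        slope, intercept, r2 = db.paired_regression(
            self._metrics(xv), self._metrics(yv))
        xc = xv - xv.mean()
        beta = (xc * yv).sum() / (xc ** 2).sum()
        alpha = yv.mean() - beta * xv.mean()
        resid = yv - (alpha + beta * xv)
        r2_cf = 1 - (resid ** 2).sum() / ((yv - yv.mean()) ** 2).sum()
        assert slope == pytest.approx(beta)
        assert intercept == pytest.approx(alpha)
        assert r2 == pytest.approx(r2_cf)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            db.paired_regression(self._metrics([1, 2]), self._metrics([1, 2]))


class TestBinnedFoldChange:
    def _metrics(self, values):
        return pd.DataFrame({"genes_detected": np.asarray(values, float)},
                            index=[f"b{i}" for i in range(len(values))])

    def test_identical_arms_all_ratios_one(self):
        x = self._metrics(np.arange(1, 101))
        out = db.binned_fold_change(x, x)
        assert np.allclose(out["median_ratio"].dropna(), 1.0)

    def test_uniform_inflation(self):
        x = self._metrics(np.arange(1, 101))
        y = self._metrics(np.arange(1, 101) * 1.5)
        out = db.binned_fold_change(x, y)
        assert np.allclose(out["median_ratio"].dropna(), 1.5)

    def test_zero_untreated_excluded_and_counted(self):
        x = self._metrics([0, 0, 1, 2, 3, 4])
        out = db.binned_fold_change(x, x, n_bins=2)
        assert out.attrs["n_zero_untreated"] == 2
        assert out["n_cells"].sum() == 4


class TestDepletionEstimate:
    def test_exact_on_constructed_pair(self):
        feats = pd.DataFrame({"id": ["16S", "g"], "name": ["16S", "g"]})
        bcs = np.array(["b1"], dtype=object)
        mu = db.UMIMatrix(sp.csr_matrix(np.array([[600, 400]])), bcs, feats)
        md = db.UMIMatrix(sp.csr_matrix(np.array([[6, 400]])), bcs, feats)
        # odds drop 600/400 -> 6/400: eps = 1 - 0.01 = 0.99
        assert db.estimate_depletion(mu, md, "16S") == pytest.approx(0.99)
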