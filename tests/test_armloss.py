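"""Residual-expression segment-loss calling on simulated cells."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from editscope import armloss
from editscope.simulate import ScSimConfig, default_gene_table, gen_sc_matrices

TARGET = ("chr12", 6_538_000)


def _residual_from_values(values, genes, barcodes=None, window=1):
    """Wrap a dense residual matrix for segment/cluster functions."""
    return armloss.ResidualMatrix(
        values=np.asarray(values, dtype=float),
        genes=genes.reset_index(drop=True),
        barcodes=barcodes or [f"c{i}" for i in range(np.asarray(values).shape[1])],
        smooth_window_genes=window,
    )


@pytest.fixture(scope="module")
def planted():
    """500+500 cells, 20% telomeric one-copy loss, effect 0.5."""
    cfg = ScSimConfig(n_edited_cells=500, n_unedited_cells=500, loss_fraction=0.2, seed=5)
    edited, unedited, genes, truth = gen_sc_matrices(cfg)
    residuals = armloss.compute_residual(edited, unedited, genes, truth["barcode"].tolist())
    return residuals, truth


class TestQCFilter:
    def test_zero_count_and_high_mito_cells_removed(self):
        genes = default_gene_table()
        n_genes = len(genes)
        mito = genes["is_mito"].to_numpy()
        healthy = np.zeros(n_genes); healthy[~mito] = 10
        sick = np.zeros(n_genes); sick[mito] = 600; sick[~mito] = 3
        empty = np.zeros(n_genes)
        counts = sp.csr_matrix(np.stack([healthy, sick, empty], axis=1))
        kept, barcodes = armloss.qc_filter_cells(
            counts, genes, ["healthy", "sick", "empty"], min_counts=500
        )
        assert barcodes == ["healthy"]

    def test_all_in_bounds_unchanged(self):
        cfg = ScSimConfig(n_edited_cells=30, n_unedited_cells=5, seed=1)
        edited, _, genes, truth = gen_sc_matrices(cfg)
        kept, barcodes = armloss.qc_filter_cells(
            edited, genes, truth["barcode"].tolist(), min_counts=0, max_counts=10**9,
            max_mito_frac=1.0,
        )
        assert barcodes == truth["barcode"].tolist()
        assert (kept != edited).nnz == 0


class TestComputeResidual:
    def test_self_comparison_neutral(self):
        """Unedited-vs-unedited cohorts: per-gene mean residual stays at 1."""
        cfg = ScSimConfig(n_edited_cells=300, n_unedited_cells=300, loss_fraction=0.0, seed=2)
        edited, unedited, genes, truth = gen_sc_matrices(cfg)
        res = armloss.compute_residual(edited, unedited, genes, truth["barcode"].tolist())
        gene_means = res.values.mean(axis=1)
        assert gene_means.min() > 0.98 and gene_means.max() < 1.02

    def test_window_one_no_denoise_is_unsmoothed(self):
        cfg = ScSimConfig(n_edited_cells=10, n_unedited_cells=10, seed=3)
        edited, unedited, genes, truth = gen_sc_matrices(cfg)
        res = armloss.compute_residual(
            edited, unedited, genes, truth["barcode"].tolist(),
            smooth_window_genes=1, denoise_quantile=None,
        )
        # reproduce by hand on the position-ordered non-mito genes
        order = genes[~genes["is_mito"]].sort_values(["chrom", "start"], kind="stable").index
        e = np.asarray(edited.todense(), float)[order]
        u = np.asarray(unedited.todense(), float)[order]
        e = np.log1p(e / e.sum(axis=0) * 1e4)
        u = np.log1p(u / u.sum(axis=0) * 1e4)
        raw = e - u.mean(axis=1, keepdims=True)
        raw = raw - np.median(raw, axis=0, keepdims=True)
        np.testing.assert_allclose(res.values, np.exp(raw), rtol=1e-12)

    def test_deep_loss_pushes_segment_below_threshold(self, planted):
        residuals, truth = planted
        table = armloss.segment_means(residuals, *TARGET)
        merged = table.cells.merge(truth, on="barcode")
        loss_means = merged.loc[merged["is_loss"], "telomeric_mean"]
        assert (loss_means < 0.95).mean() > 0.9

    def test_mismatched_gene_axis_rejected(self):
        genes = default_gene_table()
        with pytest.raises(ValueError, match="gene axis"):
            armloss.compute_residual(
                sp.csr_matrix((len(genes) - 1, 3)), sp.csr_matrix((len(genes), 3)),
                genes, ["a", "b", "c"],
            )


class TestSegmentMeans:
    def _toy_genes(self):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(6)],
                "chrom": ["chr12"] * 5 + ["chr1"],
                "start": [1_000_000, 3_000_000, 6_538_000, 8_000_000, 20_000_000, 500],
            }
        )

    def test_all_ones_gives_unit_means(self):
        res = _residual_from_values(np.ones((6, 3)), self._toy_genes())
        table = armloss.segment_means(res, *TARGET)
        assert (table.cells["telomeric_mean"] == 1.0).all()
        assert (table.cells["comparison_mean"] == 1.0).all()

    def test_telomeric_only_depression(self):
        values = np.ones((6, 2))
        values[:2] = 0.5  # the two genes before the target site
        res = _residual_from_values(values, self._toy_genes())
        table = armloss.segment_means(res, *TARGET)
        assert (table.cells["telomeric_mean"] == 0.5).all()
        assert (table.cells["comparison_mean"] == 1.0).all()

    def test_boundary_gene_in_comparison_segment(self):
        """A gene exactly at the target site belongs to the comparison side."""
        values = np.ones((6, 1))
        values[2] = 0.0  # the gene at exactly 6,538,000
        res = _residual_from_values(values, self._toy_genes())
        table = armloss.segment_means(res, *TARGET)
        assert table.cells["telomeric_mean"].iloc[0] == 1.0
        # comparison segment holds the genes at 6,538,000 and 8,000,000 only
        assert table.cells["comparison_mean"].iloc[0] == pytest.approx(0.5)

    def test_empty_segment_errors(self):
        genes = self._toy_genes()
        res = _residual_from_values(np.ones((6, 1)), genes)
        with pytest.raises(ValueError, match="telomeric"):
            armloss.segment_means(res, "chr12", 500_000)


class TestCallLoss:
    @pytest.mark.parametrize("mean,flagged", [(0.949, True), (0.95, False)])
    def test_strictly_below_threshold(self, mean, flagged):
        table = armloss.SegmentCallTable(
            cells=pd.DataFrame(
                {"barcode": ["c0"], "telomeric_mean": [mean], "comparison_mean": [1.0]}
            )
        )
        called = armloss.call_loss(table)
        assert bool(called.cells["loss"].iloc[0]) is flagged

    def test_frequency_enumeration(self):
        means = [0.5] * 20 + [1.0] * 80
        table = armloss.SegmentCallTable(
            cells=pd.DataFrame(
                {
                    "barcode": [f"c{i}" for i in range(100)],
                    "telomeric_mean": means,
                    "comparison_mean": [1.0] * 100,
                }
            )
        )
        assert armloss.call_loss(table).loss_frequency == pytest.approx(0.20)


class TestClusterCells:
    def test_planted_populations_separate(self, planted):
        residuals, truth = planted
        labels, order, heatmap = armloss.cluster_cells(residuals, *TARGET)
        m = pd.DataFrame({"barcode": residuals.barcodes, "cluster": labels}).merge(
            truth, on="barcode"
        )
        agreement = max((m["is_loss"] == (m["cluster"] == c)).mean() for c in (1, 2))
        assert agreement >= 0.95
        assert heatmap.shape[0] == len(residuals.barcodes)

    def test_deterministic(self, planted):
        residuals, _ = planted
        a = armloss.cluster_cells(residuals, *TARGET)
        b = armloss.cluster_cells(residuals, *TARGET)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()

    def test_identical_cells_zero_height(self):
        genes = pd.DataFrame(
            {"gene_id": ["g0", "g1"], "chrom": ["chr12"] * 2, "start": [1, 2]}
        )
        res = _residual_from_values(np.ones((2, 5)), genes)
        labels, order, _ = armloss.cluster_cells(res, *TARGET)
        assert len(set(labels)) == 1  # no structure to split


class TestCohortProperties:
    def test_recovery_within_band(self, planted):
        residuals, truth = planted
        table = armloss.call_loss(armloss.segment_means(residuals, *TARGET))
        assert table.loss_frequency == pytest.approx(0.20, abs=0.03)

    def test_null_false_positive_rate_bounded(self):
        cfg = ScSimConfig(n_edited_cells=400, n_unedited_cells=400, loss_fraction=0.0, seed=6)
        edited, unedited, genes, truth = gen_sc_matrices(cfg)
        res = armloss.compute_residual(edited, unedited, genes, truth["barcode"].tolist())
        table = armloss.call_loss(armloss.segment_means(res, *TARGET))
        assert table.loss_frequency <= 0.05

    def test_deeper_loss_never_detected_less(self):
        freqs = []
        for effect in (0.9, 0.7, 0.5):
            cfg = ScSimConfig(
                n_edited_cells=200, n_unedited_cells=200, loss_fraction=0.3,
                loss_effect=effect, seed=7,
            )
            edited, unedited, genes, truth = gen_sc_matrices(cfg)
            res = armloss.compute_residual(edited, unedited, genes, truth["barcode"].tolist())
            freqs.append(
                armloss.call_loss(armloss.segment_means(res, *TARGET)).loss_frequency
            )
        assert freqs == sorted(freqs)

    def test_residual_neutrality_off_segment(self, planted):
        residuals, truth = planted
        nonloss = ~truth["is_loss"].to_numpy()
        off = residuals.genes["chrom"].to_numpy() != "chr12"
        med = np.median(residuals.values[np.ix_(off, nonloss)])
        assert 0.97 <= med <= 1.03
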