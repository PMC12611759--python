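"""Chromosome-segment expression-loss calling from single-cell counts.

Monoallelic loss of a chromosomal segment halves the DNA dosage of every
gene inside it, which depresses their expression coherently. Given a
gene x cell count matrix of edited cells and a matched unedited reference,
the module reconstructs a *residual relative expression* per gene and
edited cell: library-size-normalized, log1p-transformed expression with
the unedited-cell mean subtracted per gene, smoothed along each
chromosome with a centered moving average over neighbouring genes, and
exponentiated back so that the neutral baseline is 1.0 and a one-copy
segment loss appears as a coherent block of values near 0.5.

Residuals are *denoised* against the unedited reference before the
exponentiation: the unedited cells are passed through the identical
normalize/subtract/smooth processing against their own mean, giving a
per-gene empirical null distribution of smoothed residuals, and any
edited-cell smoothed residual inside the central
``[denoise_quantile, 1 - denoise_quantile]`` band of that null is set
to zero (neutral). Quantile bands track the left-skewed dropout tail of
single-cell noise that a symmetric standard-deviation band misses. Without this step the
segment means of perfectly diploid cells fluctuate far past the call
threshold under ordinary single-cell sampling noise; with it, neutral
segments sit at 1.0 and only coherent dosage shifts survive.

Per cell, the mean residual over the telomeric segment (chromosome start
up to the target site) and over a comparison segment downstream of the
target site (7 Mb by default) is computed; a cell whose segment mean
falls strictly below a threshold (default 0.95) is called a loss cell,
and the cohort loss frequency is the flagged fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage


@dataclass
class ResidualMatrix:
    """Genes (position-ordered) x edited-cells residual relative expression."""

    values: np.ndarray  # genes x cells, neutral baseline 1.0
    genes: pd.DataFrame  # gene_id, chrom, start — ordered by (chrom, start)
    barcodes: list[str]
    smooth_window_genes: int


@dataclass
class SegmentCallTable:
    """Per-cell segment means, loss flags and the cohort loss frequency."""

    cells: pd.DataFrame  # barcode, telomeric_mean, comparison_mean[, loss]
    threshold: float | None = None

    @property
    def loss_frequency(self) -> float:
        if "loss" not in self.cells.columns:
            raise ValueError("call_loss has not been applied")
        return float(self.cells["loss"].mean())


def qc_filter_cells(
    counts: sp.spmatrix,
    genes: pd.DataFrame,
    barcodes: list[str],
    min_counts: int = 500,
    max_counts: int = 50_000,
    max_mito_frac: float = 0.2,
) -> tuple[sp.csr_matrix, list[str]]:
    """Drop empty droplets, suspected doublets and high-mito (unhealthy) cells.

    Cells with total counts outside [min_counts, max_counts] or with a
    mitochondrial read fraction above ``max_mito_frac`` are removed.
    """
    counts = sp.csr_matrix(counts)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    mito_mask = genes["is_mito"].to_numpy(dtype=bool)
    mito = np.asarray(counts[mito_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 1.0)
    keep = (totals >= min_counts) & (totals <= max_counts) & (mito_frac <= max_mito_frac)
    kept_barcodes = [b for b, k in zip(barcodes, keep) if k]
    return counts[:, keep], kept_barcodes


def _normalize_log(counts: sp.csr_matrix, target_sum: float = 1e4) -> np.ndarray:
    """Per-cell library-size normalization to ``target_sum``, then log1p."""
    dense = np.asarray(counts.todense(), dtype=float)
    totals = dense.sum(axis=0)
    totals[totals == 0] = 1.0
    return np.log1p(dense / totals * target_sum)


def _smooth_along_chromosomes(
    values: np.ndarray, chroms: np.ndarray, window: int
) -> np.ndarray:
    """Centered moving average over position-ordered genes, per chromosome.

    Edge genes use shrinking windows (the average over however many of the
    ``window`` neighbours fall on the same chromosome).
    """
    if window <= 1:
        return values
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    out = np.empty_like(values)
    kernel = np.ones(window)
    for chrom in pd.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        block = values[idx]
        sums = np.apply_along_axis(
            lambda col: np.convolve(col, kernel, mode="same"), 0, block
        )
        counts = np.convolve(np.ones(len(idx)), kernel, mode="same")
        out[idx] = sums / counts[:, None]
    return out


def compute_residual(
    edited: sp.spmatrix,
    unedited: sp.spmatrix,
    genes: pd.DataFrame,
    edited_barcodes: list[str],
    smooth_window_genes: int = 51,
    denoise_quantile: float | None = 0.005,
    exclude_mito: bool = True,
) -> ResidualMatrix:
    """Residual relative expression of edited cells against the unedited mean.

    Both matrices must share the gene axis described by ``genes``
    (gene_id, chrom, start, is_mito). Genes are sorted by (chrom, start);
    per gene the unedited-cell mean log-expression is subtracted from each
    edited cell, the residual is smoothed along the chromosome, denoised
    against the unedited cells' own smoothed-residual null (unless
    ``denoise_quantile`` is None), and exp(residual) is returned so
    neutral dosage sits at 1.0.
    """
    if edited.shape[0] != len(genes) or unedited.shape[0] != len(genes):
        raise ValueError("edited/unedited gene axis does not match the annotation table")
    if unedited.shape[1] < 1:
        raise ValueError("need at least one unedited cell")
    genes = genes.reset_index(drop=True).copy()
    if exclude_mito and "is_mito" in genes.columns:
        keep = ~genes["is_mito"].to_numpy(dtype=bool)
        edited = sp.csr_matrix(edited)[keep]
        unedited = sp.csr_matrix(unedited)[keep]
        genes = genes.loc[keep].reset_index(drop=True)
    order = genes.sort_values(["chrom", "start"], kind="stable").index.to_numpy()
    genes = genes.iloc[order].reset_index(drop=True)
    edited_log = _normalize_log(sp.csr_matrix(edited)[order])
    unedited_log = _normalize_log(sp.csr_matrix(unedited)[order])
    unedited_mean = unedited_log.mean(axis=1, keepdims=True)
    chroms = genes["chrom"].to_numpy()
    smoothed = _smooth_along_chromosomes(
        edited_log - unedited_mean, chroms, smooth_window_genes
    )
    # per-cell median centering: removes global depth/size shifts without
    # touching a minority segment's coherent dosage signal
    smoothed = smoothed - np.median(smoothed, axis=0, keepdims=True)
    if denoise_quantile is not None:
        if unedited_log.shape[1] < 2:
            raise ValueError("denoising needs at least two unedited cells")
        null = _smooth_along_chromosomes(
            unedited_log - unedited_mean, chroms, smooth_window_genes
        )
        null = null - np.median(null, axis=0, keepdims=True)
        lo = np.quantile(null, denoise_quantile, axis=1, keepdims=True)
        hi = np.quantile(null, 1.0 - denoise_quantile, axis=1, keepdims=True)
        smoothed = np.where((smoothed >= lo) & (smoothed <= hi), 0.0, smoothed)
    return ResidualMatrix(
        values=np.exp(smoothed),
        genes=genes,
        barcodes=list(edited_barcodes),
        smooth_window_genes=smooth_window_genes,
    )


def segment_means(
    residuals: ResidualMatrix,
    target_chrom: str,
    target_site_bp: int,
    comparison_extent_bp: int = 7_000_000,
) -> SegmentCallTable:
    """Per-cell mean residual over the telomeric and comparison segments.

    Telomeric segment: genes on ``target_chrom`` with start < target site.
    Comparison segment: genes with target site <= start < target site +
    extent (half-open on both boundaries, so the gene at the target site
    itself belongs to the comparison segment).
    """
    genes = residuals.genes
    on_chrom = genes["chrom"].to_numpy() == target_chrom
    starts = genes["start"].to_numpy()
    telo = on_chrom & (starts < target_site_bp)
    comp = on_chrom & (starts >= target_site_bp) & (starts < target_site_bp + comparison_extent_bp)
    if telo.sum() == 0:
        raise ValueError(f"no genes in telomeric segment of {target_chrom} before {target_site_bp}")
    if comp.sum() == 0:
        raise ValueError(f"no genes in comparison segment of {target_chrom} after {target_site_bp}")
    cells = pd.DataFrame(
        {
            "barcode": residuals.barcodes,
            "telomeric_mean": residuals.values[telo].mean(axis=0),
            "comparison_mean": residuals.values[comp].mean(axis=0),
        }
    )
    return SegmentCallTable(cells=cells)


def call_loss(
    table: SegmentCallTable, threshold: float = 0.95, segment: str = "telomeric_mean"
) -> SegmentCallTable:
    """Flag cells whose segment mean is strictly below the threshold."""
    cells = table.cells.copy()
    cells["loss"] = cells[segment] < threshold
    return SegmentCallTable(cells=cells, threshold=threshold)


def cluster_cells(
    residuals: ResidualMatrix,
    target_chrom: str,
    target_site_bp: int,
    n_clusters: int = 2,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Ward hierarchical clustering on telomeric-segment residuals.

    Cells are clustered (Ward linkage, Euclidean distance — deterministic
    given the input) on their residuals restricted to genes up to the
    target site. Returns (labels, leaf order, heatmap matrix) where the
    heatmap frame is cells-in-dendrogram-order x position-ordered genes.
    """
    genes = residuals.genes
    mask = (genes["chrom"].to_numpy() == target_chrom) & (
        genes["start"].to_numpy() < target_site_bp
    )
    if mask.sum() == 0:
        raise ValueError("no genes upstream of the target site to cluster on")
    X = residuals.values[mask].T  # cells x genes
    if X.shape[0] < 2:
        labels = np.ones(X.shape[0], dtype=int)
        order = np.arange(X.shape[0])
    else:
        Z = linkage(X, method="ward")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
        order = leaves_list(Z)
    chrom_mask = genes["chrom"].to_numpy() == target_chrom
    heatmap = pd.DataFrame(
        residuals.values[chrom_mask].T[order],
        index=[residuals.barcodes[i] for i in order],
        columns=genes.loc[chrom_mask, "gene_id"].to_list(),
    )
    return labels, order, heatmap
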