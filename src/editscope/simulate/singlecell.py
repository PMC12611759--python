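"""Edited / unedited single-cell count-matrix simulator.

Per-gene baseline means are drawn log-uniformly and counts are negative
binomial (mean mu, variance mu + dispersion * mu^2), i.i.d. across cells.
A configurable fraction of *edited* cells carries a monoallelic loss of a
chromosomal segment: every gene inside ``loss_segment`` has its mean
multiplied by ``loss_effect`` (0.5 = one copy of two lost). Mitochondrial
genes are included so QC filtering is exercisable. Ground-truth loss
labels are returned per edited cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


def default_gene_table(
    target_chrom: str = "chr12",
    n_target_chrom: int = 220,
    target_chrom_span_bp: int = 25_000_000,
    n_other: int = 80,
    n_mito: int = 13,
    seed: int = 20_240_101,
) -> pd.DataFrame:
    """A synthetic gene annotation panel for simulations.

    Genes on the target chromosome are spread uniformly over
    ``target_chrom_span_bp`` (deterministically, fixed seed), plus a
    block of off-target-chromosome genes and mitochondrial genes.
    """
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(10_000, target_chrom_span_bp, size=n_target_chrom))
    rows = [
        {"gene_id": f"G{target_chrom}_{i:04d}", "chrom": target_chrom, "start": int(s), "is_mito": False}
        for i, s in enumerate(starts)
    ]
    other_starts = np.sort(rng.integers(10_000, 100_000_000, size=n_other))
    rows += [
        {"gene_id": f"Gchr1_{i:04d}", "chrom": "chr1", "start": int(s), "is_mito": False}
        for i, s in enumerate(other_starts)
    ]
    rows += [
        {"gene_id": f"MT-{i:02d}", "chrom": "chrM", "start": 100 + 500 * i, "is_mito": True}
        for i in range(n_mito)
    ]
    return pd.DataFrame(rows)


@dataclass
class ScSimConfig:
    """Configuration for :func:`gen_sc_matrices`."""

    gene_table: pd.DataFrame = field(default_factory=default_gene_table)
    n_edited_cells: int = 500
    n_unedited_cells: int = 500
    loss_fraction: float = 0.0
    loss_segment: tuple[str, int, int] = ("chr12", 0, 6_538_000)
    loss_effect: float = 0.5
    nb_mean_range: tuple[float, float] = (0.5, 20.0)
    nb_dispersion: float = 0.3
    sampling: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.loss_effect <= 1.0):
            raise ValueError("loss_effect must be in (0, 1]")
        if not (0.0 <= self.loss_fraction <= 1.0):
            raise ValueError("loss_fraction must be in [0, 1]")
        required = {"gene_id", "chrom", "start"}
        if not required <= set(self.gene_table.columns):
            raise ValueError(f"gene_table needs columns {sorted(required)}")


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float, n_cells: int
) -> np.ndarray:
    """Negative-binomial counts, genes x cells, var = mu + dispersion mu^2."""
    if dispersion <= 0:
        return rng.poisson(means[:, None], size=(len(means), n_cells))
    r = 1.0 / dispersion
    p = r / (r + means)
    return rng.negative_binomial(r, p[:, None], size=(len(means), n_cells))


def gen_sc_matrices(
    cfg: ScSimConfig,
) -> tuple[sp.csr_matrix, sp.csr_matrix, pd.DataFrame, pd.DataFrame]:
    """Simulate edited and unedited count matrices with loss ground truth.

    Returns (edited, unedited, genes, truth): matrices are genes x cells;
    ``truth`` has one row per edited cell (barcode, is_loss). The loss
    set is an exact count round(n_edited * loss_fraction) by default.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_table.reset_index(drop=True).copy()
    if "is_mito" not in genes.columns:
        genes["is_mito"] = genes["chrom"].isin(["chrM", "MT"])
    n_genes = len(genes)
    lo, hi = cfg.nb_mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))

    chrom, seg_lo, seg_hi = cfg.loss_segment
    in_segment = (
        (genes["chrom"].to_numpy() == chrom)
        & (genes["start"].to_numpy() >= seg_lo)
        & (genes["start"].to_numpy() < seg_hi)
    )

    if cfg.sampling:
        is_loss = rng.random(cfg.n_edited_cells) < cfg.loss_fraction
    else:
        n_loss = round(cfg.n_edited_cells * cfg.loss_fraction)
        is_loss = np.zeros(cfg.n_edited_cells, dtype=bool)
        is_loss[rng.permutation(cfg.n_edited_cells)[:n_loss]] = True

    edited = np.empty((n_genes, cfg.n_edited_cells), dtype=np.int64)
    normal = _nb_counts(rng, means, cfg.nb_dispersion, cfg.n_edited_cells)
    loss_means = np.where(in_segment, means * cfg.loss_effect, means)
    lost = _nb_counts(rng, loss_means, cfg.nb_dispersion, cfg.n_edited_cells)
    edited[:, ~is_loss] = normal[:, ~is_loss]
    edited[:, is_loss] = lost[:, is_loss]
    unedited = _nb_counts(rng, means, cfg.nb_dispersion, cfg.n_unedited_cells)

    edited_barcodes = [f"ED-{i:05d}" for i in range(cfg.n_edited_cells)]
    truth = pd.DataFrame({"barcode": edited_barcodes, "is_loss": is_loss})
    return (
        sp.csr_matrix(edited),
        sp.csr_matrix(unedited),
        genes,
        truth,
    )
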