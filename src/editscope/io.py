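"""Shared readers and writers.

FASTQ parsing goes through Bio.SeqIO (gzip handled transparently); FASTQ
*writing* is done by hand so that simulator output is byte-reproducible.
Sparse count matrices use the 10x-style triplet layout: ``matrix.mtx`` +
``genes.tsv`` (gene_id, chrom, start, is_mito) + ``barcodes.tsv``.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO


@dataclass
class Read:
    """A sequencing read; quality is kept but never used by the analyses."""

    id: str
    seq: str
    qual: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> list[Read]:
    """Read a FASTQ or FASTQ.gz file into a list of reads.

    Sequences are upper-cased; characters outside {A,C,G,T,N} raise.
    Truncated records are reported with an approximate line number.
    """
    path = Path(path)
    reads: list[Read] = []
    n_bases_n = 0
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                seq = str(rec.seq).upper()
                bad = set(seq) - set("ACGTN")
                if bad:
                    raise ValueError(
                        f"{path}: read {rec.id} has invalid characters {sorted(bad)}"
                    )
                n_bases_n += seq.count("N")
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
                reads.append(Read(rec.id, seq, qual))
        except ValueError as e:
            if "invalid characters" in str(e):
                raise
            raise ValueError(
                f"{path}: malformed FASTQ near record {len(reads) + 1} "
                f"(~line {4 * len(reads) + 1}): {e}"
            ) from e
    if n_bases_n:
        print(f"[editscope] {path.name}: {n_bases_n} N bases", file=sys.stderr)
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as FASTQ (gzip if the path ends in .gz), byte-stable."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", newline="\n") as fh:  # type: ignore[operator]
        for r in reads:
            qual = r.qual if r.qual is not None else "5" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def write_matrix_dir(
    counts: sp.spmatrix,
    genes: pd.DataFrame,
    barcodes: list[str],
    outdir: str | Path,
) -> None:
    """Write a genes x cells count matrix as matrix.mtx + genes.tsv + barcodes.tsv.

    ``genes`` needs columns gene_id, chrom, start and optionally is_mito.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = sp.coo_matrix(counts)
    if counts.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {counts.shape} != (genes {len(genes)}, cells {len(barcodes)})"
        )
    scipy.io.mmwrite(outdir / "matrix.mtx", counts, field="integer")
    cols = ["gene_id", "chrom", "start"] + (
        ["is_mito"] if "is_mito" in genes.columns else []
    )
    genes[cols].to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
    (outdir / "barcodes.tsv").write_text("".join(b + "\n" for b in barcodes))


def read_matrix_dir(indir: str | Path) -> tuple[sp.csr_matrix, pd.DataFrame, list[str]]:
    """Read a triplet matrix directory; checks dimension agreement."""
    indir = Path(indir)
    counts = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(
        indir / "genes.tsv",
        sep="\t",
        header=None,
        names=["gene_id", "chrom", "start", "is_mito"],
    )
    if genes["is_mito"].isna().all():
        genes["is_mito"] = genes["chrom"].isin(["chrM", "MT"])
    genes["is_mito"] = genes["is_mito"].astype(bool)
    barcodes = (indir / "barcodes.tsv").read_text().split()
    if counts.shape[0] != len(genes):
        raise ValueError(
            f"{indir}: matrix has {counts.shape[0]} rows but genes.tsv has {len(genes)}"
        )
    if counts.shape[1] != len(barcodes):
        raise ValueError(
            f"{indir}: matrix has {counts.shape[1]} columns but barcodes.tsv has {len(barcodes)}"
        )
    if len(barcodes) == 0:
        raise ValueError(f"{indir}: no cells")
    return counts, genes, barcodes


def read_droplet_csv(path: str | Path) -> pd.DataFrame:
    """Read a droplet count table: sample, channel, n_total, n_positive[, replicate]."""
    df = pd.read_csv(path)
    required = {"sample", "channel", "n_total", "n_positive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if (df["n_positive"] > df["n_total"]).any() or (df["n_total"] <= 0).any():
        raise ValueError(f"{path}: require 0 <= n_positive <= n_total and n_total > 0")
    return df


def write_manifest(outdir: str | Path, config: dict, inputs: Iterable[str | Path] = ()) -> Path:
    """Write a run manifest: config hash, seed, package version, input checksums."""
    from editscope import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for p in inputs:
        p = Path(p)
        checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "input_sha256": checksums,
        "editscope_version": __version__,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str) + "\n")
    return path
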