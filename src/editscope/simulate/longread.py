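"""ONT-like long-read amplicon simulator.

Each on-locus read is assembled as forward primer + 30-nt locus anchor +
core (optionally carrying a kilobase-scale internal deletion spanning the
cut site, or the HDR template insertion) + 30-nt locus anchor +
reverse-complemented reverse primer, after which per-base substitution
and 1-2 bp indel noise is applied and a configurable fraction of reads is
emitted reverse-complemented. Contaminant (off-locus) reads are random
sequences of comparable length carrying no primers. Class fractions are
realized as exact counts by default (``sampling=False``) so downstream
recovery tests have exact expectations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from ..io import Read
from ..specs import AmpliconSpec, revcomp
from ._noise import add_noise, random_dna

DeletionSampler = Callable[[np.random.Generator], int]


@dataclass
class LongReadSimConfig:
    """Configuration for :func:`gen_longreads`.

    ``deletion_fraction`` and ``hdr_fraction`` apply to the on-locus
    (non-contaminant) reads; ``contaminant_fraction`` applies to the
    whole read set. ``deletion_size_sampler`` may be an int (fixed size),
    a (lo, hi) tuple (uniform, inclusive) or a callable taking the RNG;
    by default deletions are uniform in [1000, trimmed_length - 200].
    """

    amplicon: AmpliconSpec
    n_reads: int
    deletion_fraction: float = 0.0
    deletion_size_sampler: int | tuple[int, int] | DeletionSampler | None = None
    hdr_fraction: float = 0.0
    substitution_rate: float = 0.0
    indel_noise_rate: float = 0.0
    contaminant_fraction: float = 0.0
    reverse_strand_fraction: float = 0.0
    sampling: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "deletion_fraction": self.deletion_fraction,
            "hdr_fraction": self.hdr_fraction,
            "substitution_rate": self.substitution_rate,
            "indel_noise_rate": self.indel_noise_rate,
            "contaminant_fraction": self.contaminant_fraction,
            "reverse_strand_fraction": self.reverse_strand_fraction,
        }
        for name, v in rates.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.deletion_fraction + self.hdr_fraction > 1.0 + 1e-12:
            raise ValueError("deletion_fraction + hdr_fraction must be <= 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.amplicon.reference_core is None:
            raise ValueError("amplicon.reference_core is required for simulation")
        if self.hdr_fraction > 0 and self.amplicon.hdr_insertion_size is None:
            raise ValueError("hdr_fraction > 0 requires amplicon.hdr_insertion_size")


def _resolve_sampler(cfg: LongReadSimConfig) -> DeletionSampler:
    s = cfg.deletion_size_sampler
    core_len = len(cfg.amplicon.reference_core)
    if s is None:
        lo, hi = 1000, max(1001, core_len - 200)
        return lambda rng: int(rng.integers(lo, hi + 1))
    if isinstance(s, int):
        return lambda rng: s
    if isinstance(s, tuple):
        lo, hi = s
        return lambda rng: int(rng.integers(lo, hi + 1))
    return s


def _class_counts(cfg: LongReadSimConfig, rng: np.random.Generator) -> list[str]:
    n = cfg.n_reads
    if cfg.sampling:
        classes = rng.choice(
            ["contaminant", "other"],
            size=n,
            p=[cfg.contaminant_fraction, 1 - cfg.contaminant_fraction],
        ).tolist()
        on_locus = [i for i, c in enumerate(classes) if c == "other"]
        draws = rng.choice(
            ["deletion", "hdr", "unedited"],
            size=len(on_locus),
            p=[
                cfg.deletion_fraction,
                cfg.hdr_fraction,
                1 - cfg.deletion_fraction - cfg.hdr_fraction,
            ],
        )
        for i, c in zip(on_locus, draws):
            classes[i] = str(c)
        return classes
    n_cont = round(n * cfg.contaminant_fraction)
    m = n - n_cont
    n_del = round(m * cfg.deletion_fraction)
    n_hdr = round(m * cfg.hdr_fraction)
    n_wt = m - n_del - n_hdr
    classes = (
        ["contaminant"] * n_cont
        + ["deletion"] * n_del
        + ["hdr"] * n_hdr
        + ["unedited"] * n_wt
    )
    return [classes[i] for i in rng.permutation(n)]


def _delete_span(core: str, spec: AmpliconSpec, size: int, rng: np.random.Generator) -> tuple[str, int]:
    """Remove ``size`` bases spanning the cut site, clamped to the anchor-free interior."""
    a = 30  # anchors at both ends must survive
    interior_lo, interior_hi = a, len(core) - a  # half-open interior
    max_size = interior_hi - interior_lo - 1
    size = min(size, max_size)
    cut = min(max(spec.cut_offset_in_core, interior_lo + 1), interior_hi - 1)
    lo = max(interior_lo, cut - size)
    hi = min(cut, interior_hi - size)
    start = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    return core[:start] + core[start + size :], size


def gen_longreads(cfg: LongReadSimConfig) -> tuple[list[Read], pd.DataFrame]:
    """Simulate long reads and their per-read truth table.

    Returns (reads, truth) where truth has columns read_id, true_class
    (unedited / deletion / hdr / contaminant), deletion_size, strand.
    Deletion sizes that do not fit between the locus anchors are clamped
    to the largest size that does (and recorded clamped in the truth
    table). Identical config + seed gives byte-identical reads.
    """
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.amplicon
    core = spec.reference_core
    sampler = _resolve_sampler(cfg)
    hdr_insert = (
        random_dna(rng, spec.hdr_insertion_size) if spec.hdr_insertion_size else ""
    )
    classes = _class_counts(cfg, rng)
    fwd = spec.forward_primer
    rev_rc = revcomp(spec.reverse_primer)
    reads: list[Read] = []
    rows = []
    for i, cls in enumerate(classes):
        del_size = 0
        if cls == "contaminant":
            length = int(rng.integers(int(0.8 * len(core)), int(1.2 * len(core)) + 1))
            seq = random_dna(rng, length)
        else:
            body = core
            if cls == "deletion":
                body, del_size = _delete_span(core, spec, sampler(rng), rng)
            elif cls == "hdr":
                cut = spec.cut_offset_in_core
                body = core[:cut] + hdr_insert + core[cut:]
            seq = fwd + body + rev_rc
        seq = add_noise(seq, rng, cfg.substitution_rate, cfg.indel_noise_rate)
        strand = "-" if rng.random() < cfg.reverse_strand_fraction else "+"
        if strand == "-":
            seq = revcomp(seq)
        read_id = f"sim_{cfg.seed}_{i:06d}"
        reads.append(Read(read_id, seq, "5" * len(seq)))
        rows.append(
            {
                "read_id": read_id,
                "true_class": cls,
                "deletion_size": del_size,
                "strand": strand,
            }
        )
    return reads, pd.DataFrame(rows)
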