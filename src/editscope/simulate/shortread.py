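"""Short-read amplicon simulator for the HDR/WT/indel classifier.

Four allele classes are planted on the classifier's wild-type amplicon:

* **WT** — the unedited amplicon.
* **HDR** — the full substitution barcode: the wild-type reference k-mer
  between the anchors is replaced by an edited k-mer differing at
  ``n_barcode_substitutions`` positions (12 by default, matching a 12-nt
  barcode inside a 15-mer window).
* **partial HDR** — only ``hamming_threshold`` of those substitutions,
  so the read still crosses the HDR-calling threshold but is not the
  full barcode.
* **indel** — a deletion (or insertion) at the cut site that breaks the
  fixed anchor spacing and overlaps the indel-calling window. Indel
  reads are drawn from a small recurrent allele repertoire generated
  once per config, mirroring the strongly peaked allele spectra of real
  end-joining outcomes (important because rare-allele frequency
  filtering downstream would otherwise discard unique indel reads).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..io import Read
from ..specs import HDRClassSpec
from ._noise import add_noise, random_dna

_ROTATE = {"A": "C", "C": "G", "G": "T", "T": "A"}


def barcode_window(spec: HDRClassSpec, n_substitutions: int) -> str:
    """The wild-type reference k-mer with its first n positions substituted.

    Substituted bases are rotated A->C->G->T->A, so the Hamming distance
    to the wild-type reference is exactly ``n_substitutions``.
    """
    if n_substitutions > len(spec.wt_reference):
        raise ValueError("more substitutions than reference positions")
    wt = spec.wt_reference
    return "".join(_ROTATE[b] for b in wt[:n_substitutions]) + wt[n_substitutions:]


@dataclass
class ShortReadSimConfig:
    """Configuration for :func:`gen_shortreads`.

    Fractions must sum to <= 1; the remainder is WT. ``wt_fraction`` may
    be given explicitly for readability, in which case the four fractions
    must sum to 1.
    """

    class_spec: HDRClassSpec
    n_reads: int
    hdr_fraction: float = 0.0
    partial_hdr_fraction: float = 0.0
    indel_fraction: float = 0.0
    wt_fraction: float | None = None
    substitution_rate: float = 0.0
    n_barcode_substitutions: int = 12
    indel_size_range: tuple[int, int] = (1, 10)
    n_indel_alleles: int = 8
    sampling: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        edited = self.hdr_fraction + self.partial_hdr_fraction + self.indel_fraction
        if edited > 1.0 + 1e-12:
            raise ValueError("class fractions sum to more than 1")
        if self.wt_fraction is None:
            self.wt_fraction = 1.0 - edited
        elif abs(self.wt_fraction + edited - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 when wt_fraction is explicit")
        if self.class_spec.hamming_threshold > self.n_barcode_substitutions:
            raise ValueError(
                "full barcode carries fewer substitutions than the HDR threshold"
            )


def _class_assignment(cfg: ShortReadSimConfig, rng: np.random.Generator) -> list[str]:
    n = cfg.n_reads
    fracs = {
        "HDR": cfg.hdr_fraction,
        "partial_HDR": cfg.partial_hdr_fraction,
        "indel": cfg.indel_fraction,
    }
    if cfg.sampling:
        names = list(fracs) + ["WT"]
        p = list(fracs.values()) + [cfg.wt_fraction]
        return [str(c) for c in rng.choice(names, size=n, p=p)]
    classes: list[str] = []
    for name, f in fracs.items():
        classes += [name] * round(n * f)
    classes += ["WT"] * (n - len(classes))
    return [classes[i] for i in rng.permutation(n)]


def gen_shortreads(cfg: ShortReadSimConfig) -> tuple[list[Read], pd.DataFrame]:
    """Simulate short amplicon reads and their truth table.

    HDR-class reads carry the full barcode (``n_barcode_substitutions``
    mismatches to the wild-type reference); partial-HDR reads carry
    exactly ``hamming_threshold`` of them; indel reads carry a deletion
    or insertion at the cut site. Deterministic per config + seed.
    """
    spec = cfg.class_spec
    rng = np.random.default_rng(cfg.seed)
    wt = spec.wt_amplicon
    win_start = wt.find(spec.anchor_left) + len(spec.anchor_left) + spec.wt_offset_in_gap
    k = len(spec.wt_reference)
    hdr_amplicon = wt[:win_start] + barcode_window(spec, cfg.n_barcode_substitutions) + wt[win_start + k :]
    partial_amplicon = (
        wt[:win_start] + barcode_window(spec, spec.hamming_threshold) + wt[win_start + k :]
    )
    cut = spec.cut_offset  # 1-based; indels placed starting at this base
    lo, hi = cfg.indel_size_range
    repertoire: list[str] = []
    for _ in range(cfg.n_indel_alleles):
        size = int(rng.integers(lo, hi + 1))
        if rng.random() < 0.7:  # deletions dominate end-joining outcomes
            repertoire.append(wt[: cut - 1] + wt[cut - 1 + size :])
        else:
            repertoire.append(wt[: cut - 1] + random_dna(rng, size) + wt[cut - 1 :])
    classes = _class_assignment(cfg, rng)
    reads: list[Read] = []
    rows = []
    for i, cls in enumerate(classes):
        if cls == "HDR":
            seq = hdr_amplicon
        elif cls == "partial_HDR":
            seq = partial_amplicon
        elif cls == "indel":
            seq = repertoire[int(rng.integers(0, len(repertoire)))]
        else:
            seq = wt
        seq = add_noise(seq, rng, cfg.substitution_rate, 0.0)
        read_id = f"sr_{cfg.seed}_{i:06d}"
        reads.append(Read(read_id, seq, "5" * len(seq)))
        rows.append({"read_id": read_id, "true_class": cls})
    return reads, pd.DataFrame(rows)
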