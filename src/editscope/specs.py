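"""Amplicon and classifier specifications.

Two configuration objects drive the sequence-level pipelines:

:class:`AmpliconSpec` describes one long-read amplicon: the PCR primers used
for end-to-end filtering, the 30-nt genomic anchor sequences immediately
inside the primer binding sites used for locus identity, the unedited
amplicon length, the cut-site offset and (optionally) the size of an HDR
template insertion expected at the locus.

:class:`HDRClassSpec` describes the short-read HDR/WT/indel classifier: a
pair of 20-nt anchors flanking a fixed-width gap, a wild-type reference
k-mer inside that gap, and the Hamming-distance threshold separating HDR
alleles (which carry a multi-base substitution barcode) from unedited ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import yaml

DNA_ALPHABET = set("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_dna(seq: str, name: str, allow_n: bool = False) -> str:
    seq = seq.strip().upper()
    allowed = DNA_ALPHABET | ({"N"} if allow_n else set())
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{name}: invalid DNA characters {sorted(bad)}")
    return seq


@dataclass
class AmpliconSpec:
    """One long-read amplicon target locus.

    ``unedited_length`` is the full amplicon length including both primers.
    ``locus_anchor_fwd``/``locus_anchor_rev`` are the 30-nt genomic
    sequences immediately following the forward primer and immediately
    preceding the reverse-primer binding site, both given on the forward
    strand of the amplicon. ``cut_offset`` is 1-based from the amplicon
    start. ``reference_core`` optionally carries the full primer-trimmed
    unedited sequence (anchors included); it is required for the on-target
    identity QC and by the read simulator.
    """

    locus_name: str
    chrom: str
    unedited_length: int
    forward_primer: str
    reverse_primer: str
    locus_anchor_fwd: str
    locus_anchor_rev: str
    cut_offset: int
    hdr_insertion_size: int | None = None
    size_buffer: int = 20
    reference_core: str | None = None

    def __post_init__(self) -> None:
        self.forward_primer = _clean_dna(self.forward_primer, "forward_primer")
        self.reverse_primer = _clean_dna(self.reverse_primer, "reverse_primer")
        self.locus_anchor_fwd = _clean_dna(self.locus_anchor_fwd, "locus_anchor_fwd")
        self.locus_anchor_rev = _clean_dna(self.locus_anchor_rev, "locus_anchor_rev")
        if self.reference_core is not None:
            self.reference_core = _clean_dna(self.reference_core, "reference_core")
        for name in ("locus_anchor_fwd", "locus_anchor_rev"):
            if len(getattr(self, name)) != 30:
                raise ValueError(f"{name} must be 30 nt, got {len(getattr(self, name))}")
        primer_len = len(self.forward_primer) + len(self.reverse_primer)
        if self.unedited_length <= primer_len + 60:
            raise ValueError("unedited_length must exceed primers plus both anchors")
        for p in (self.forward_primer, self.reverse_primer):
            if p == revcomp(p):
                raise ValueError("palindromic primers make strand assignment ambiguous")
        if not (0 < self.cut_offset < self.unedited_length):
            raise ValueError("cut_offset must lie inside the amplicon")
        if self.hdr_insertion_size is not None and self.hdr_insertion_size <= 0:
            raise ValueError("hdr_insertion_size must be positive")
        if self.size_buffer < 0:
            raise ValueError("size_buffer must be >= 0")
        if self.reference_core is not None:
            if len(self.reference_core) != self.trimmed_length:
                raise ValueError(
                    f"reference_core length {len(self.reference_core)} != "
                    f"trimmed unedited length {self.trimmed_length}"
                )
            if not self.reference_core.startswith(self.locus_anchor_fwd):
                raise ValueError("reference_core must start with locus_anchor_fwd")
            if not self.reference_core.endswith(revcomp(self.locus_anchor_rev)):
                raise ValueError("reference_core must end with revcomp(locus_anchor_rev)")

    @property
    def trimmed_length(self) -> int:
        """Expected primer-trimmed length L* of an unedited read."""
        return self.unedited_length - len(self.forward_primer) - len(self.reverse_primer)

    @property
    def cut_offset_in_core(self) -> int:
        """Cut-site offset relative to the primer-trimmed core (0-based)."""
        return self.cut_offset - 1 - len(self.forward_primer)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HDRClassSpec:
    """Anchor-pair short-read classifier configuration.

    HDR alleles carry a substitution barcode between two fixed anchors
    separated by exactly ``inter_anchor_distance`` bases; the k-mer at
    ``wt_offset_in_gap`` inside the gap is compared by Hamming distance to
    ``wt_reference`` (>= ``hamming_threshold`` mismatches calls HDR).
    Reads without a valid anchor pair are forwarded to the window-based
    indel caller, which aligns them to ``wt_amplicon`` and looks for
    inserted/deleted bases within ``quant_window`` bases centered on
    ``cut_offset`` (1-based on the amplicon).
    """

    anchor_left: str
    anchor_right: str
    wt_reference: str
    wt_amplicon: str
    cut_offset: int
    inter_anchor_distance: int = 32
    wt_offset_in_gap: int | None = None
    hamming_threshold: int = 11
    allele_freq_min: float = 0.002
    quant_window: int = 30
    hdr_reference: str | None = None
    anchor_mismatch_budget: int = 0

    def __post_init__(self) -> None:
        self.anchor_left = _clean_dna(self.anchor_left, "anchor_left")
        self.anchor_right = _clean_dna(self.anchor_right, "anchor_right")
        self.wt_reference = _clean_dna(self.wt_reference, "wt_reference")
        self.wt_amplicon = _clean_dna(self.wt_amplicon, "wt_amplicon")
        if self.hdr_reference is not None:
            self.hdr_reference = _clean_dna(self.hdr_reference, "hdr_reference")
            if len(self.hdr_reference) != len(self.wt_reference):
                raise ValueError("hdr_reference must match wt_reference length")
        if self.hamming_threshold > len(self.wt_reference):
            raise ValueError("hamming_threshold exceeds wt_reference length")
        if self.wt_offset_in_gap is None:
            self.wt_offset_in_gap = self._locate_wt_reference()
        if self.wt_offset_in_gap + len(self.wt_reference) > self.inter_anchor_distance:
            raise ValueError("wt_reference does not fit in the inter-anchor gap")
        if not (0.0 <= self.allele_freq_min < 1.0):
            raise ValueError("allele_freq_min must be in [0, 1)")
        if self.quant_window <= 0:
            raise ValueError("quant_window must be positive")
        if not (0 < self.cut_offset <= len(self.wt_amplicon)):
            raise ValueError("cut_offset must lie inside wt_amplicon")
        gap = self.wt_gap
        if gap[self.wt_offset_in_gap : self.wt_offset_in_gap + len(self.wt_reference)] != self.wt_reference:
            raise ValueError("wt_reference not found at wt_offset_in_gap in wt_amplicon gap")

    def _locate_wt_reference(self) -> int:
        """Derive the offset of the WT k-mer inside the gap from wt_amplicon."""
        i = self.wt_amplicon.find(self.anchor_left)
        if i < 0:
            raise ValueError("anchor_left not found in wt_amplicon")
        gap_start = i + len(self.anchor_left)
        gap = self.wt_amplicon[gap_start : gap_start + self.inter_anchor_distance]
        if (
            self.wt_amplicon[gap_start + self.inter_anchor_distance :].find(self.anchor_right)
            != 0
        ):
            raise ValueError(
                "anchor_right does not follow anchor_left at inter_anchor_distance in wt_amplicon"
            )
        j = gap.find(self.wt_reference)
        if j < 0:
            raise ValueError("wt_reference not found between the anchors in wt_amplicon")
        return j

    @property
    def wt_gap(self) -> str:
        """The unedited inter-anchor segment taken from wt_amplicon."""
        i = self.wt_amplicon.find(self.anchor_left)
        gap_start = i + len(self.anchor_left)
        return self.wt_amplicon[gap_start : gap_start + self.inter_anchor_distance]

    def to_dict(self) -> dict:
        return asdict(self)


def load_spec(path: str | Path) -> AmpliconSpec | HDRClassSpec:
    """Load an AmpliconSpec or HDRClassSpec from a JSON or YAML file.

    The file must carry a ``kind`` key: ``"amplicon"`` or ``"hdr_class"``.
    DNA is upper-cased; all invariants are validated at load time.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    if not isinstance(data, dict) or "kind" not in data:
        raise ValueError(f"{path}: spec file must be a mapping with a 'kind' key")
    kind = data.pop("kind")
    cls: Callable
    if kind == "amplicon":
        cls = AmpliconSpec
    elif kind == "hdr_class":
        cls = HDRClassSpec
    else:
        raise ValueError(f"{path}: unknown spec kind {kind!r}")
    return cls(**data)


def save_spec(spec: AmpliconSpec | HDRClassSpec, path: str | Path) -> None:
    path = Path(path)
    kind = "amplicon" if isinstance(spec, AmpliconSpec) else "hdr_class"
    data = {"kind": kind, **spec.to_dict()}
    path.write_text(json.dumps(data, indent=1) + "\n")
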