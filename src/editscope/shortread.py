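"""Anchor-based HDR / WT / indel classification of short amplicon reads.

HDR alleles at the target locus are tagged by a multi-base substitution
barcode. Classification proceeds in two stages:

* Reads containing both classifier anchors separated by exactly the
  configured gap (default 32 bp) are split into HDR vs unedited by the
  Hamming distance between the gap k-mer at the configured offset and the
  wild-type reference 15-mer: distance >= threshold (default 11) calls
  HDR, anything less calls WT.
* Reads without a valid anchor pair are candidate indel reads. A global
  affine-gap alignment against the wild-type amplicon calls "indel" when
  any inserted or deleted base overlaps the quantification window
  (default 30 bp) centered on the cut site; otherwise the read stays
  unclassified.

Allele-frequency summarization groups identical read sequences, drops
alleles below a minimum frequency of total reads (default 0.2%), and
reports class fractions over the retained reads with partial-HDR alleles
merged into the HDR fraction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from Bio import Align

from .io import Read
from .specs import HDRClassSpec

HDR = "HDR"
PARTIAL_HDR = "partial_HDR"
WT = "WT"
INDEL = "indel"
UNCLASSIFIED = "unclassified"
CANDIDATE_INDEL = "candidate_indel"


def hamming(a: str, b: str) -> int:
    """Number of mismatched positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _matches_at(read: str, pos: int, anchor: str, budget: int) -> bool:
    if pos < 0 or pos + len(anchor) > len(read):
        return False
    if budget == 0:
        return read[pos : pos + len(anchor)] == anchor
    return hamming(read[pos : pos + len(anchor)], anchor) <= budget


def find_anchor_pair(read: str, spec: HDRClassSpec) -> str | None:
    """Locate the anchor pair with the exact inter-anchor spacing.

    Returns the gap segment between the anchors, or None when no placement
    satisfies the spacing. The leftmost valid placement wins. Matching is
    exact by default; ``spec.anchor_mismatch_budget`` relaxes it.
    """
    al, ar = spec.anchor_left, spec.anchor_right
    budget = spec.anchor_mismatch_budget
    gap = spec.inter_anchor_distance
    for i in range(len(read) - len(al) - gap - len(ar) + 1):
        if not _matches_at(read, i, al, budget):
            continue
        if _matches_at(read, i + len(al) + gap, ar, budget):
            return read[i + len(al) : i + len(al) + gap]
    return None


def classify_read(read: str, spec: HDRClassSpec) -> str:
    """Classify one read as HDR, WT or candidate_indel.

    With a valid anchor pair the k-mer at ``wt_offset_in_gap`` inside the
    gap is Hamming-compared to the WT reference; distance >= threshold is
    HDR, else WT. Reads without the pair are forwarded to the indel caller.
    """
    gap = find_anchor_pair(read, spec)
    if gap is None:
        return CANDIDATE_INDEL
    window = gap[spec.wt_offset_in_gap : spec.wt_offset_in_gap + len(spec.wt_reference)]
    if hamming(window, spec.wt_reference) >= spec.hamming_threshold:
        return HDR
    return WT


def _aligner(spec: HDRClassSpec) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def call_indels(reads: Sequence[str], spec: HDRClassSpec) -> list[str]:
    """Window-based indel call for candidate reads.

    Each read is globally aligned to the WT amplicon (match 2, mismatch
    -1, gap open -5, extend -1). A read is "indel" when any inserted or
    deleted base overlaps the ``quant_window``-bp window centered on the
    cut site; substitution-only reads stay unclassified.
    """
    half = spec.quant_window // 2
    # window on WT amplicon coordinates, 0-based half-open
    w_lo = max(0, spec.cut_offset - half)
    w_hi = min(len(spec.wt_amplicon), spec.cut_offset + half)
    aligner = _aligner(spec)
    calls: list[str] = []
    for read in reads:
        aln = aligner.align(spec.wt_amplicon, read)[0]
        if _indel_in_window(aln, w_lo, w_hi):
            calls.append(INDEL)
        else:
            calls.append(UNCLASSIFIED)
    return calls


def _indel_in_window(aln, w_lo: int, w_hi: int) -> bool:
    """True if the alignment has a gap touching [w_lo, w_hi) on the target."""
    t_blocks, q_blocks = aln.aligned
    # deletions: gaps between consecutive target blocks; insertions: gaps
    # between query blocks, located at the target position where they occur
    prev_t_end = None
    prev_q_end = None
    for (t_start, t_end), (q_start, q_end) in zip(t_blocks, q_blocks):
        if prev_t_end is not None:
            if t_start > prev_t_end:  # deletion of target bases [prev_t_end, t_start)
                if t_start > w_lo and prev_t_end < w_hi:
                    return True
            if q_start > prev_q_end:  # insertion at target position prev_t_end
                if w_lo <= prev_t_end <= w_hi:
                    return True
        prev_t_end, prev_q_end = t_end, q_end
    if not len(t_blocks):
        return True  # nothing aligned at all
    # terminal gaps (read truncated relative to amplicon)
    if t_blocks[0][0] > 0 and t_blocks[0][0] > w_lo:
        return True
    if t_blocks[-1][1] < len(aln.target) and t_blocks[-1][1] < w_hi:
        return True
    return False


@dataclass
class EditOutcomeTable:
    """Allele-grouped outcome counts and fractions after the frequency filter."""

    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)
    n_total: int = 0
    n_retained: int = 0
    n_excluded_low_freq: int = 0
    allele_table: pd.DataFrame | None = None

    @property
    def hdr_rate(self) -> float:
        """HDR fraction of retained reads (partial HDR already merged)."""
        return self.fractions.get(HDR, 0.0)

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "fractions": dict(self.fractions),
            "n_total": self.n_total,
            "n_retained": self.n_retained,
            "n_excluded_low_freq": self.n_excluded_low_freq,
        }


def _is_partial_hdr(read: str, spec: HDRClassSpec) -> bool:
    """HDR-called read whose edited window differs from the full-HDR reference."""
    if spec.hdr_reference is None:
        return False
    gap = find_anchor_pair(read, spec)
    if gap is None:
        return False
    window = gap[spec.wt_offset_in_gap : spec.wt_offset_in_gap + len(spec.wt_reference)]
    return window != spec.hdr_reference


def summarize_outcomes(
    reads: Sequence[Read] | Sequence[str], spec: HDRClassSpec
) -> EditOutcomeTable:
    """Group reads into alleles, filter rare alleles, and tabulate outcomes.

    Identical read sequences form one allele; alleles with frequency below
    ``spec.allele_freq_min`` of *total* reads are excluded. Class fractions
    are computed over the retained reads, with partial-HDR counted inside
    the HDR fraction (and also reported separately).
    """
    seqs = [r.seq if isinstance(r, Read) else r for r in reads]
    n_total = len(seqs)
    table = EditOutcomeTable(n_total=n_total)
    classes = [HDR, PARTIAL_HDR, WT, INDEL, UNCLASSIFIED]
    if n_total == 0:
        table.counts = {c: 0 for c in classes}
        table.fractions = {c: float("nan") for c in classes}
        table.allele_table = pd.DataFrame(
            columns=["sequence", "count", "frequency", "class"]
        )
        return table

    allele_counts = Counter(seqs)
    min_count = spec.allele_freq_min * n_total
    retained: list[tuple[str, int]] = []
    for seq, count in allele_counts.items():
        if count < min_count:
            table.n_excluded_low_freq += count
        else:
            retained.append((seq, count))

    counts = {c: 0 for c in classes}
    rows = []
    candidates = [seq for seq, _ in retained if classify_read(seq, spec) == CANDIDATE_INDEL]
    indel_calls = dict(zip(candidates, call_indels(candidates, spec)))
    for seq, count in retained:
        cls = classify_read(seq, spec)
        if cls == CANDIDATE_INDEL:
            cls = indel_calls[seq]
        elif cls == HDR and _is_partial_hdr(seq, spec):
            cls = PARTIAL_HDR
        counts[cls] += count
        rows.append({"sequence": seq, "count": count, "class": cls})

    n_retained = sum(counts.values())
    table.n_retained = n_retained
    table.counts = counts
    fractions = {c: counts[c] / n_retained for c in classes}
    # partial HDR is reported merged into the HDR fraction
    fractions[HDR] = (counts[HDR] + counts[PARTIAL_HDR]) / n_retained
    table.fractions = fractions
    allele_df = pd.DataFrame(rows)
    allele_df["frequency"] = allele_df["count"] / n_total
    table.allele_table = allele_df.sort_values(
        "count", ascending=False, kind="stable"
    ).reset_index(drop=True)[["sequence", "count", "frequency", "class"]]
    return table
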