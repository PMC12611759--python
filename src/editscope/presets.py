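"""Packaged example specifications.

Both presets are *synthetic*: the short-read classifier preset embeds the
published anchor and wild-type reference sequences for the GAPDH 3'-UTR
classifier in synthetic flanking sequence (the surrounding amplicon is
generated, not genomic), and the long-read preset is an entirely
synthetic 3.5-kb amplicon. They exist so that examples, tests and
simulations run without any genomic download.
"""

from __future__ import annotations

import numpy as np

from .simulate._noise import random_dna
from .specs import AmpliconSpec, HDRClassSpec, revcomp

# Published GAPDH classifier sequences (anchors flank a 32-bp gap that
# contains the 15-nt wild-type reference; HDR alleles carry a 12-nt
# substitution barcode inside it).
GAPDH_ANCHOR_LEFT = "CCCCCACCACACTGAATCTC"
GAPDH_ANCHOR_RIGHT = "AGAGGGGAGGGGCCTAGGGA"
GAPDH_WT_REFERENCE = "CCTCACAGTTGCCAT"


def gapdh_hdr_spec(hamming_threshold: int = 11) -> HDRClassSpec:
    """GAPDH-style anchor classifier on a synthetic ~200-bp amplicon.

    The anchors and the 15-nt wild-type reference are the published
    classifier sequences; the rest of the amplicon and the position of
    the reference inside the 32-bp gap are synthetic (the published
    analysis only locates the reference 'between the two anchors').
    """
    rng = np.random.default_rng(12_061)
    offset = 8  # centers the 15-mer in the 32-bp gap
    gap = (
        random_dna(rng, offset)
        + GAPDH_WT_REFERENCE
        + random_dna(rng, 32 - offset - len(GAPDH_WT_REFERENCE))
    )
    left_flank = random_dna(rng, 60)
    right_flank = random_dna(rng, 68)
    wt_amplicon = left_flank + GAPDH_ANCHOR_LEFT + gap + GAPDH_ANCHOR_RIGHT + right_flank
    cut_offset = len(left_flank) + len(GAPDH_ANCHOR_LEFT) + 16  # inside the gap
    from .simulate.shortread import barcode_window

    spec = HDRClassSpec(
        anchor_left=GAPDH_ANCHOR_LEFT,
        anchor_right=GAPDH_ANCHOR_RIGHT,
        wt_reference=GAPDH_WT_REFERENCE,
        wt_amplicon=wt_amplicon,
        cut_offset=cut_offset,
        inter_anchor_distance=32,
        hamming_threshold=hamming_threshold,
    )
    spec.hdr_reference = barcode_window(spec, 12)
    return spec


def example_amplicon_spec(
    unedited_length: int = 3500,
    hdr_insertion_size: int | None = None,
    seed: int = 35_000,
) -> AmpliconSpec:
    """A synthetic long-read amplicon spec with its reference core.

    Primers are 25 nt, locus anchors 30 nt, cut site at the amplicon
    midpoint. ``hdr_insertion_size=228`` models a locus with a known HDR
    template insertion.
    """
    rng = np.random.default_rng(seed)
    fwd = random_dna(rng, 25)
    rev = random_dna(rng, 25)
    core_len = unedited_length - len(fwd) - len(rev)
    core = random_dna(rng, core_len)
    anchor_fwd = core[:30]
    anchor_rev = revcomp(core[-30:])
    return AmpliconSpec(
        locus_name="synthetic_locus",
        chrom="chrS",
        unedited_length=unedited_length,
        forward_primer=fwd,
        reverse_primer=rev,
        locus_anchor_fwd=anchor_fwd,
        locus_anchor_rev=anchor_rev,
        cut_offset=unedited_length // 2,
        hdr_insertion_size=hdr_insertion_size,
        reference_core=core,
    )
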