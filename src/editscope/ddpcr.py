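"""Droplet digital PCR Poisson quantification.

A ddPCR reaction partitions template molecules into ~20,000 droplets;
each droplet reads out positive when it received at least one template
copy. Under Poisson partitioning with mean copies-per-droplet lambda, the
positive fraction p satisfies p = 1 - exp(-lambda), so

    lambda = -ln(1 - n_positive / n_total).

Copy numbers are always reported as ratios of two lambdas (target over
reference channel), so droplet volume cancels everywhere. A condition's
ratio normalized to the unedited control gives the CNV on a scale where
1 means no change and the fractional change is normalized_cnv - 1
(e.g. -0.14 = 14% average copy loss). Lentiviral vector copy number (VCN)
is the target/reference lambda ratio scaled by the copies-per-genome of
the diploid reference gene (RPP30, 2 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass
class DropletAssay:
    """One channel of one ddPCR well: total and positive droplet counts."""

    channel: str
    n_total: int
    n_positive: int
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not (0 <= self.n_positive <= self.n_total):
            raise ValueError("require 0 <= n_positive <= n_total")


@dataclass
class CopyNumberResult:
    lambda_target: float
    lambda_reference: float
    ratio: float
    normalized_cnv: float | None = None
    fractional_change: float | None = None
    ci_lambda_target: tuple[float, float] | None = None
    ci_lambda_reference: tuple[float, float] | None = None


class SaturatedAssayError(ValueError):
    """All droplets positive: lambda is unbounded and cannot be estimated."""


def poisson_lambda(assay: DropletAssay, ci: float | None = None) -> float | tuple[float, tuple[float, float]]:
    """Mean copies per droplet from the positive-droplet fraction.

    lambda = -ln(1 - p) with p the positive fraction. With ``ci`` set
    (e.g. 0.95) a normal-approximation confidence interval on the ln scale
    is returned as (lambda, (lo, hi)). Zero positives give lambda = 0;
    a saturated assay (all droplets positive) raises.
    """
    if assay.n_positive == assay.n_total:
        raise SaturatedAssayError(
            f"{assay.channel}: all {assay.n_total} droplets positive — saturated assay"
        )
    p = assay.n_positive / assay.n_total
    lam = -math.log1p(-p)
    if ci is None:
        return lam
    if assay.n_positive == 0:
        return lam, (0.0, 0.0)
    # delta method: se(lambda) = sqrt(p / (n (1-p))); interval on ln(lambda)
    se_lam = math.sqrt(p / (assay.n_total * (1.0 - p)))
    z = norm.ppf(0.5 + ci / 2.0)
    half = z * se_lam / lam
    return lam, (lam * math.exp(-half), lam * math.exp(half))


def copy_ratio(target: DropletAssay, reference: DropletAssay) -> float:
    """Target/reference copy ratio lambda_t / lambda_r for one well."""
    lam_t = poisson_lambda(target)
    lam_r = poisson_lambda(reference)
    if lam_r == 0:
        raise ValueError(f"{reference.channel}: reference not amplified (lambda = 0)")
    return lam_t / lam_r


def replicate_ratio(
    targets: list[DropletAssay], references: list[DropletAssay], pooled: bool = False
) -> tuple[float, float]:
    """Mean and s.d. of the copy ratio across paired replicate wells.

    By default the ratio is computed per replicate and then averaged
    (matching per-well instrument practice); ``pooled=True`` instead sums
    droplet counts across replicates before a single ratio.
    """
    if len(targets) != len(references):
        raise ValueError("paired replicate lists must have equal length")
    if pooled:
        t = DropletAssay(
            targets[0].channel,
            sum(a.n_total for a in targets),
            sum(a.n_positive for a in targets),
        )
        r = DropletAssay(
            references[0].channel,
            sum(a.n_total for a in references),
            sum(a.n_positive for a in references),
        )
        return copy_ratio(t, r), float("nan")
    ratios = np.array([copy_ratio(t, r) for t, r in zip(targets, references)])
    return float(ratios.mean()), float(ratios.std(ddof=1)) if len(ratios) > 1 else float("nan")


def normalized_cnv(ratio_condition: float, ratio_control: float) -> CopyNumberResult:
    """CNV of a condition normalized to the unedited control condition.

    normalized_cnv = ratio_condition / ratio_control; the control
    normalized against itself is exactly 1. fractional_change is
    normalized_cnv - 1 (negative values are average copy loss).
    """
    if ratio_control == 0:
        raise ValueError("control ratio is zero — cannot normalize")
    cnv = ratio_condition / ratio_control
    return CopyNumberResult(
        lambda_target=float("nan"),
        lambda_reference=float("nan"),
        ratio=ratio_condition,
        normalized_cnv=cnv,
        fractional_change=cnv - 1.0,
    )


def vcn(
    target: DropletAssay, rpp30: DropletAssay, reference_copies_per_genome: int = 2
) -> float:
    """Lentiviral vector copy number per genome.

    VCN = reference_copies_per_genome * lambda_target / lambda_RPP30,
    with the reference a diploid housekeeping locus (2 copies/genome).
    """
    lam_t = poisson_lambda(target)
    lam_r = poisson_lambda(rpp30)
    if lam_r == 0:
        raise ValueError(f"{rpp30.channel}: reference not amplified (lambda = 0)")
    return reference_copies_per_genome * lam_t / lam_r
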