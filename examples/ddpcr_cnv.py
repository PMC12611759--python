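"""Copy-number quantification from Poisson-partitioned droplet counts.

Simulates an edited sample whose target locus dropped to half the
reference copy number, plus an unedited control, and reports the
normalized CNV and fractional change.
"""

from editscope.ddpcr import copy_ratio, normalized_cnv, vcn, DropletAssay
from editscope.simulate import DropletSimConfig, gen_droplets

edited_t, edited_r = gen_droplets(DropletSimConfig(20_000, 0.25, 0.5, seed=1))
control_t, control_r = gen_droplets(DropletSimConfig(20_000, 0.5, 0.5, seed=2))

ratio_edited = copy_ratio(edited_t, edited_r)
ratio_control = copy_ratio(control_t, control_r)
result = normalized_cnv(ratio_edited, ratio_control)

print(f"edited target/reference ratio:  {ratio_edited:.4f}")
print(f"control target/reference ratio: {ratio_control:.4f}")
print(f"normalized CNV: {result.normalized_cnv:.4f}")
print(f"fractional change: {result.fractional_change:+.4f}")

vcn_value = vcn(DropletAssay("u5", 15_000, 3_270), DropletAssay("rpp30", 15_000, 6_116))
print(f"example lentiviral VCN: {vcn_value:.2f} copies/genome")
# fractional change near -0.5 means the edited cells lost on average
# half their target-locus copies relative to the unedited condition.
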