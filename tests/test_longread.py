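"""Three-round filtering and length-based deletion quantification."""

import numpy as np
import pytest

from editscope.io import Read
from editscope.longread import (
    REASON_NO_FWD_PRIMER,
    call_longread_hdr,
    compute_deletion_profile,
    filter_round1_end_to_end,
    filter_round2_locus,
    filter_round3_size,
    run_longread_pipeline,
)
from editscope.simulate import LongReadSimConfig, gen_longreads
from editscope.specs import revcomp


def _unedited_read(spec, read_id="r0"):
    return Read(read_id, spec.forward_primer + spec.reference_core + revcomp(spec.reverse_primer))


class TestRound1:
    def test_exact_read_trimmed_to_core(self, amplicon_spec):
        out, report = filter_round1_end_to_end([_unedited_read(amplicon_spec)], amplicon_spec)
        assert len(out) == 1
        assert out[0].seq == amplicon_spec.reference_core
        assert report.n_pass_round1 == 1

    def test_reverse_strand_read_canonicalized(self, amplicon_spec):
        read = _unedited_read(amplicon_spec)
        rc_read = Read("rc", revcomp(read.seq))
        out, _ = filter_round1_end_to_end([rc_read], amplicon_spec)
        assert len(out) == 1
        assert out[0].seq == amplicon_spec.reference_core

    def test_core_only_rejected_with_reason(self, amplicon_spec):
        out, report = filter_round1_end_to_end(
            [Read("naked", amplicon_spec.reference_core)], amplicon_spec
        )
        assert out == []
        assert report.rejections == {REASON_NO_FWD_PRIMER: 1}

    def test_empty_input_ok(self, amplicon_spec):
        out, report = filter_round1_end_to_end([], amplicon_spec)
        assert out == [] and report.n_input == 0


class TestRound2:
    def test_exact_anchors_retained_untrimmed(self, amplicon_spec):
        core = amplicon_spec.reference_core
        out, _ = filter_round2_locus([Read("r", core)], amplicon_spec)
        assert out[0].seq == core  # anchors are genomic sequence, not trimmed

    def test_off_locus_read_rejected(self, amplicon_spec):
        rng = np.random.default_rng(0)
        other = "".join(rng.choice(list("ACGT"), size=len(amplicon_spec.reference_core)))
        out, report = filter_round2_locus([Read("x", other)], amplicon_spec)
        assert out == []
        assert report.rejections["missing anchor"] == 1

    def test_three_mismatches_in_anchor_allowed_at_default_rate(self, amplicon_spec):
        core = amplicon_spec.reference_core
        mutated = list(core)
        for i in (0, 10, 20):  # 3 mismatches in the 30-nt 5' anchor
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        out, _ = filter_round2_locus([Read("m3", "".join(mutated))], amplicon_spec)
        assert len(out) == 1  # ceil(0.1 * 30) = 3 edits allowed
        for i in (3, 13, 23, 27):  # 4 mismatches exceeds the budget
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        out, _ = filter_round2_locus([Read("m7", "".join(mutated))], amplicon_spec)
        assert out == []


class TestRound3:
    @pytest.mark.parametrize(
        "delta,kept",
        [(20, True), (21, False), (-1500, True)],
        ids=["at-buffer", "past-buffer", "large-deletion"],
    )
    def test_size_cap_boundary(self, amplicon_spec, delta, kept):
        length = amplicon_spec.trimmed_length + delta
        out, _ = filter_round3_size([Read("r", "A" * length)], amplicon_spec)
        assert (len(out) == 1) is kept

    def test_cap_includes_hdr_insertion(self, hdr_amplicon_spec):
        length = hdr_amplicon_spec.trimmed_length + 228 + 20
        out, _ = filter_round3_size([Read("hdr", "A" * length)], hdr_amplicon_spec)
        assert len(out) == 1


class TestDeletionProfile:
    def test_enumerated_sizes_and_frequency(self, amplicon_spec):
        L = amplicon_spec.trimmed_length  # 3450
        reads = [Read(f"r{i}", "A" * l) for i, l in enumerate([L, L - 1500, L, L - 3100])]
        profile = compute_deletion_profile(reads, amplicon_spec)
        assert sorted(profile.deletion_sizes) == [0, 0, 1500, 3100]
        assert profile.freq_deletion_gt[1000] == 0.5

    def test_all_unedited_zero_frequency(self, amplicon_spec):
        reads = [Read(f"r{i}", "A" * amplicon_spec.trimmed_length) for i in range(4)]
        profile = compute_deletion_profile(reads, amplicon_spec)
        assert profile.freq_deletion_gt[1000] == 0.0

    def test_survival_curve_non_increasing_and_bounded(self, amplicon_spec):
        rng = np.random.default_rng(1)
        lengths = rng.integers(300, amplicon_spec.trimmed_length + 1, size=200)
        reads = [Read(f"r{i}", "A" * int(l)) for i, l in enumerate(lengths)]
        profile = compute_deletion_profile(reads, amplicon_spec)
        frac = profile.survival_curve["fraction_greater"].to_numpy()
        assert (np.diff(frac) <= 0).all()
        assert ((frac >= 0) & (frac <= 1)).all()
        # frequency at size 0 = fraction of reads with any deletion
        at0 = profile.survival_curve.loc[profile.survival_curve["size"] == 0, "fraction_greater"]
        assert float(at0.iloc[0]) == (profile.deletion_sizes > 0).mean()

    def test_zero_reads_flagged(self, amplicon_spec):
        profile = compute_deletion_profile([], amplicon_spec)
        assert not profile.defined
        assert np.isnan(profile.freq_deletion_gt[1000])


class TestLongReadHDR:
    def test_exact_insertion_called(self, hdr_amplicon_spec):
        L = hdr_amplicon_spec.trimmed_length
        reads = [Read("a", "A" * (L + 228)), Read("b", "A" * L)]
        assert call_longread_hdr(reads, hdr_amplicon_spec) == 0.5

    def test_half_mixture_fraction(self, hdr_amplicon_spec):
        L = hdr_amplicon_spec.trimmed_length
        reads = [Read(f"h{i}", "A" * (L + 228)) for i in range(50)]
        reads += [Read(f"w{i}", "A" * L) for i in range(50)]
        assert call_longread_hdr(reads, hdr_amplicon_spec) == 0.5

    def test_requires_insertion_size(self, amplicon_spec):
        with pytest.raises(ValueError, match="hdr_insertion_size"):
            call_longread_hdr([Read("r", "A" * 100)], amplicon_spec)


class TestPipelineProperties:
    def test_noise_free_oracle_equivalence(self, amplicon_spec):
        """Recovered deletion-size multiset equals generator truth exactly."""
        cfg = LongReadSimConfig(
            amplicon=amplicon_spec, n_reads=300, deletion_fraction=0.4,
            contaminant_fraction=0.05, reverse_strand_fraction=0.5, seed=11,
        )
        reads, truth = gen_longreads(cfg)
        report, profile, table = run_longread_pipeline(reads, amplicon_spec)
        on_locus = truth[truth["true_class"] != "contaminant"]
        assert sorted(profile.deletion_sizes) == sorted(on_locus["deletion_size"])
        report.validate()

    def test_order_invariance(self, amplicon_spec):
        cfg = LongReadSimConfig(
            amplicon=amplicon_spec, n_reads=120, deletion_fraction=0.3,
            substitution_rate=0.02, indel_noise_rate=0.03,
            contaminant_fraction=0.1, reverse_strand_fraction=0.5, seed=12,
        )
        reads, _ = gen_longreads(cfg)
        rep_a, prof_a, _ = run_longread_pipeline(reads, amplicon_spec)
        rep_b, prof_b, _ = run_longread_pipeline(reads[::-1], amplicon_spec)
        assert rep_a.to_dict() == rep_b.to_dict()
        assert prof_a.freq_deletion_gt == prof_b.freq_deletion_gt
        assert sorted(prof_a.deletion_sizes) == sorted(prof_b.deletion_sizes)

    def test_hdr_insertion_alleles_survive_and_are_called(self, hdr_amplicon_spec):
        cfg = LongReadSimConfig(
            amplicon=hdr_amplicon_spec, n_reads=200, hdr_fraction=0.5, seed=13
        )
        reads, _ = gen_longreads(cfg)
        report, profile, _ = run_longread_pipeline(reads, hdr_amplicon_spec)
        assert report.n_pass_round3 == 200
        assert profile.hdr_fraction_longread == pytest.approx(0.5)
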