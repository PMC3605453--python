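"""Allele-mixture model, segment calling, fusion and prevalence summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from karyolute.clonality import (
    AberrationCall,
    NotQuantifiableError,
    Thresholds,
    call_imbalance,
    detection_limit,
    estimate_ac,
    expected_mbaf,
    fuse_segments,
    invert_mbaf,
    majority_clone_consistency,
    mirror_baf,
    summarize_case,
)
from karyolute.profiles import BafSegment

GENOTYPES = [("loss", (1, 0)), ("gain", (2, 1)), ("cnn_imbalance", (2, 0))]


class TestMirrorBaf:
    def test_fixed_point_and_symmetry(self):
        assert mirror_baf(0.5) == 0.5
        assert mirror_baf(0.2) == pytest.approx(0.8)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_mirror_invariance(self, b):
        assert mirror_baf(b) == mirror_baf(1.0 - b)
        assert 0.5 <= mirror_baf(b) <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mirror_baf(1.2)


class TestCallImbalance:
    def _seg(self, mbaf, log2):
        return BafSegment("1", 1, 100, mbaf, log2)

    @pytest.mark.parametrize(
        "mbaf,log2,expected",
        [
            (0.52, 0.5, "neutral"),
            (0.70, 0.20, "gain"),
            (0.70, 0.00, "cnn_imbalance"),
            (0.70, -0.20, "loss"),
            (0.55, 0.2, "neutral"),  # boundary: imbalance requires mBAF > 0.55
        ],
    )
    def test_classification(self, mbaf, log2, expected):
        assert call_imbalance(self._seg(mbaf, log2)) == expected

    def test_literal_positive_loss_cutoff_available(self):
        # the printed (sign-ambiguous) loss cutoff can be configured literally;
        # gains keep precedence where the two classes then overlap
        t = Thresholds(log2_loss=0.080)
        assert call_imbalance(self._seg(0.7, 0.05), t) == "loss"
        assert call_imbalance(self._seg(0.7, 0.05)) == "cnn_imbalance"


class TestFuseSegments:
    def _pair(self, gap, dmbaf):
        a = BafSegment("3", 1_000_000, 2_000_000, 0.70, 0.1, 0.65, 0.75, 100)
        b = BafSegment(
            "3", 2_000_001 + gap, 3_500_000 + gap, 0.70 + dmbaf, 0.1,
            0.66 + dmbaf, 0.74 + dmbaf, 300,
        )
        return [a, b]

    def test_wide_gap_not_fused(self):
        assert len(fuse_segments(self._pair(2_000_000, 0.05))) == 2

    def test_close_similar_segments_fused(self):
        fused = fuse_segments(self._pair(500_000, 0.05))
        assert len(fused) == 1
        seg = fused[0]
        assert seg.mbaf == pytest.approx((0.70 * 100 + 0.75 * 300) / 400)
        assert seg.mbaf_min == 0.65 and seg.mbaf_max == pytest.approx(0.79)
        assert seg.n_markers == 400  # marker count preserved

    def test_large_mbaf_difference_not_fused(self):
        assert len(fuse_segments(self._pair(500_000, 0.15))) == 2

    def test_different_chromosomes_never_fused(self):
        a, b = self._pair(500_000, 0.0)
        b = BafSegment("4", b.start, b.end, b.mbaf, b.log2ratio)
        assert len(fuse_segments([a, b])) == 2

    def test_left_to_right_chaining(self):
        # three abutting similar segments collapse to one
        segs = [
            BafSegment("5", i * 1_000_000 + 1, (i + 1) * 1_000_000, 0.7, 0.1,
                       n_markers=50)
            for i in range(3)
        ]
        assert len(fuse_segments(segs)) == 1

    @given(st.lists(st.floats(min_value=0.5, max_value=1.0), min_size=1, max_size=8))
    def test_never_increases_count(self, mbafs):
        segs = [
            BafSegment("1", i * 10**6 + 1, (i + 1) * 10**6, m, 0.0, n_markers=10)
            for i, m in enumerate(mbafs)
        ]
        fused = fuse_segments(segs)
        assert len(fused) <= len(segs)
        assert sum(s.n_markers for s in fused) == 10 * len(segs)


class TestAlleleMixtureModel:
    def test_no_clone_gives_balanced_mbaf(self):
        assert expected_mbaf((1, 0), 0.0) == 0.5
        assert expected_mbaf((3, 1), 0.0) == 0.5

    def test_pure_deletion_gives_full_imbalance(self):
        assert expected_mbaf((1, 0), 1.0) == 1.0

    def test_half_mixed_single_copy_gain(self):
        assert expected_mbaf((2, 1), 0.5) == pytest.approx(0.6)

    def test_no_dna_domain_error(self):
        with pytest.raises(ValueError):
            expected_mbaf((0, 0), 1.0)

    @pytest.mark.parametrize("_, genotype", GENOTYPES)
    def test_strictly_increasing_in_f(self, _, genotype):
        f = np.linspace(0, 1, 101)
        m = [expected_mbaf(genotype, fi) for fi in f]
        assert np.all(np.diff(m) > 0)

    @pytest.mark.parametrize("_, genotype", GENOTYPES)
    @pytest.mark.parametrize("f", [0.25, 0.4, 0.6, 0.8, 1.0])
    def test_inversion_is_identity(self, _, genotype, f):
        m = expected_mbaf(genotype, f)
        assert invert_mbaf(m, genotype) == pytest.approx(f, abs=1e-9)

    def test_tetraploid_background_inversion(self):
        m = expected_mbaf((3, 1), 0.6, background_ploidy=4)
        assert invert_mbaf(m, (3, 1), background_ploidy=4) == pytest.approx(0.6, abs=1e-9)

    def test_balanced_genotype_not_invertible(self):
        with pytest.raises(NotQuantifiableError):
            invert_mbaf(0.5, (1, 1))


class TestDetectionLimit:
    def test_hemizygous_loss_limit(self):
        # 1/(2-f) = 0.56  =>  f = 2 - 1/0.56 = 3/14
        assert detection_limit("loss", 0.56) == pytest.approx(3 / 14, abs=1e-12)

    def test_single_copy_gain_limit(self):
        # (1+f)/(2+f) = 0.56  =>  f = 0.12/0.44 = 3/11
        assert detection_limit("gain", 0.56) == pytest.approx(3 / 11, abs=1e-12)

    def test_limit_vanishes_at_threshold_half(self):
        assert detection_limit("loss", 0.5 + 1e-9) < 1e-7

    def test_monotone_in_threshold(self):
        # below 2/3 no genotype's limit saturates at f = 1 yet (a pure
        # single-copy gain tops out at mBAF 2/3)
        grid = np.linspace(0.51, 0.66, 40)
        for call in ("loss", "gain", "cnn_imbalance"):
            lims = [detection_limit(call, t) for t in grid]
            assert np.all(np.diff(lims) > 0)


class TestEstimateAc:
    def _seg(self, mbaf, log2, lo=None, hi=None):
        return BafSegment("11", 1, 10**6, mbaf, log2, lo, hi)

    def test_deletion_near_threshold(self):
        call = estimate_ac(self._seg(0.56, -0.2))
        assert call.call_type == "loss"
        assert call.ac_mean == pytest.approx(0.214, abs=0.001)

    def test_gain_near_threshold(self):
        call = estimate_ac(self._seg(0.56, 0.2))
        assert call.ac_mean == pytest.approx(0.273, abs=0.001)

    def test_interval_from_segment_extrema(self):
        call = estimate_ac(self._seg(0.70, -0.2, 0.65, 0.80))
        assert call.ac_min == pytest.approx(invert := 2 - 1 / 0.65, abs=1e-9)
        assert call.ac_max == pytest.approx(2 - 1 / 0.80, abs=1e-9)
        assert call.ac_min <= call.ac_mean <= call.ac_max

    def test_below_calling_threshold_refused(self):
        with pytest.raises(NotQuantifiableError):
            estimate_ac(self._seg(0.555, -0.2))

    def test_amplified_genotype_refused(self):
        with pytest.raises(NotQuantifiableError, match="amplified"):
            estimate_ac(self._seg(0.9, 0.9), genotype=(5, 1))


class TestCaseSummaries:
    def _call(self, ac, cls="numerical", spread=0.05):
        return AberrationCall(
            label=f"+{int(ac * 100)}", call_type="gain", genotype=(2, 1),
            ac_mean=ac, ac_min=max(ac - spread, 0), ac_max=min(ac + spread, 1),
            aberration_class=cls,
        )

    def test_single_call_all_spans_zero(self):
        s = summarize_case([self._call(0.6)], case_id="x")
        assert (s.span_total, s.span_numerical, s.span_structural) == (0, 0, 0)

    def test_span_arithmetic(self):
        s = summarize_case([self._call(0.80), self._call(0.60), self._call(0.35)])
        assert s.span_total == pytest.approx(45.0)

    def test_class_spans_use_their_own_extrema(self):
        calls = [
            self._call(0.80, "numerical"),
            self._call(0.70, "numerical"),
            self._call(0.30, "structural"),
        ]
        s = summarize_case(calls)
        assert s.span_numerical == pytest.approx(10.0)
        assert s.span_structural == 0.0
        assert s.span_total == pytest.approx(50.0)
        assert max(s.span_numerical, s.span_structural) <= s.span_total
        assert (s.n_numerical, s.n_structural) == (2, 1)

    def test_empty_case_rejected(self):
        with pytest.raises(ValueError):
            summarize_case([])

    def test_majority_clone_membership(self):
        calls = [
            self._call(0.80, "numerical", 0.05),
            self._call(0.78, "numerical", 0.05),
            self._call(0.75, "structural", 0.05),
            self._call(0.30, "structural", 0.02),
        ]
        frac = majority_clone_consistency(calls)
        assert frac["numerical"] == 1.0
        assert frac["structural"] == 0.5
        assert frac["all"] == pytest.approx(0.75)
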