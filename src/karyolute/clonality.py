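"""Clone-prevalence estimation from mirrored B-allele frequencies.

In a tumour sample where a fraction *f* of the DNA carries an allelic
imbalance with major/minor allele copies (nA, nB) against a balanced
background of ploidy *b*, the expected segment-level mirrored BAF is the
allele-mixture ratio

    mBAF(f) = (f * nA + (1 - f) * b/2) / (f * (nA + nB) + (1 - f) * b)

which is 0.5 for f = 0 and strictly increasing in f whenever nA > nB.
Inverting this relation at a segment's observed mBAF yields the *abnormality
content* (AC): the estimated fraction of sampled DNA carrying the
aberration.  The per-segment minimum and maximum mBAF give an AC interval.
Closed forms on a diploid background:

    hemizygous loss (1,0):  f = 2 - 1/m
    single-copy gain (2,1): f = (2m - 1) / (1 - m)
    CNN-LOH (2,0):          f = 2m - 1

Case-level diversity is summarised as the *prevalence span*: the difference
in AC between the most and the least prevalent aberration in the case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .profiles import BafSegment

CALL_TYPES = ("neutral", "gain", "loss", "cnn_imbalance")

#: default genotype model (nA, nB) of the aberrant clone, per call type
DEFAULT_GENOTYPES: dict[str, tuple[int, int]] = {
    "loss": (1, 0),
    "gain": (2, 1),
    "cnn_imbalance": (2, 0),
}

MAX_QUANTIFIABLE_COPIES = 5  # amplified sequences (>5 copies) are not quantifiable


class NotQuantifiableError(ValueError):
    """The aberration's DNA fraction cannot be estimated from mBAF."""


@dataclass(frozen=True)
class Thresholds:
    """Classification and calling thresholds for segment interpretation.

    ``mbaf_imbalance`` flags allelic imbalance; the slightly higher
    ``mbaf_call`` is required before an AC value is quantified.  Segments in
    imbalance are classed as gains above ``log2_gain``, losses below
    ``log2_loss`` and copy-number-neutral imbalances in between.  The loss
    cutoff defaults to -0.080: the gain/neutral/loss classes are only
    disjoint when the loss bound lies below the gain bound.
    """

    mbaf_imbalance: float = 0.55
    mbaf_call: float = 0.56
    log2_gain: float = 0.073
    log2_loss: float = -0.080


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class AberrationCall:
    """An interpreted genomic imbalance with its estimated clone DNA fraction."""

    label: str
    call_type: str
    genotype: tuple[int, int]
    ac_mean: float
    ac_min: float
    ac_max: float
    aberration_class: str = "structural"  # 'numerical' or 'structural'

    def __post_init__(self):
        if self.call_type not in CALL_TYPES:
            raise ValueError(f"unknown call type {self.call_type!r}")
        if self.aberration_class not in ("numerical", "structural"):
            raise ValueError(f"unknown aberration class {self.aberration_class!r}")
        if not (0 <= self.ac_min <= self.ac_mean <= self.ac_max <= 1):
            raise ValueError(
                f"AC interval must satisfy 0 <= min <= mean <= max <= 1, got "
                f"({self.ac_min}, {self.ac_mean}, {self.ac_max})"
            )


@dataclass(frozen=True)
class CasePrevalenceSummary:
    """Per-case prevalence spans (percentage points) by aberration class."""

    case_id: str
    span_total: float
    span_numerical: float
    span_structural: float
    n_segments: int
    n_numerical: int
    n_structural: int
    ploidy: str = ""


# ---------------------------------------------------------------------------
# Core model
# ---------------------------------------------------------------------------


def mirror_baf(baf: float) -> float:
    """Mirror a B-allele frequency into [0.5, 1]: max(baf, 1 - baf)."""
    if not (0.0 <= baf <= 1.0):
        raise ValueError(f"BAF {baf} outside [0, 1]")
    return max(baf, 1.0 - baf)


def expected_mbaf(
    genotype: tuple[int, int], f: float, background_ploidy: int = 2
) -> float:
    """Expected segment mBAF for clone fraction ``f`` under a genotype model.

    ``genotype`` is the aberrant clone's (nA, nB) allele copy pair with
    nA >= nB; the remaining 1 - f of the DNA is balanced at
    ``background_ploidy``.
    """
    nA, nB = genotype
    if nB > nA or nB < 0:
        raise ValueError(f"genotype must satisfy nA >= nB >= 0, got {genotype}")
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"clone fraction {f} outside [0, 1]")
    b = background_ploidy
    denom = f * (nA + nB) + (1.0 - f) * b
    if denom == 0:
        raise ValueError("no DNA: genotype (0, 0) at f = 1")
    return (f * nA + (1.0 - f) * b / 2.0) / denom


def invert_mbaf(
    mbaf: float, genotype: tuple[int, int], background_ploidy: int = 2
) -> float:
    """Clone DNA fraction solving ``expected_mbaf(genotype, f) = mbaf``.

    The mixture relation is linear in f, so the inversion is closed form:
    f = b(1/2 - m) / (m(nA + nB - b) - nA + b/2).  Results are clipped to
    [0, 1].
    """
    nA, nB = genotype
    b = background_ploidy
    denom = mbaf * (nA + nB - b) - nA + b / 2.0
    if denom == 0:
        raise NotQuantifiableError(
            f"genotype {genotype} is balanced against ploidy {b}; mBAF carries "
            "no clone-fraction information"
        )
    f = b * (0.5 - mbaf) / denom
    return float(np.clip(f, 0.0, 1.0))


def detection_limit(
    call_type: str,
    mbaf_threshold: float = DEFAULT_THRESHOLDS.mbaf_call,
    background_ploidy: int = 2,
    genotype: tuple[int, int] | None = None,
) -> float:
    """Minimal clone DNA fraction detectable at an mBAF calling threshold.

    This is the f at which the expected mBAF first reaches the threshold;
    clones below it are invisible to mBAF-based calling.  At the 0.56
    default a hemizygous loss needs f > 3/14 (~21.4%) and a single-copy
    gain f > 3/11 (~27.3%) of the sampled DNA.
    """
    if not (0.5 < mbaf_threshold < 1.0):
        raise ValueError(f"threshold {mbaf_threshold} outside (0.5, 1)")
    if genotype is None:
        genotype = DEFAULT_GENOTYPES[call_type]
    return invert_mbaf(mbaf_threshold, genotype, background_ploidy)


# ---------------------------------------------------------------------------
# Segment classification and fusion
# ---------------------------------------------------------------------------


def call_imbalance(
    segment: BafSegment, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> str:
    """Classify a segment as neutral / gain / loss / cnn_imbalance."""
    if segment.mbaf <= thresholds.mbaf_imbalance:
        return "neutral"
    if segment.log2ratio > thresholds.log2_gain:
        return "gain"
    if segment.log2ratio < thresholds.log2_loss:
        return "loss"
    return "cnn_imbalance"


def fuse_segments(
    segments: Sequence[BafSegment],
    max_gap: int = 1_000_000,
    max_mbaf_diff: float = 0.1,
) -> list[BafSegment]:
    """Fuse adjacent same-chromosome segments separated by < ``max_gap`` bp
    with mBAF difference < ``max_mbaf_diff``.

    Fusion proceeds left-to-right, re-testing after each merge.  The fused
    mBAF is the marker-count-weighted mean (length-weighted when marker
    counts are absent); mbaf_min/mbaf_max take the union extrema and marker
    counts add, so total marker count is preserved.
    """
    by_chrom: dict[str, list[BafSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chromosome, []).append(s)

    fused: list[BafSegment] = []
    for chrom in by_chrom:
        run = sorted(by_chrom[chrom], key=lambda s: s.start)
        out = [run[0]]
        for seg in run[1:]:
            prev = out[-1]
            gap = seg.start - prev.end - 1
            if gap < max_gap and abs(seg.mbaf - prev.mbaf) < max_mbaf_diff:
                out[-1] = _merge(prev, seg)
            else:
                out.append(seg)
        fused.extend(out)
    return fused


def _merge(a: BafSegment, b: BafSegment) -> BafSegment:
    if a.n_markers is not None and b.n_markers is not None:
        wa, wb = a.n_markers, b.n_markers
        n_markers = a.n_markers + b.n_markers
    else:
        wa, wb = a.length, b.length
        n_markers = None
    w = wa + wb
    mbaf = (a.mbaf * wa + b.mbaf * wb) / w
    return BafSegment(
        chromosome=a.chromosome,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        mbaf=mbaf,
        log2ratio=(a.log2ratio * wa + b.log2ratio * wb) / w,
        # the weighted mean can fall a rounding error outside the union extrema
        mbaf_min=min(a.mbaf_min, b.mbaf_min, mbaf),
        mbaf_max=max(a.mbaf_max, b.mbaf_max, mbaf),
        n_markers=n_markers,
    )


# ---------------------------------------------------------------------------
# AC estimation
# ---------------------------------------------------------------------------


def estimate_ac(
    segment: BafSegment,
    genotype: tuple[int, int] | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    background_ploidy: int = 2,
    label: str | None = None,
    aberration_class: str = "structural",
) -> AberrationCall:
    """Estimate the DNA fraction carrying a segment's imbalance.

    The segment mBAF, mbaf_min and mbaf_max are each inverted through the
    allele-mixture model under the chosen genotype (defaulting by call type:
    loss (1,0), gain (2,1), CNN-LOH (2,0)).  Segments below the calling
    threshold, and genotypes with more than five copies (amplifications),
    are refused as not quantifiable.
    """
    call_type = call_imbalance(segment, thresholds)
    if call_type == "neutral" or segment.mbaf < thresholds.mbaf_call:
        raise NotQuantifiableError(
            f"segment mBAF {segment.mbaf:.3f} below calling threshold "
            f"{thresholds.mbaf_call}"
        )
    if genotype is None:
        genotype = DEFAULT_GENOTYPES[call_type]
    if sum(genotype) > MAX_QUANTIFIABLE_COPIES:
        raise NotQuantifiableError(
            f"genotype {genotype} has >{MAX_QUANTIFIABLE_COPIES} copies; amplified "
            "sequences cannot be quantified from mBAF"
        )
    acs = sorted(
        invert_mbaf(m, genotype, background_ploidy)
        for m in (segment.mbaf_min, segment.mbaf, segment.mbaf_max)
    )
    return AberrationCall(
        label=label or f"{_SIGN.get(call_type, '')}{segment.chromosome}",
        call_type=call_type,
        genotype=genotype,
        ac_min=acs[0],
        ac_mean=invert_mbaf(segment.mbaf, genotype, background_ploidy),
        ac_max=acs[2],
        aberration_class=aberration_class,
    )


_SIGN = {"gain": "+", "loss": "-", "cnn_imbalance": "upd"}


# ---------------------------------------------------------------------------
# Case summaries
# ---------------------------------------------------------------------------


def _span(values: Sequence[float]) -> float:
    return float(max(values) - min(values)) if values else 0.0


def summarize_case(
    calls: Sequence[AberrationCall], case_id: str = "", ploidy: str = ""
) -> CasePrevalenceSummary:
    """Prevalence spans for one case, overall and per aberration class.

    Spans are max - min of ac_mean, reported in percentage points.  Each
    class uses its own extrema, so a class span never exceeds the total span
    but the total need not equal any class span.
    """
    if not calls:
        raise ValueError("summarize_case requires at least one call")
    num = [c.ac_mean for c in calls if c.aberration_class == "numerical"]
    struct = [c.ac_mean for c in calls if c.aberration_class == "structural"]
    return CasePrevalenceSummary(
        case_id=case_id,
        span_total=100.0 * _span([c.ac_mean for c in calls]),
        span_numerical=100.0 * _span(num),
        span_structural=100.0 * _span(struct),
        n_segments=len(calls),
        n_numerical=len(num),
        n_structural=len(struct),
        ploidy=ploidy,
    )


def majority_clone_consistency(
    calls: Sequence[AberrationCall],
) -> dict[str, float]:
    """Fraction of calls, per class, lying at the majority clone's DNA level.

    A DNA-content level is a call's [ac_min, ac_max] interval.  The majority
    level is the interval overlapping the largest number of calls; a call is
    consistent with the majority clone when its own interval overlaps that
    level.  Returns fractions for 'all', 'numerical' and 'structural'
    (NaN for an absent class).
    """
    if not calls:
        raise ValueError("majority_clone_consistency requires at least one call")
    iv = [(c.ac_min, c.ac_max) for c in calls]

    def overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
        return a[0] <= b[1] and b[0] <= a[1]

    n_overlap = [sum(overlaps(a, b) for b in iv) for a in iv]
    majority = iv[int(np.argmax(n_overlap))]

    member = [overlaps(i, majority) for i in iv]
    out: dict[str, float] = {"all": float(np.mean(member))}
    for cls in ("numerical", "structural"):
        sel = [m for m, c in zip(member, calls) if c.aberration_class == cls]
        out[cls] = float(np.mean(sel)) if sel else float("nan")
    return out
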