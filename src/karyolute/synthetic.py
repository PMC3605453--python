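"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators emulate the artifact's observed data without any external
download, each seed-deterministic and emitting its ground truth alongside
the data:

* :func:`gen_baf_segments` — BAF segment tables for a mixture of tumour
  subclones at known DNA fractions, with marker-level mBAF noise;
* :func:`gen_fish_counts` — per-cell FISH signal-count tables with a small
  mis-scoring rate;
* :func:`gen_cohort` — karyotype cohorts in which each case is one virtual
  tumour evolved under a chosen mitotic segregation-error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import clonality
from .fish import FishCountTable
from .profiles import BafSegment, CopyNumberProfile, KaryotypeRecord
from .segsim import (
    SegregationModel,
    SimulationConfig,
    SimulationError,
    evolve_to_target_copies,
)

#: rough GRCh37 chromosome lengths (Mb) used for segment placement
_CHROM_MB = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115, "14": 107,
    "15": 103, "16": 90, "17": 81, "18": 78, "19": 59, "20": 63, "21": 48,
    "22": 51,
}


@dataclass(frozen=True)
class Aberration:
    """One genomic imbalance carried by a clone."""

    chromosome: str
    start: int
    end: int
    genotype: tuple[int, int]  # (nA, nB) in the aberrant clone
    label: str = ""
    aberration_class: str = "structural"


@dataclass(frozen=True)
class Clone:
    fraction: float  # of tumour DNA
    aberrations: tuple[Aberration, ...] = ()


@dataclass(frozen=True)
class ClonalTruth:
    """The subclonal composition of a simulated tumour sample."""

    clones: tuple[Clone, ...]
    normal_contamination: float = 0.0
    background_ploidy: int = 2

    def __post_init__(self):
        fr = [c.fraction for c in self.clones]
        if any(f < 0 for f in fr) or self.normal_contamination < 0:
            raise ValueError("fractions must be >= 0")
        total = sum(fr) + self.normal_contamination
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone fractions + contamination sum to {total}, not 1")


def _segment_expected_mbaf(truth: ClonalTruth, ab: Aberration) -> tuple[float, float]:
    """Expected (mBAF, total-copies) at a locus carried by exactly one clone.

    Clones not carrying the aberration, and the normal contamination,
    contribute balanced background DNA.
    """
    b = truth.background_ploidy
    nA = nB = 0.0
    for clone in truth.clones:
        if ab in clone.aberrations:
            nA += clone.fraction * ab.genotype[0]
            nB += clone.fraction * ab.genotype[1]
        else:
            nA += clone.fraction * b / 2
            nB += clone.fraction * b / 2
    nA += truth.normal_contamination * b / 2
    nB += truth.normal_contamination * b / 2
    total = nA + nB
    return max(nA, nB) / total, total


def gen_baf_segments(
    truth: ClonalTruth,
    markers_per_segment: tuple[int, int] = (50, 500),
    noise_sd: float = 0.05,
    n_neutral: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[BafSegment], pd.DataFrame]:
    """Generate a BAF segment table for a subclone mixture.

    One segment is emitted per aberration plus ``n_neutral`` balanced filler
    segments.  ``noise_sd`` is the per-marker mBAF noise; the segment-level
    (median) mBAF receives noise of sd ``noise_sd / sqrt(markers)`` and the
    per-segment min/max come from the simulated marker spread.  Returns the
    segments and a truth table (one row per segment: clone fraction,
    genotype, expected mBAF).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    segments: list[BafSegment] = []
    truth_rows: list[dict] = []

    def emit(chrom, start, end, exp_mbaf, total_copies, clone_fraction, genotype, label, cls):
        n_mark = int(rng.integers(markers_per_segment[0], markers_per_segment[1] + 1))
        markers = exp_mbaf + rng.normal(0.0, noise_sd, size=n_mark)
        markers = np.clip(np.maximum(markers, 1.0 - markers), 0.5, 1.0)
        m = exp_mbaf + rng.normal(0.0, noise_sd / np.sqrt(n_mark))
        m = float(np.clip(max(m, 1.0 - m), 0.5, 1.0))
        log2 = float(
            np.log2(total_copies / truth.background_ploidy)
            + rng.normal(0.0, noise_sd / np.sqrt(n_mark))
        )
        seg = BafSegment(
            chromosome=chrom,
            start=start,
            end=end,
            mbaf=m,
            log2ratio=log2,
            mbaf_min=float(min(markers.min(), m)),
            mbaf_max=float(max(markers.max(), m)),
            n_markers=n_mark,
        )
        segments.append(seg)
        truth_rows.append(
            dict(
                chromosome=chrom, start=start, end=end, label=label,
                aberration_class=cls, clone_fraction=clone_fraction,
                nA=genotype[0], nB=genotype[1], expected_mbaf=exp_mbaf,
                expected_total_copies=total_copies,
            )
        )

    for clone in truth.clones:
        for ab in clone.aberrations:
            exp_m, total = _segment_expected_mbaf(truth, ab)
            emit(
                ab.chromosome, ab.start, ab.end, exp_m, total, clone.fraction,
                ab.genotype, ab.label or f"{ab.chromosome}:{ab.start}-{ab.end}",
                ab.aberration_class,
            )

    used = {ab.chromosome for c in truth.clones for ab in c.aberrations}
    free = [c for c in _CHROM_MB if c not in used] or list(_CHROM_MB)
    for i in range(n_neutral):
        chrom = free[i % len(free)]
        length = rng.integers(5, 30) * 1_000_000
        start = int(rng.integers(1, _CHROM_MB[chrom] * 1_000_000 - length))
        emit(chrom, start, int(start + length - 1), 0.5,
             float(truth.background_ploidy), 0.0, (1, 1), "neutral", "structural")

    return segments, pd.DataFrame(truth_rows)


def recover_clone_fractions(
    segments: Sequence[BafSegment],
    truth_table: pd.DataFrame,
    thresholds: clonality.Thresholds = clonality.DEFAULT_THRESHOLDS,
    background_ploidy: int = 2,
) -> pd.DataFrame:
    """Run AC estimation on generated segments and tabulate estimated vs
    true clone fractions (quantifiable, non-neutral segments only)."""
    rows = []
    for seg, (_, t) in zip(segments, truth_table.iterrows()):
        if t["clone_fraction"] == 0:
            continue
        try:
            call = clonality.estimate_ac(
                seg,
                genotype=(int(t["nA"]), int(t["nB"])),
                thresholds=thresholds,
                background_ploidy=background_ploidy,
                label=str(t["label"]),
            )
        except clonality.NotQuantifiableError:
            continue
        rows.append(
            dict(
                label=t["label"], true_fraction=float(t["clone_fraction"]),
                ac_mean=call.ac_mean, ac_min=call.ac_min, ac_max=call.ac_max,
                call_type=call.call_type,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FISH
# ---------------------------------------------------------------------------


def gen_fish_counts(
    truth: ClonalTruth,
    probe_map: Mapping[str, str],
    n_cells: int = 200,
    epsilon: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[FishCountTable], pd.DataFrame]:
    """Generate FISH signal-count tables for a clone mixture.

    ``probe_map`` maps probe name to chromosome label; a clone's copy
    number at a probe is its aberration's total allele copies there, or the
    background ploidy.  Clone fractions are taken as cell fractions.  Each
    scored cell is mis-scored by +/-1 signal with probability ``epsilon``.
    """
    if not (0.0 <= epsilon <= 0.1):
        raise ValueError(f"epsilon {epsilon} outside [0, 0.1]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    fractions = [c.fraction for c in truth.clones] + [truth.normal_contamination]
    clone_of_cell = rng.choice(len(fractions), size=n_cells, p=fractions)

    def copies_at(clone_idx: int, chrom: str) -> int:
        if clone_idx == len(truth.clones):  # normal cells
            return truth.background_ploidy
        for ab in truth.clones[clone_idx].aberrations:
            if ab.chromosome == chrom:
                return sum(ab.genotype)
        return truth.background_ploidy

    tables, truth_rows = [], []
    for probe, chrom in probe_map.items():
        true_counts = np.array([copies_at(c, chrom) for c in clone_of_cell])
        err = rng.random(n_cells) < epsilon
        shift = rng.choice([-1, 1], size=n_cells)
        scored = np.maximum(true_counts + err * shift, 0)
        vals, cnt = np.unique(scored, return_counts=True)
        tables.append(
            FishCountTable.from_counts(
                "synthetic", probe, {int(v): int(c) for v, c in zip(vals, cnt)}
            )
        )
        for i, clone in enumerate(truth.clones):
            truth_rows.append(
                dict(probe=probe, clone=i, fraction=clone.fraction,
                     true_copies=copies_at(i, chrom))
            )
    return tables, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Karyotype cohorts
# ---------------------------------------------------------------------------


def gen_cohort(
    model: SegregationModel,
    n_cases: int,
    targetN_range: tuple[int, int],
    config: SimulationConfig = SimulationConfig(),
    seed: int | None = None,
) -> tuple[list[KaryotypeRecord], pd.DataFrame]:
    """Generate a cohort of tumour cases evolved under one error model.

    Each case is a single viable virtual tumour evolved to a target
    chromosome number drawn uniformly from ``targetN_range`` (inclusive).
    Targets that are unreachable — or so improbable under the mechanism that
    the rejection budget runs out (e.g. a 78-chromosome gains daughter of a
    single tripolar division of a diploid cell) — are redrawn.  Returns the
    records and a truth table recording the generating model per case.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    lo, hi = targetN_range
    records, rows = [], []
    batch_cfg = replace(config, n_virtual=32, seed=None, max_attempts=500)
    for i in range(n_cases):
        copies = None
        for _ in range(1000):
            targetN = int(rng.integers(lo, hi + 1))
            if not model.reachable(targetN, config.n_chromosome_types):
                continue
            try:
                copies = evolve_to_target_copies(model, targetN, batch_cfg, rng)
            except SimulationError:
                continue
            break
        if copies is None:
            raise ValueError(f"no workable target in {targetN_range} under {model.kind}")
        profile = CopyNumberProfile.from_copies(copies[rng.integers(len(copies))])
        rec = KaryotypeRecord(case_id=f"synth{i + 1:03d}", profile=profile)
        records.append(rec)
        rows.append(
            dict(case_id=rec.case_id, model=model.kind,
                 start_ploidy=model.start_ploidy, targetN=targetN)
        )
    return records, pd.DataFrame(rows)
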