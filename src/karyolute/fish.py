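"""Copy-number heterogeneity statistics from FISH signal-count tables.

Each table records, for one sample and one probe, how many scored nuclei
carried each signal count.  The modal number is the most frequent count;
the non-modal fraction (percentage of nuclei deviating from it) is the
per-probe heterogeneity score.  A control-derived significance threshold is
mean + 3 standard deviations of the non-modal fractions observed in a
karyotypically stable control sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_ANALYSIS_CELLS = 200


@dataclass(frozen=True)
class FishCountTable:
    """Per-cell signal counts for one sample/probe pair."""

    sample_id: str
    probe: str
    counts: tuple[tuple[int, int], ...]  # (copy_number, n_cells), sorted

    def __post_init__(self):
        counts = {int(k): int(v) for k, v in dict(self.counts).items()}
        if any(k < 0 for k in counts) or any(v < 0 for v in counts.values()):
            raise ValueError("copy numbers and cell counts must be >= 0")
        object.__setattr__(
            self, "counts", tuple(sorted((k, v) for k, v in counts.items() if v > 0))
        )
        if self.n_cells < MIN_ANALYSIS_CELLS:
            warnings.warn(
                f"{self.sample_id}/{self.probe}: only {self.n_cells} cells scored "
                f"(< {MIN_ANALYSIS_CELLS} expected for analysis-grade tables)",
                stacklevel=2,
            )

    @classmethod
    def from_counts(cls, sample_id, probe, counts: Mapping[int, int]):
        return cls(sample_id, probe, tuple(counts.items()))

    @property
    def n_cells(self) -> int:
        return sum(v for _, v in self.counts)

    def as_dict(self) -> dict[int, int]:
        return dict(self.counts)


def modal_number(table: FishCountTable, expected_ploidy: int = 2) -> int:
    """Copy-number class with the most cells.

    Ties are broken toward the class nearest ``expected_ploidy``, then
    toward the lower class, and flagged with a warning.
    """
    counts = table.as_dict()
    if not counts:
        raise ValueError(f"{table.sample_id}/{table.probe}: empty count table")
    top = max(counts.values())
    tied = sorted(k for k, v in counts.items() if v == top)
    if len(tied) > 1:
        warnings.warn(
            f"{table.sample_id}/{table.probe}: modal number tied between {tied}; "
            f"breaking toward ploidy {expected_ploidy}",
            stacklevel=2,
        )
        tied.sort(key=lambda k: (abs(k - expected_ploidy), k))
    return tied[0]


def nonmodal_fraction(table: FishCountTable, expected_ploidy: int = 2) -> float:
    """Percentage of nuclei with a copy number other than the modal number."""
    modal = modal_number(table, expected_ploidy)
    return 100.0 * (1.0 - table.as_dict()[modal] / table.n_cells)


def control_threshold(control_values: Sequence[float]) -> float:
    """Significance threshold from control non-modal fractions:
    mean + 3 x sample standard deviation (n - 1 denominator)."""
    vals = np.asarray(control_values, dtype=float)
    if vals.size < 2:
        raise ValueError("control_threshold needs at least 2 control values")
    return float(vals.mean() + 3.0 * vals.std(ddof=1))


@dataclass(frozen=True)
class DiversityComparison:
    test: str  # 'ttest', 'fisher_exact' or 'permutation'
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    note: str = ""


def compare_diversity(group_a, group_b) -> DiversityComparison:
    """Compare two groups of non-modal fractions (two-tailed t-test) or two
    count rows of a 2x2 contingency table (two-tailed Fisher exact).

    Groups of real values with degenerate (zero) variance fall back to an
    exact permutation test, noted in the report.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 2 and b.size == 2 and _is_counts(a) and _is_counts(b):
        odds, p = stats.fisher_exact(np.vstack([a, b]), alternative="two-sided")
        return DiversityComparison(
            "fisher_exact", float(odds), float(p), 2, 2, a.mean(), b.mean()
        )
    if a.std() == 0 and b.std() == 0:
        res = stats.permutation_test(
            (a, b),
            lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            permutation_type="independent",
            n_resamples=np.inf,
        )
        return DiversityComparison(
            "permutation",
            float(res.statistic),
            float(res.pvalue),
            a.size,
            b.size,
            a.mean(),
            b.mean(),
            note="degenerate variance; exact permutation test used",
        )
    t, p = stats.ttest_ind(a, b)
    return DiversityComparison(
        "ttest", float(t), float(p), a.size, b.size, a.mean(), b.mean()
    )


def _is_counts(x: np.ndarray) -> bool:
    return bool(np.all(x == np.round(x)) and np.all(x >= 0))


# ---------------------------------------------------------------------------
# Tidy table I/O: sample, probe, copy_number, cells
# ---------------------------------------------------------------------------


def read_fish_table(path: str | Path) -> list[FishCountTable]:
    df = pd.read_csv(path, sep="\t")
    needed = {"sample", "probe", "copy_number", "cells"}
    missing = needed - set(c.lower() for c in df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df.columns = [c.lower() for c in df.columns]
    tables = []
    for (sample, probe), grp in df.groupby(["sample", "probe"], sort=True):
        counts = dict(zip(grp["copy_number"].astype(int), grp["cells"].astype(int)))
        tables.append(FishCountTable.from_counts(str(sample), str(probe), counts))
    return tables


def write_fish_table(tables: Iterable[FishCountTable], path: str | Path) -> None:
    rows = [
        dict(sample=t.sample_id, probe=t.probe, copy_number=k, cells=v)
        for t in tables
        for k, v in t.counts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
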