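"""Copy-number profiles, numerical-karyotype parsing, and cohort table I/O.

The unit of comparison throughout the package is the *copy-number profile*:
the multiset of per-chromosome-type copy numbers of a tumour stem line,
summarised as counts of chromosome types per copy-number class (monosomies,
disomies, trisomies, ...).  Profiles are built either from ISCN-style
numerical karyotype strings or read from tabular cohort files, and compared
against profiles emitted by the segregation-error simulators.

The genome is modelled as 23 chromosome types by default: the 22 autosome
pairs plus a single sex-chromosome slot, so a normal diploid genome has
N = 46 and a tetraploid one N = 92.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_CHROMOSOME_TYPES = 23
HIGH_POLYSOMY_CAP = 5  # display pooling: pentasomies and higher pooled

SUBTYPES = ("1", "2A", "2B", "unknown")
SOURCES = ("cytogenetics", "snp_array")
FLAGS = (
    "recurrent",
    "adult",
    "incomplete",
    "marker",
    "ring",
    "no_numerical_change",
    "count_mismatch",
    "count_range",
)


class FormatError(ValueError):
    """A table is structurally unreadable (e.g. a required column is missing)."""


class RowError(ValueError):
    """One or more table rows violate the format's invariants."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid rows:\n" + "\n".join(self.problems))


class KaryotypeParseError(ValueError):
    """An ISCN-style karyotype string cannot be interpreted."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CopyNumberProfile:
    """Counts of chromosome types per copy-number class.

    ``items`` maps copy-number class (0, 1, 2, ...) to the number of
    chromosome types in that class.  Exact copy numbers are kept internally
    even above the high-polysomy display cap, so the total chromosome number
    N is always exact.
    """

    items: tuple[tuple[int, int], ...]
    n_chromosome_types: int = N_CHROMOSOME_TYPES

    def __post_init__(self):
        counts = dict(self.items)
        if any(k < 0 for k in counts):
            raise ValueError("copy-number classes must be >= 0")
        if any(v < 0 for v in counts.values()):
            raise ValueError("class counts must be >= 0")
        total = sum(counts.values())
        if total != self.n_chromosome_types:
            raise ValueError(
                f"class counts sum to {total}, expected {self.n_chromosome_types}"
            )
        canonical = tuple(sorted((k, v) for k, v in counts.items() if v > 0))
        object.__setattr__(self, "items", canonical)

    @classmethod
    def from_counts(
        cls, counts: Mapping[int, int], n_chromosome_types: int = N_CHROMOSOME_TYPES
    ) -> "CopyNumberProfile":
        return cls(tuple(sorted(counts.items())), n_chromosome_types)

    @classmethod
    def from_copies(cls, copies: Iterable[int]) -> "CopyNumberProfile":
        """Build a profile from a per-chromosome-type copy-number vector."""
        copies = list(int(c) for c in copies)
        return cls.from_counts(Counter(copies), n_chromosome_types=len(copies))

    @property
    def counts(self) -> dict[int, int]:
        return dict(self.items)

    @property
    def N(self) -> int:
        """Total chromosome number, exact over all classes."""
        return sum(k * v for k, v in self.items)

    def count(self, copy_number: int) -> int:
        return dict(self.items).get(copy_number, 0)

    def is_viable(self) -> bool:
        """False if any chromosome type is nullisomic."""
        return self.count(0) == 0

    def has_monosomy(self) -> bool:
        return self.count(1) > 0

    def pooled(self, cap: int = HIGH_POLYSOMY_CAP) -> dict[int, int]:
        """Counts with classes >= ``cap`` pooled into one high-polysomy bin.

        Pooling is a display convention only; :attr:`N` always uses the
        exact internal classes.
        """
        out: Counter[int] = Counter()
        for k, v in self.items:
            out[min(k, cap)] += v
        return dict(sorted(out.items()))

    def sorted_copies(self) -> tuple[int, ...]:
        """Canonical per-type copy vector (sorted), ignoring which type is which."""
        out: list[int] = []
        for k, v in self.items:
            out.extend([k] * v)
        return tuple(out)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"{k}:{v}" for k, v in self.items)
        return f"CopyNumberProfile({{{body}}}, N={self.N})"


@dataclass(frozen=True)
class KaryotypeRecord:
    """A single tumour case: identity, clinical-genetic subtype and profile."""

    case_id: str
    profile: CopyNumberProfile
    subtype: str = "unknown"
    source: str = "cytogenetics"
    flags: frozenset[str] = frozenset()
    age_years: float | None = None
    karyotype: str | None = None

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        object.__setattr__(self, "flags", frozenset(self.flags))


@dataclass(frozen=True)
class BafSegment:
    """A genomic segment with mirrored B-allele frequency and log2 ratio.

    Coordinates are 1-based inclusive positions on GRCh37.  ``mbaf`` is the
    segment median mirrored BAF in [0.5, 1]; ``mbaf_min``/``mbaf_max`` bound
    the marker-level spread within the segment and default to ``mbaf``.
    """

    chromosome: str
    start: int
    end: int
    mbaf: float
    log2ratio: float
    mbaf_min: float | None = None
    mbaf_max: float | None = None
    n_markers: int | None = None

    def __post_init__(self):
        if self.mbaf_min is None:
            object.__setattr__(self, "mbaf_min", self.mbaf)
        if self.mbaf_max is None:
            object.__setattr__(self, "mbaf_max", self.mbaf)
        problems = self.validate()
        if problems:
            raise ValueError("; ".join(problems))

    def validate(self) -> list[str]:
        p = []
        if not (0.5 <= self.mbaf <= 1.0):
            p.append(f"mBAF {self.mbaf} outside [0.5, 1] (values must be mirrored)")
        if self.mbaf_min is not None and self.mbaf_max is not None:
            if not (self.mbaf_min <= self.mbaf <= self.mbaf_max):
                p.append(
                    f"mBAF {self.mbaf} outside [mbaf_min, mbaf_max]="
                    f"[{self.mbaf_min}, {self.mbaf_max}]"
                )
        if self.start > self.end:
            p.append(f"start {self.start} > end {self.end}")
        if self.n_markers is not None and self.n_markers < 1:
            p.append(f"n_markers {self.n_markers} < 1")
        return p

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Segment table I/O
# ---------------------------------------------------------------------------

_SEGMENT_ALIASES: dict[str, tuple[str, ...]] = {
    "chromosome": ("chromosome", "chrom", "chr"),
    "start": ("start",),
    "end": ("end", "stop"),
    "mbaf": ("mbaf",),
    "log2ratio": ("log2ratio", "log2_ratio", "log2", "logr"),
    "mbaf_min": ("mbaf_min", "mbafmin"),
    "mbaf_max": ("mbaf_max", "mbafmax"),
    "n_markers": ("n_markers", "markers", "nmarkers", "probes"),
}
_REQUIRED_SEGMENT_COLS = ("chromosome", "start", "end", "mbaf", "log2ratio")


def _resolve_columns(columns: Sequence[str], aliases: Mapping[str, tuple[str, ...]]):
    lower = {str(c).strip().lower(): c for c in columns}
    resolved = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in lower:
                resolved[canonical] = lower[name]
                break
    return resolved


def read_segment_table(path: str | Path) -> list[BafSegment]:
    """Read a tab-delimited BAF segment table into :class:`BafSegment` records.

    The header must name at least Chromosome/Start/End/mBAF/Log2ratio
    (case-insensitive aliases accepted).  Rows violating segment invariants
    are collected and reported with their 1-based file line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df.columns, _SEGMENT_ALIASES)
    missing = [c for c in _REQUIRED_SEGMENT_COLS if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    segments: list[BafSegment] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            kwargs = dict(
                chromosome=str(row[cols["chromosome"]]),
                start=int(row[cols["start"]]),
                end=int(row[cols["end"]]),
                mbaf=float(row[cols["mbaf"]]),
                log2ratio=float(row[cols["log2ratio"]]),
            )
            for opt in ("mbaf_min", "mbaf_max"):
                if opt in cols and pd.notna(row[cols[opt]]):
                    kwargs[opt] = float(row[cols[opt]])
            if "n_markers" in cols and pd.notna(row[cols["n_markers"]]):
                kwargs["n_markers"] = int(float(row[cols["n_markers"]]))
            segments.append(BafSegment(**kwargs))
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise RowError(problems)
    return segments


def write_segment_table(segments: Iterable[BafSegment], path: str | Path) -> None:
    rows = []
    for s in segments:
        rows.append(
            dict(
                Chromosome=s.chromosome,
                Start=s.start,
                End=s.end,
                mBAF=s.mbaf,
                Log2ratio=s.log2ratio,
                mBAF_min=s.mbaf_min,
                mBAF_max=s.mbaf_max,
                n_markers=s.n_markers,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ISCN numerical karyotype parsing
# ---------------------------------------------------------------------------

_NUMERIC_TOKEN = re.compile(r"^([+-])(\d+|X|Y)$")
_STRUCT_GAIN = re.compile(r"^([+-])(?:del|dup|der|i|inv|ins|add|t)\((\d+|X|Y)[);]")
_SEX_FIELD = re.compile(r"^[XY]+$")
_COUNT_FIELD = re.compile(r"^(\d+)(?:[-~](\d+))?$")
_RING_TOKEN = re.compile(r"^\+?(?:\d*~?\d*)?r(\(|$)")


def _chrom_index(label: str, n_types: int) -> int:
    """Map a chromosome label to a type slot (autosomes 1..22, X/Y pooled)."""
    if label in ("X", "Y"):
        return n_types - 1
    idx = int(label) - 1
    if not (0 <= idx < n_types - 1):
        raise KaryotypeParseError(f"chromosome {label} outside 1..{n_types - 1}")
    return idx


def baseline_ploidy(count: int, n_types: int = N_CHROMOSOME_TYPES) -> int:
    """Per-type baseline copy number: the multiple of ``n_types`` nearest
    to the modal chromosome count (46 -> 2, 69 -> 3, 92 -> 4, ...)."""
    return max(1, round(count / n_types))


def parse_iscn_numerical(
    karyotype: str,
    n_chromosome_types: int = N_CHROMOSOME_TYPES,
    case_id: str = "",
    source: str = "cytogenetics",
    slack: int = 0,
) -> KaryotypeRecord:
    """Parse a single-clone ISCN-like numerical karyotype string.

    Only whole-chromosome arithmetic is interpreted: the leading modal count
    fixes a baseline ploidy (nearest multiple of 23), the sex field sets the
    sex-chromosome slot, and ``+chr``/``-chr`` tokens adjust individual
    types.  Structural tokens (del, dup, t, add, i, ...) leave chromosome
    counts unchanged; dmin/hsr imply MYCN amplification and set subtype 2B;
    inc/mar/r set the corresponding exclusion flags.
    """
    text = karyotype.replace("−", "-").replace("–", "-").strip()
    if not text:
        raise KaryotypeParseError("empty karyotype string")
    tokens = [t.strip() for t in text.split(",") if t.strip()]

    m = _COUNT_FIELD.match(tokens[0])
    if not m:
        raise KaryotypeParseError(f"unparseable chromosome count field {tokens[0]!r}")
    count = int(m.group(1))
    flags: set[str] = set()
    if m.group(2) is not None:
        flags.add("count_range")

    base = baseline_ploidy(count, n_chromosome_types)
    copies = np.full(n_chromosome_types, base, dtype=int)

    rest = tokens[1:]
    if rest and _SEX_FIELD.match(rest[0]):
        copies[n_chromosome_types - 1] = len(rest[0])
        rest = rest[1:]

    subtype = "unknown"
    n_numeric_tokens = 0
    for tok in rest:
        low = tok.lower()
        if "dmin" in low or "hsr" in low:
            subtype = "2B"
            continue
        if low == "inc" or low.endswith(")inc"):
            flags.add("incomplete")
            continue
        if "mar" in low:
            flags.add("marker")
            continue
        if _RING_TOKEN.match(low):
            flags.add("ring")
            continue
        m = _NUMERIC_TOKEN.match(tok)
        if m is None:
            m = _STRUCT_GAIN.match(tok)  # e.g. "+der(3)..." gains a type-3 copy
        if m:
            sign = 1 if m.group(1) == "+" else -1
            copies[_chrom_index(m.group(2), n_chromosome_types)] += sign
            n_numeric_tokens += 1
            continue
        # any other structural token: no whole-chromosome effect

    if copies.min() < 0:
        raise KaryotypeParseError(
            f"{karyotype!r}: loss tokens drive a chromosome below zero copies"
        )
    profile = CopyNumberProfile.from_copies(copies)
    if n_numeric_tokens == 0 and profile.N == 2 * n_chromosome_types and base == 2:
        flags.add("no_numerical_change")
    if abs(profile.N - count) > slack:
        flags.add("count_mismatch")
    return KaryotypeRecord(
        case_id=case_id or text,
        profile=profile,
        subtype=subtype,
        source=source,
        flags=frozenset(flags),
        karyotype=karyotype,
    )


# ---------------------------------------------------------------------------
# Cohort filtering
# ---------------------------------------------------------------------------

DEFAULT_EXCLUSION_RULES = (
    "incomplete",
    "marker",
    "ring",
    "no_numerical_change",
    "adult",
    "recurrent",
)


def filter_cohort(
    records: Iterable[KaryotypeRecord],
    rules: Sequence[str] = DEFAULT_EXCLUSION_RULES,
    adult_age_years: float = 18.0,
) -> list[KaryotypeRecord]:
    """Drop records matching any enabled exclusion rule.

    ``adult`` excludes by flag or by ``age_years`` strictly above
    ``adult_age_years``; the remaining rules match flags directly.  Counts
    removed per rule are logged.  The operation is idempotent.
    """
    removed: Counter[str] = Counter()
    kept: list[KaryotypeRecord] = []
    for rec in records:
        hit = None
        for rule in rules:
            if rule == "adult":
                if "adult" in rec.flags or (
                    rec.age_years is not None and rec.age_years > adult_age_years
                ):
                    hit = rule
                    break
            elif rule in rec.flags:
                hit = rule
                break
        if hit is None:
            kept.append(rec)
        else:
            removed[hit] += 1
    for rule, n in sorted(removed.items()):
        logger.info("filter_cohort: excluded %d record(s) by rule %r", n, rule)
    return kept


# ---------------------------------------------------------------------------
# Profile (cohort) table I/O: one case per row — total chromosome number,
# per-class counts, clinical-genetic subtype
# ---------------------------------------------------------------------------


def write_profile_table(records: Iterable[KaryotypeRecord], path: str | Path) -> None:
    """Write a cohort as a tab-delimited table: N, per-class counts, subtype.

    Copy-number class columns are named ``cn<k>`` and cover every class seen
    in the cohort exactly (no pooling), so the round trip is lossless.
    """
    records = list(records)
    classes = sorted({k for r in records for k, _ in r.profile.items})
    if not classes:
        classes = [2]
    rows = []
    for r in records:
        row: dict[str, object] = {"case_id": r.case_id, "N": r.profile.N}
        for k in classes:
            row[f"cn{k}"] = r.profile.count(k)
        row["subtype"] = r.subtype
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profile_table(
    path: str | Path,
    source: str = "cytogenetics",
    n_chromosome_types: int = N_CHROMOSOME_TYPES,
) -> list[KaryotypeRecord]:
    """Read a cohort table in the layout written by :func:`write_profile_table`.

    The first data column gives the total chromosome number per case, the
    ``cn<k>`` columns the distribution over copy-number classes, the last
    the clinical-genetic subtype.  Rows whose class counts do not sum to the
    number of chromosome types, or whose N disagrees with the class counts,
    are reported with line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    cn_cols = {
        int(str(c)[2:]): c
        for c in df.columns
        if str(c).lower().startswith("cn") and str(c)[2:].isdigit()
    }
    if not cn_cols:
        raise FormatError(f"{path}: no copy-number class columns (cn1, cn2, ...)")
    has_n = "N" in df.columns

    records: list[KaryotypeRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        line = i + 2
        counts = {k: int(row[c]) for k, c in cn_cols.items() if int(row[c]) != 0}
        total_types = sum(counts.values())
        if total_types != n_chromosome_types:
            problems.append(
                f"line {line}: class counts sum to {total_types}, "
                f"expected {n_chromosome_types}"
            )
            continue
        profile = CopyNumberProfile.from_counts(counts, n_chromosome_types)
        if has_n and int(row["N"]) != profile.N:
            problems.append(
                f"line {line}: stated N={int(row['N'])} != class-count N={profile.N}"
            )
            continue
        subtype = str(row["subtype"]) if "subtype" in df.columns else "unknown"
        if subtype not in SUBTYPES:
            subtype = "unknown"
        case_id = str(row["case_id"]) if "case_id" in df.columns else f"case{i + 1}"
        records.append(
            KaryotypeRecord(case_id=case_id, profile=profile, subtype=subtype, source=source)
        )
    if problems:
        raise RowError(problems)
    return records
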