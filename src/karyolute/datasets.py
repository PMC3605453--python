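"""Bundled reference tables from the published neuroblastoma study data.

Two small observed-data tables ship with the package:

* the 30-case clone-prevalence summary (SNP-array mBAF analysis): per case,
  the clinical-genetic subtype, ploidy, aberration counts and the
  prevalence span in percentage points;
* the single-cell-clone FISH heterogeneity table: per cell line, sample
  (mother culture or single-cell clone) and probe, the modal signal count
  and the percentage of nuclei outside it, including the fibroblast
  technical control.

The much larger karyotype cohorts used for segregation-model evaluation
(public cytogenetic and SNP-array copy-number profiles) are not
redistributed; :func:`load_karyotype_cohort` reads a locally supplied copy
in the package's cohort table layout.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .profiles import KaryotypeRecord, read_profile_table


def _read_bundled(name: str) -> pd.DataFrame:
    with resources.files("karyolute.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_prevalence_spans() -> pd.DataFrame:
    """The 30-case clone-prevalence span summary (percentage points)."""
    return _read_bundled("nb_prevalence_spans.tsv")


def mean_span_by_subtype(df: pd.DataFrame | None = None) -> pd.Series:
    """Mean prevalence span per clinical-genetic subtype."""
    if df is None:
        df = load_prevalence_spans()
    return df.groupby("subtype")["span_pct"].mean()


def load_single_cell_clone_fish() -> pd.DataFrame:
    """Per-probe FISH modal numbers and non-modal percentages for two
    neuroblastoma cell lines, their single-cell clones, and the fibroblast
    control."""
    return _read_bundled("single_cell_clone_fish.tsv")


def clone_centromere_means(df: pd.DataFrame | None = None) -> pd.Series:
    """Mean non-modal percentage over centromere probes (whole-chromosome
    copy numbers) across each line's single-cell clones."""
    if df is None:
        df = load_single_cell_clone_fish()
    sel = df[(df["is_clone"] == 1) & df["probe"].str.startswith("CEP")]
    return sel.groupby("cell_line")["nonmodal_pct"].mean()


def load_karyotype_cohort(path: str | Path) -> list[KaryotypeRecord]:
    """Read a locally supplied whole-chromosome copy-number cohort table
    (total chromosome number, per-class counts, subtype per case).

    The cytogenetic (52-case) and SNP-array (68-case) neuroblastoma cohorts
    evaluated against the segregation-error models are not bundled with the
    package; convert them to the ``cn<k>`` column layout documented in
    :func:`karyolute.profiles.read_profile_table` and point this loader at
    the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: karyotype cohort table not found. The published "
            "cytogenetic/SNP-array cohorts are not redistributed with this "
            "package; supply a local copy in the cohort table layout."
        )
    return read_profile_table(path)
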