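"""Stochastic models of mitotic chromosome segregation errors.

Four mechanisms that generate aneuploidy in tumours are simulated, each
starting from a balanced karyotype (diploid N=46 or tetraploid N=92 over 23
chromosome types) and evolving a virtual stem line until its total
chromosome number equals the number observed in a real tumour:

1. **Loss from tetraploidy** — single chromatids are lost sequentially and
   at random from the tetraploid complement; a lost chromatid is drawn
   uniformly over all chromatids, i.e. with probability proportional to a
   chromosome's current copy number.
2. **Sequential sister-chromatid non-disjunction** — each step mis-segregates
   one chromosome (chosen uniformly over types), producing a trisomic and a
   monosomic daughter; the lineage followed is the daughter whose total
   moves toward the target.
3. **Tripolar mitosis with randomised segregation** — after replication every
   chromatid is assigned to one of three poles with equal probability; one
   daughter is followed.
4. **Tripolar mitosis with amphitelic segregation and cytokinetic failure** —
   each sister-chromatid pair splits cleanly between a uniformly chosen pair
   of the three poles; cytokinesis then fails between two fixed poles,
   yielding one merged daughter with chromosome gains and one with losses.

Virtual cells that acquire a nullisomy are eliminated and replaced by
random sampling from the remaining population.  Under monosomy selection,
finished tumours carrying any monosomy are likewise replaced by resampling
from the monosomy-free part of the set.  A cohort of 10,000 virtual tumours
per case yields the *expected prevalence* of the observed copy-number
profile — the probability, under the mechanism, of drawing exactly the
observed distribution of monosomies, disomies, trisomies, etc. — and a
pooled expected copy-number distribution for chi-square comparison against
the observed cohort.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import CopyNumberProfile, KaryotypeRecord, N_CHROMOSOME_TYPES

MODEL_KINDS = (
    "loss_from_tetraploidy",
    "seq_nondisjunction",
    "tripolar_random",
    "tripolar_amphitelic_cytofail",
)

_START_COPIES = {"diploid": 2, "tetraploid": 4}


class SimulationError(RuntimeError):
    """The simulation could not produce the requested population."""


@dataclass(frozen=True)
class SegregationModel:
    """A segregation-error mechanism with its starting ploidy."""

    kind: str
    start_ploidy: str = "tetraploid"

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.start_ploidy not in _START_COPIES:
            raise ValueError(f"unknown start ploidy {self.start_ploidy!r}")
        if self.kind == "loss_from_tetraploidy" and self.start_ploidy != "tetraploid":
            raise ValueError("loss_from_tetraploidy requires a tetraploid start")

    def start_copies(self, n_types: int = N_CHROMOSOME_TYPES) -> int:
        return _START_COPIES[self.start_ploidy]

    def start_N(self, n_types: int = N_CHROMOSOME_TYPES) -> int:
        return self.start_copies(n_types) * n_types

    def reachable(self, targetN: int, n_types: int = N_CHROMOSOME_TYPES) -> bool:
        """Whether a viable (nullisomy-free) stem line with ``targetN``
        chromosomes can arise under this mechanism."""
        if targetN < n_types:  # at least one copy of every type
            return False
        start = self.start_N(n_types)
        if self.kind == "loss_from_tetraploidy":
            return targetN <= start
        if self.kind == "seq_nondisjunction":
            return True  # monotone +/-1 steps reach any viable total
        if self.kind == "tripolar_random":
            return targetN <= 2 * start  # all chromatids to the followed pole
        # amphitelic + cytokinetic failure: losses daughter in [n_types, start],
        # gains daughter in [start, 2*start]
        return targetN <= 2 * start


@dataclass(frozen=True)
class SimulationConfig:
    n_virtual: int = 10_000
    monosomy_selection: bool = False
    seed: int | None = None
    n_chromosome_types: int = N_CHROMOSOME_TYPES
    max_attempts: int = 2_000  # rejection budget, in multiples of n_virtual

    def __post_init__(self):
        if self.n_virtual < 1:
            raise ValueError("n_virtual must be >= 1")


# ---------------------------------------------------------------------------
# Model cores (vectorised over cells; copies arrays are (n_cells, n_types))
# ---------------------------------------------------------------------------


def _weighted_chromatid_loss(
    copies: np.ndarray, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Remove ``n_steps`` chromatids per cell, each drawn uniformly over the
    cell's remaining chromatids (probability proportional to copy number)."""
    n, k = copies.shape
    total = int(copies[0].sum())
    rows = np.arange(n)
    for step in range(n_steps):
        remaining = total - step
        r = rng.integers(0, remaining, size=n)
        cum = np.cumsum(copies, axis=1)
        idx = (r[:, None] >= cum).sum(axis=1)
        copies[rows, idx] -= 1
    return copies


def _uniform_type_loss(copies, n_steps, rng):
    """Uniform-over-types chromatid loss (alternative weighting)."""
    n, k = copies.shape
    rows = np.arange(n)
    for _ in range(n_steps):
        idx = rng.integers(0, k, size=n)
        hit = copies[rows, idx] > 0
        copies[rows[hit], idx[hit]] -= 1
    return copies


def _evolve_loss_from_tetraploidy(targetN, n, n_types, rng, weighting="copy_number"):
    copies = np.full((n, n_types), 4, dtype=np.int64)
    steps = 4 * n_types - targetN
    if weighting == "copy_number":
        copies = _weighted_chromatid_loss(copies, steps, rng)
    else:
        copies = _uniform_type_loss(copies, steps, rng)
    return copies


def _evolve_seq_nondisjunction(startN, targetN, n, n_types, rng):
    copies = np.full((n, n_types), startN // n_types, dtype=np.int64)
    d = 1 if targetN >= startN else -1
    rows = np.arange(n)
    for _ in range(abs(targetN - startN)):
        idx = rng.integers(0, n_types, size=n)
        if d > 0:
            copies[rows, idx] += 1
        else:
            # a chromosome type already at zero cannot mis-segregate; the cell
            # is dead anyway and will be replaced
            hit = copies[rows, idx] > 0
            copies[rows[hit], idx[hit]] -= 1
    return copies


def tripolar_random_division(
    parent: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One tripolar division with randomised chromatid segregation.

    Each chromosome contributes 2x its copy number in chromatids, assigned
    multinomially to the three poles with equal probability.  Returns a
    (3, n_types) array of daughter copy numbers; per chromosome the three
    daughters sum to twice the parent's copy number.
    """
    parent = np.asarray(parent)
    daughters = np.empty((3, parent.size), dtype=np.int64)
    for j, c in enumerate(parent):
        daughters[:, j] = rng.multinomial(2 * int(c), [1 / 3] * 3)
    return daughters


def tripolar_amphitelic_division(
    parent: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One tripolar division with amphitelic segregation and cytokinetic
    failure between two fixed poles.

    Every sister-chromatid pair segregates to a pole pair chosen uniformly
    among the three; the two poles that fail to separate merge into the
    "gains" daughter, the third pole forms the "losses" daughter.  Returns
    (gains, losses); per chromosome they sum to twice the parent copy number.
    """
    parent = np.asarray(parent)
    # X pairs (of the c per type) send both chromatids into the merged poles
    x = rng.binomial(parent, 1 / 3)
    return parent + x, parent - x


def _rejection_sample(draw_batch, accept, n, max_total, batch=20_000):
    """Generic rejection sampler: accumulate ``n`` accepted rows."""
    out = []
    got = 0
    tried = 0
    while got < n:
        if tried >= max_total:
            raise SimulationError(
                f"rejection sampling exhausted after {tried} divisions "
                f"({got}/{n} accepted); target may be effectively unreachable"
            )
        rows = draw_batch(batch)
        keep = rows[accept(rows)]
        tried += batch
        if len(keep):
            out.append(keep[: n - got])
            got += len(out[-1])
    return np.concatenate(out, axis=0)


def _evolve_tripolar_random(startN, targetN, n, n_types, rng, max_total):
    c = startN // n_types
    # The followed daughter of a full multinomial division, marginally:
    # independent Binomial(2c, 1/3) copies per chromosome type.
    def draw(batch):
        return rng.binomial(2 * c, 1 / 3, size=(batch, n_types)).astype(np.int64)

    def accept(rows):
        return (rows.sum(axis=1) == targetN) & (rows.min(axis=1) > 0)

    return _rejection_sample(draw, accept, n, max_total)


def _evolve_tripolar_amphitelic(startN, targetN, n, n_types, rng, max_total):
    c = startN // n_types
    gains_side = targetN > startN

    def draw(batch):
        x = rng.binomial(c, 1 / 3, size=(batch, n_types)).astype(np.int64)
        return c + x if gains_side else c - x

    def accept(rows):
        return (rows.sum(axis=1) == targetN) & (rows.min(axis=1) > 0)

    return _rejection_sample(draw, accept, n, max_total)


# ---------------------------------------------------------------------------
# Population assembly: nullisomy elimination and monosomy selection
# ---------------------------------------------------------------------------


def _replace_rows(copies, bad, rng, what):
    """Replace ``bad`` rows by uniform resampling from the remaining rows."""
    if not bad.any():
        return copies
    good_idx = np.flatnonzero(~bad)
    if good_idx.size == 0:
        raise SimulationError(f"every virtual tumour was {what}; replacement pool empty")
    take = rng.integers(0, good_idx.size, size=int(bad.sum()))
    copies[np.flatnonzero(bad)] = copies[good_idx[take]]
    return copies


def evolve_to_target_copies(
    model: SegregationModel,
    targetN: int,
    config: SimulationConfig = SimulationConfig(),
    rng: np.random.Generator | None = None,
    loss_weighting: str = "copy_number",
) -> np.ndarray:
    """Evolve ``config.n_virtual`` virtual tumours to ``targetN`` chromosomes.

    Returns an (n_virtual, n_types) copy-number array.  Cells acquiring a
    nullisomy during evolution are eliminated by replacement with random
    sampling from the remaining population; with ``monosomy_selection``,
    finished tumours with any monosomy are replaced by resampling from the
    monosomy-free tumours.
    """
    n_types = config.n_chromosome_types
    if not model.reachable(targetN, n_types):
        raise ValueError(
            f"targetN={targetN} unreachable under {model.kind} from "
            f"{model.start_ploidy} start with {n_types} chromosome types"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_virtual
    startN = model.start_N(n_types)
    max_total = config.max_attempts * n

    if model.kind == "loss_from_tetraploidy":
        copies = _evolve_loss_from_tetraploidy(
            targetN, n, n_types, rng, weighting=loss_weighting
        )
    elif model.kind == "seq_nondisjunction":
        copies = _evolve_seq_nondisjunction(startN, targetN, n, n_types, rng)
    elif model.kind == "tripolar_random":
        copies = _evolve_tripolar_random(startN, targetN, n, n_types, rng, max_total)
    else:
        copies = _evolve_tripolar_amphitelic(
            startN, targetN, n, n_types, rng, max_total
        )

    # both loss routes are monotone, so a nullisomy ever acquired is still
    # present at the end; the tripolar samplers reject non-viable daughters
    copies = _replace_rows(copies, (copies == 0).any(axis=1), rng, "nullisomic")
    if config.monosomy_selection:
        copies = _replace_rows(copies, (copies == 1).any(axis=1), rng, "monosomic")
    assert (copies.sum(axis=1) == targetN).all()
    return copies


def evolve_to_target(
    model: SegregationModel,
    targetN: int,
    config: SimulationConfig = SimulationConfig(),
    rng: np.random.Generator | None = None,
) -> list[CopyNumberProfile]:
    """As :func:`evolve_to_target_copies`, returning copy-number profiles."""
    copies = evolve_to_target_copies(model, targetN, config, rng)
    return [CopyNumberProfile.from_copies(row) for row in copies]


# ---------------------------------------------------------------------------
# Statistics over simulated populations
# ---------------------------------------------------------------------------


def _as_copies_array(simulated) -> np.ndarray:
    if isinstance(simulated, np.ndarray):
        return simulated
    rows = []
    for p in simulated:
        if isinstance(p, CopyNumberProfile):
            rows.append(p.sorted_copies())
        else:
            rows.append(np.sort(np.asarray(p)))
    if not rows:
        return np.empty((0, 0), dtype=np.int64)
    return np.asarray(rows, dtype=np.int64)


def expected_prevalence(observed: CopyNumberProfile, simulated) -> float:
    """Fraction of simulated tumours whose copy-number class counts equal
    the observed profile's (which chromosome carries which copy number is
    ignored)."""
    sim = _as_copies_array(simulated)
    if sim.size == 0:
        raise ValueError("empty simulated population")
    obs = np.asarray(observed.sorted_copies(), dtype=np.int64)
    simN = sim.sum(axis=1)
    if not (simN == observed.N).all():
        raise ValueError(
            f"simulated chromosome numbers {np.unique(simN)} do not all match "
            f"observed N={observed.N}"
        )
    sim_sorted = np.sort(sim, axis=1)
    return float((sim_sorted == obs).all(axis=1).mean())


def pooled_cn_distribution(population) -> dict[int, float]:
    """Relative frequencies of copy-number classes pooled over a population
    of profiles, records or a copies array.  Frequencies sum to 1."""
    if isinstance(population, np.ndarray):
        vals, cnt = np.unique(population, return_counts=True)
        total = population.size
        return {int(v): float(c) / total for v, c in zip(vals, cnt)}
    counter: Counter[int] = Counter()
    total = 0
    for item in population:
        profile = item.profile if isinstance(item, KaryotypeRecord) else item
        for k, v in profile.items:
            counter[k] += v
            total += v
    if total == 0:
        raise ValueError("empty population")
    return {k: counter[k] / total for k in sorted(counter)}


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    pvalue: float
    df: int
    classes: tuple[int, ...]  # class labels after sparse pooling


def chisq_compare(
    observed_counts: Mapping[int, float],
    expected_freqs: Mapping[int, float],
    min_expected: float = 5.0,
) -> ChisqResult:
    """Pearson chi-square of observed class counts against expected relative
    frequencies, with df = classes - 1.

    Classes whose expected count falls below ``min_expected`` are pooled
    into the adjacent class (upward, then the tail downward) before testing.
    """
    classes = sorted(set(observed_counts) | set(expected_freqs))
    obs = np.array([observed_counts.get(k, 0.0) for k in classes], dtype=float)
    if obs.sum() == 0:
        raise ValueError("all-zero observed counts")
    exp = np.array([expected_freqs.get(k, 0.0) for k in classes], dtype=float)
    exp = exp / exp.sum() * obs.sum()

    # pool sparse classes into their upper neighbour, then mop up the tail
    o, e, labs = [], [], []
    acc_o = acc_e = 0.0
    acc_lab = None
    for k, ok, ek in zip(classes, obs, exp):
        acc_o += ok
        acc_e += ek
        acc_lab = k if acc_lab is None else acc_lab
        if acc_e >= min_expected:
            o.append(acc_o)
            e.append(acc_e)
            labs.append(acc_lab)
            acc_o = acc_e = 0.0
            acc_lab = None
    if acc_lab is not None:
        if o:
            o[-1] += acc_o
            e[-1] += acc_e
        else:
            o, e, labs = [acc_o], [acc_e], [acc_lab]
    o_arr, e_arr = np.asarray(o), np.asarray(e)
    if len(o_arr) < 2:
        return ChisqResult(0.0, 1.0, 0, tuple(labs))
    stat, p = stats.chisquare(o_arr, f_exp=e_arr)
    return ChisqResult(float(stat), float(p), len(o_arr) - 1, tuple(labs))


# ---------------------------------------------------------------------------
# Cohort evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortEvaluation:
    """Result of evaluating one segregation-error model against a cohort."""

    model: SegregationModel
    per_case: pd.DataFrame  # case_id, N, expected_prevalence, flag
    mean_prevalence: float
    pooled_expected: dict[int, float]
    pooled_observed: dict[int, float]
    chisq: ChisqResult | None


def run_cohort_evaluation(
    cohort: Sequence[KaryotypeRecord],
    model: SegregationModel,
    config: SimulationConfig = SimulationConfig(),
) -> CohortEvaluation:
    """Evaluate a segregation-error model against a cohort of tumours.

    For every case, ``config.n_virtual`` virtual tumours are evolved to the
    case's chromosome number and the expected prevalence of the case's
    profile is recorded.  Cases whose chromosome number is unreachable under
    the model are flagged and scored at prevalence 0 (the mechanism assigns
    them zero probability).  The pooled simulated copy-number distribution
    is compared to the cohort's observed pooled distribution by chi-square.
    """
    if not cohort:
        raise ValueError("empty cohort")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(cohort))

    rows = []
    sim_class_counts: Counter[int] = Counter()
    n_sim_total = 0
    for rec, child in zip(cohort, children):
        targetN = rec.profile.N
        rng = np.random.default_rng(child)
        if not model.reachable(targetN, config.n_chromosome_types):
            rows.append(
                dict(case_id=rec.case_id, N=targetN, expected_prevalence=0.0,
                     flag="unreachable")
            )
            continue
        try:
            copies = evolve_to_target_copies(model, targetN, config, rng)
        except SimulationError as exc:
            rows.append(
                dict(case_id=rec.case_id, N=targetN, expected_prevalence=0.0,
                     flag=f"simulation_error: {exc}")
            )
            continue
        prev = expected_prevalence(rec.profile, copies)
        rows.append(
            dict(case_id=rec.case_id, N=targetN, expected_prevalence=prev, flag="")
        )
        vals, cnt = np.unique(copies, return_counts=True)
        for v, c in zip(vals, cnt):
            sim_class_counts[int(v)] += int(c)
        n_sim_total += copies.size

    per_case = pd.DataFrame(rows)
    mean_prev = float(per_case["expected_prevalence"].mean())

    pooled_observed_freq = pooled_cn_distribution(cohort)
    n_obs_types = sum(v for r in cohort for _, v in r.profile.items)
    observed_counts = {k: f * n_obs_types for k, f in pooled_observed_freq.items()}

    if n_sim_total:
        pooled_expected = {k: v / n_sim_total for k, v in sorted(sim_class_counts.items())}
        chisq = chisq_compare(observed_counts, pooled_expected)
    else:
        pooled_expected = {}
        chisq = None
    return CohortEvaluation(
        model=model,
        per_case=per_case,
        mean_prevalence=mean_prev,
        pooled_expected=pooled_expected,
        pooled_observed=pooled_observed_freq,
        chisq=chisq,
    )


def rank_models(
    cohort: Sequence[KaryotypeRecord],
    models: Sequence[SegregationModel],
    config: SimulationConfig = SimulationConfig(),
) -> pd.DataFrame:
    """Evaluate several models on one cohort; rows sorted by mean expected
    prevalence, best first."""
    rows = []
    for i, model in enumerate(models):
        cfg = config if config.seed is None else replace(config, seed=config.seed + i)
        ev = run_cohort_evaluation(cohort, model, cfg)
        rows.append(
            dict(
                kind=model.kind,
                start_ploidy=model.start_ploidy,
                mean_prevalence=ev.mean_prevalence,
                chisq_p=ev.chisq.pvalue if ev.chisq else float("nan"),
            )
        )
    return (
        pd.DataFrame(rows)
        .sort_values("mean_prevalence", ascending=False)
        .reset_index(drop=True)
    )
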