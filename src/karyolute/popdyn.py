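"""Generational population model of chromosome loss under whole-genome
duplication and viability selection.

A synchronized population of ``n_cells`` virtual cells, each a vector of 23
chromosome-type copy numbers starting from a normal diploid genome, evolves
for a fixed number of mitotic generations.  At each mitosis a cell either
undergoes whole-genome duplication with probability ``t`` (every copy
number doubles), or divides with independent per-chromosome single-copy
loss with probability ``p`` per chromosome, the remainder ``1 - p - t``
being error-free divisions.  Cells left with <= 1 copy of any chromosome
(monosomy or nullisomy) or with more than ``max_N`` chromosomes are
excluded from future generations; the population is then restored to
constant size by uniform resampling among the surviving viable cells.

With the defaults (p = 0.04 per chromosome per mitosis, t = 0.06, exclusion
above N = 92) the interplay of continuous chromosome loss, selection
against monosomy and occasional tetraploidisation drives the population to
fluctuate around the triploid level: an early hypotetraploid takeover is
followed by gradual drift down through triploidy toward hyperdiploidy, at
which point cells that re-duplicate their genome again take over.  The
control population with duplication disabled stays diploid, because any
loss from disomy creates a monosomy and is selected away.

*Net growth* at a time point is the fraction of newly formed cells that
remain able to divide, i.e. are free of nullisomies, monosomies and high
polyploidy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .profiles import N_CHROMOSOME_TYPES


class ExtinctionError(RuntimeError):
    """No viable cell survived a generation."""

    def __init__(self, generation: int):
        self.generation = generation
        super().__init__(f"population extinct at generation {generation}")


@dataclass(frozen=True)
class DynamicsConfig:
    """Parameters of the dynamic model.

    p : per-chromosome, per-mitosis probability of losing one copy.
    t : per-mitosis probability of whole-genome duplication; exclusive with
        loss within a single mitosis.
    max_N : viability ceiling on total chromosome number.
    wgd_enabled : False gives the control population (no duplication).
    """

    p: float = 0.04
    t: float = 0.06
    n_cells: int = 10_000
    generations: int = 500
    max_N: int = 92
    seed: int | None = None
    wgd_enabled: bool = True
    n_chromosome_types: int = N_CHROMOSOME_TYPES
    start_copies: int = 2

    def __post_init__(self):
        if not (0 <= self.p <= 1 and 0 <= self.t <= 1 and self.p + self.t <= 1):
            raise ValueError("need 0 <= p, t and p + t <= 1")
        if self.n_cells < 1 or self.generations < 0:
            raise ValueError("n_cells >= 1 and generations >= 0 required")


@dataclass
class Trajectory:
    """Per-generation population summary.

    ``histograms[g]`` counts cells by total chromosome number N (index 0..
    max_N) in the viable population recorded at generation g; row sums all
    equal ``n_cells``.  ``net_growth[g]`` is the viable fraction of the
    cells produced at generation g (1.0 at g = 0 by convention).
    """

    config: DynamicsConfig
    histograms: np.ndarray  # (generations+1, max_N+1)
    mean_N: np.ndarray  # (generations+1,)
    net_growth: np.ndarray  # (generations+1,)

    @property
    def n_generations(self) -> int:
        return len(self.mean_N) - 1

    def modal_N(self, generation: int) -> int:
        """Most frequent total chromosome number at a generation."""
        return int(np.argmax(self.histograms[generation]))

    def mean_N_over(self, start: int, stop: int) -> float:
        """Mean of per-generation mean N over generations [start, stop]."""
        return float(self.mean_N[start : stop + 1].mean())


def step_generation(
    population: np.ndarray, config: DynamicsConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Advance the population one synchronized mitotic generation.

    Returns the next viable population (restored to ``n_cells`` by uniform
    resampling among survivors) and the viable fraction before resampling.
    Raises :class:`ExtinctionError` via the caller when no cell survives.
    """
    n, k = population.shape
    if config.wgd_enabled and config.t > 0:
        wgd = rng.random(n) < config.t
    else:
        wgd = np.zeros(n, dtype=bool)
    losses = (rng.random((n, k)) < config.p) & ~wgd[:, None]
    offspring = np.where(wgd[:, None], population * 2, population - losses)

    viable = (offspring.min(axis=1) >= 2) & (offspring.sum(axis=1) <= config.max_N)
    frac = float(viable.mean())
    survivors = offspring[viable]
    if survivors.shape[0] == 0:
        return survivors, 0.0
    take = rng.integers(0, survivors.shape[0], size=n)
    return survivors[take], frac


def run_dynamics(config: DynamicsConfig = DynamicsConfig()) -> Trajectory:
    """Run the full dynamic model; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    k = config.n_chromosome_types
    pop = np.full((config.n_cells, k), config.start_copies, dtype=np.int64)

    G = config.generations
    hist = np.zeros((G + 1, config.max_N + 1), dtype=np.int64)
    mean_N = np.zeros(G + 1)
    net_growth = np.ones(G + 1)

    def record(g, population):
        N = population.sum(axis=1)
        hist[g] = np.bincount(N, minlength=config.max_N + 1)
        mean_N[g] = N.mean()

    record(0, pop)
    for g in range(1, G + 1):
        pop, frac = step_generation(pop, config, rng)
        if pop.shape[0] == 0:
            raise ExtinctionError(g)
        net_growth[g] = frac
        record(g, pop)
    return Trajectory(config=config, histograms=hist, mean_N=mean_N, net_growth=net_growth)
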