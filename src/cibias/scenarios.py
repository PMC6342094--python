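"""Genotype-level fitness simulator for cytoplasmic-incompatibility scenarios.

Unidirectional cytoplasmic incompatibility (CI) caused by *Wolbachia* ruins
crosses between infected males and uninfected females: uninfected genotypes
can therefore show collapsed female fitness while — because infected males
are often poor sperm competitors — their males may be unusually fit.  The
simulator draws sex-specific fitness for a panel of genotypes under a
configurable fraction of CI-affected (uninfected) genotypes and either
"random" or "high" male fitness for those genotypes, then measures how often
the male-female fitness correlation across genotypes comes out negative
and/or significant.  A grid runner sweeps the standard 3 x 2 battery
({0%, 10%, 20% CI} x {random, high male fitness}).

Fitness values are plain normal draws (no truncation at zero), matching the
behaviour of ``rnorm``-style generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stats import (
    CorrelationResult,
    CorrelationTallies,
    DegenerateDataError,
    pearson_rmf,
    tally_correlations,
)

__all__ = [
    "ScenarioConfig",
    "ReplicateTable",
    "ScenarioSummary",
    "simulate_replicate",
    "run_scenario",
    "run_scenario_grid",
    "grid_to_frame",
]

MALE_MODES = ("random", "high")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulated CI scenario.

    Defaults are the standard study conditions: 10 genotypes, 100 replicates,
    baseline fitness ~ Normal(60, 15), CI females ~ Normal(5, 2), high-male
    fitness ~ Normal(85, 15), two-tailed alpha 0.05.
    """

    n_genotypes: int = 10
    n_replicates: int = 100
    baseline_mean: float = 60.0
    baseline_sd: float = 15.0
    ci_female_mean: float = 5.0
    ci_female_sd: float = 2.0
    high_male_mean: float = 85.0
    high_male_sd: float = 15.0
    ci_fraction: float = 0.0
    male_mode: str = "random"
    alpha: float = 0.05
    seed: int | None = None

    @property
    def n_uninfected(self) -> int:
        """Genotypes flagged uninfected (CI-affected) per replicate."""
        return round(self.ci_fraction * self.n_genotypes)

    def validate(self) -> None:
        if self.n_genotypes < 3:
            raise ValueError(f"n_genotypes must be >= 3, got {self.n_genotypes}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        for name in ("baseline_sd", "ci_female_sd", "high_male_sd"):
            sd = getattr(self, name)
            if not sd > 0:
                raise ValueError(f"{name} must be > 0, got {sd}")
        if not 0.0 <= self.ci_fraction < 1.0:
            raise ValueError(f"ci_fraction must be in [0, 1), got {self.ci_fraction}")
        if self.n_uninfected >= self.n_genotypes:
            raise ValueError(
                f"ci_fraction={self.ci_fraction} would mark all "
                f"{self.n_genotypes} genotypes as uninfected"
            )
        if self.male_mode not in MALE_MODES:
            raise ValueError(
                f"male_mode must be one of {MALE_MODES}, got {self.male_mode!r}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class ReplicateTable:
    """One replicate: per-genotype mean fitness for each sex.

    ``uninfected[i]`` is True where genotype ``i`` lacks the infection and its
    females suffered CI.
    """

    male_fitness: np.ndarray
    female_fitness: np.ndarray
    uninfected: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.male_fitness)
        if not (len(self.female_fitness) == len(self.uninfected) == n):
            raise ValueError("replicate columns must have equal length")

    @property
    def n_genotypes(self) -> int:
        return len(self.male_fitness)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype_id": np.arange(self.n_genotypes),
                "male_fitness": self.male_fitness,
                "female_fitness": self.female_fitness,
                "uninfected": self.uninfected,
            }
        )


@dataclass(frozen=True)
class ScenarioSummary:
    """Tallies of correlation sign/significance over a scenario's replicates."""

    config: ScenarioConfig
    tallies: CorrelationTallies
    per_replicate: list[CorrelationResult | None] = field(repr=False)

    @property
    def n_positive(self) -> int:
        return self.tallies.n_positive

    @property
    def n_negative(self) -> int:
        return self.tallies.n_negative

    @property
    def n_sig_positive(self) -> int:
        return self.tallies.n_sig_positive

    @property
    def n_sig_negative(self) -> int:
        return self.tallies.n_sig_negative

    @property
    def n_significant(self) -> int:
        return self.tallies.n_sig_positive + self.tallies.n_sig_negative


def simulate_replicate(
    config: ScenarioConfig, rng: np.random.Generator
) -> ReplicateTable:
    """Draw one replicate of per-genotype male and female fitness.

    Infected genotypes get both sexes from Normal(baseline_mean, baseline_sd).
    ``round(ci_fraction * n_genotypes)`` genotypes, chosen uniformly without
    replacement, are uninfected: their females come from
    Normal(ci_female_mean, ci_female_sd) and their males from the baseline
    distribution (``male_mode="random"``) or from
    Normal(high_male_mean, high_male_sd) (``male_mode="high"``).
    """
    config.validate()
    n = config.n_genotypes
    male = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    female = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    uninfected = np.zeros(n, dtype=bool)
    k = config.n_uninfected
    if k > 0:
        idx = rng.choice(n, size=k, replace=False)
        uninfected[idx] = True
        female[idx] = rng.normal(config.ci_female_mean, config.ci_female_sd, size=k)
        if config.male_mode == "high":
            male[idx] = rng.normal(config.high_male_mean, config.high_male_sd, size=k)
    return ReplicateTable(male_fitness=male, female_fitness=female, uninfected=uninfected)


def run_scenario(
    config: ScenarioConfig, seed_seq: np.random.SeedSequence | None = None
) -> ScenarioSummary:
    """Run all replicates of one scenario and tally correlation outcomes.

    Each replicate's male-vs-female Pearson correlation across genotypes is
    tested two-tailed at ``config.alpha``.  A degenerate replicate (zero
    variance in either sex — only possible with pathological parameters) is
    recorded as ``None``, excluded from both tallies, and warned about.
    Replicates use independent substreams spawned from ``config.seed`` (or
    from ``seed_seq`` when given), so batteries are reproducible and
    order-independent.
    """
    config.validate()
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    results: list[CorrelationResult | None] = []
    for i, child in enumerate(seed_seq.spawn(config.n_replicates)):
        table = simulate_replicate(config, np.random.default_rng(child))
        try:
            results.append(pearson_rmf(table.male_fitness, table.female_fitness))
        except DegenerateDataError as exc:
            warnings.warn(
                f"replicate {i}: correlation undefined ({exc}); "
                "excluded from tallies",
                stacklevel=2,
            )
            results.append(None)
    tallies = tally_correlations(results, alpha=config.alpha)
    return ScenarioSummary(config=config, tallies=tallies, per_replicate=results)


#: The standard scenario battery, in presentation order.
GRID = (
    (0.0, "random"),
    (0.1, "random"),
    (0.2, "random"),
    (0.0, "high"),
    (0.1, "high"),
    (0.2, "high"),
)


def run_scenario_grid(
    base_config: ScenarioConfig | None = None, seed: int | None = None
) -> list[ScenarioSummary]:
    """Run the 3 x 2 battery {0, 10, 20% CI} x {random, high male fitness}.

    Every cell inherits ``base_config``'s parameters; each gets an
    independent substream of ``seed`` so cells are reproducible and
    order-independent.
    """
    base = base_config if base_config is not None else ScenarioConfig()
    if seed is None:
        seed = base.seed
    cell_seeds = np.random.SeedSequence(seed).spawn(len(GRID))
    summaries = []
    for (ci, mode), cell_ss in zip(GRID, cell_seeds):
        cfg = replace(base, ci_fraction=ci, male_mode=mode, seed=seed)
        summaries.append(run_scenario(cfg, seed_seq=cell_ss))
    return summaries


def grid_to_frame(summaries: list[ScenarioSummary]) -> pd.DataFrame:
    """Tabulate a scenario battery: one row per scenario, four tallies."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "ci_percent": round(s.config.ci_fraction * 100),
                "male_mode": s.config.male_mode,
                "n_positive": s.n_positive,
                "n_negative": s.n_negative,
                "n_sig_positive": s.n_sig_positive,
                "n_sig_negative": s.n_sig_negative,
            }
        )
    return pd.DataFrame(rows)
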