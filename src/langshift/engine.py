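"""Simulation orchestration: years of interaction rounds plus demographic change.

A run executes ``years`` model years.  Within each year: ``T`` interaction
rounds (default 365), then the year boundary — every agent's tenure
increments, the SLA innovation pass runs (Model 2 only), and the regime's
demographic step fires.  Two innovation models are supported:

* **Model 1** — an L2 speaker may innovate only at the moment of entry
  (with probability ``mu`` it enters with the pure novel-variant
  distribution instead of the population mean).
* **Model 2 (SLA)** — in addition, every L2 speaker still within the
  second-language-acquisition window (default seven years after entry)
  independently mutates to the pure novel-variant distribution with
  probability ``mu`` at the start of each year.  Entry counts as the
  tenure-0 opportunity, so the default window gives exactly seven
  opportunities per recruit.

Replicate ensembles at one parameter setting summarise the cross-run mean
and spread of the novel variant's mean usage per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from ._kernel import run_rounds
from .core import (
    LearningParams,
    Population,
    SpeakerClass,
    interaction_round,
    mutate_to_novel,
)
from .demography import (
    CensusTable,
    DemographicSchedule,
    RateSet,
    census_to_schedule,
    expanding_step,
    fixed_step,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "Ensemble",
    "LanguageShiftModel",
    "run_year",
    "sla_mutation_pass",
    "run_simulation",
    "run_ensemble",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one simulation run.

    Parameters
    ----------
    model : {"model1", "model2"}
        Innovation model: entry-only, or entry plus the multi-year SLA window.
    regime : {"fixed", "expanding", "census"}
        Demographic regime.
    n0 : int
        Initial population size (fixed/expanding regimes).
    rates : RateSet
        Per-capita b, r, d (fixed/expanding regimes).
    census : CensusTable, optional
        Census table (census regime); the start year and horizon follow it.
    mortality : float
        Per-capita death rate used to build the census schedule (default 0.02).
    scale : float
        Census-count divisor for desk-scale runs (default 100).
    params : LearningParams
        Learning weight l, innovation rate mu, novel variant index.
    n_variants : int
        Number of variants of the feature (study runs use 2).
    T : int
        Interaction rounds per year (default 365).
    years : int
        Horizon in model years (ignored for census runs, which cover the table).
    sla_window_years : int
        Length of the SLA window for model2 (default 7).
    sla_entry_counts : bool
        If True (default) entry is the tenure-0 opportunity and the annual
        pass covers tenures 1..window-1 (window opportunities in total); if
        False the pass covers tenures 1..window (window + 1 in total).
    """

    model: Literal["model1", "model2"] = "model1"
    regime: Literal["fixed", "expanding", "census"] = "fixed"
    n0: int = 100
    rates: RateSet = field(default_factory=RateSet)
    census: CensusTable | None = None
    mortality: float = 0.02
    scale: float = 100.0
    params: LearningParams = field(default_factory=LearningParams)
    n_variants: int = 2
    T: int = 365
    years: int = 100
    sla_window_years: int = 7
    sla_entry_counts: bool = True

    def __post_init__(self) -> None:
        if self.model not in ("model1", "model2"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.regime not in ("fixed", "expanding", "census"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.T < 0 or self.years < 1 or self.sla_window_years < 1:
            raise ValueError("T must be >= 0, years and sla_window_years >= 1")
        if self.regime == "census" and self.census is None:
            raise ValueError("census regime requires a census table")
        if self.regime != "census" and self.n0 < 2:
            raise ValueError("n0 must be >= 2")


class Trajectory:
    """Per-year record of one run.

    ``frame`` columns: year, mean_novel, n, n_l1, n_l2, innovations — where
    mean_novel is the population mean usage of the novel variant and
    innovations counts cumulative innovation events.
    """

    def __init__(self, frame: pd.DataFrame, config: SimulationConfig, seed: int):
        self.frame = frame
        self.config = config
        self.seed = seed

    @property
    def years(self) -> np.ndarray:
        return self.frame["year"].to_numpy()

    @property
    def mean_novel(self) -> np.ndarray:
        return self.frame["mean_novel"].to_numpy()

    def at_year(self, year: int) -> float:
        """Novel-variant mean usage at one (calendar) year."""
        row = self.frame.loc[self.frame["year"] == year, "mean_novel"]
        if row.empty:
            raise KeyError(f"year {year} not in trajectory")
        return float(row.iloc[0])

    def to_csv(self, path, run_id: int = 0) -> None:
        out = self.frame.copy()
        out.insert(0, "run_id", run_id)
        out.to_csv(path, index=False)

    def plot(self, ax=None, **kwargs):
        """Novel-variant mean usage over time (matplotlib line plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.years, self.mean_novel, **kwargs)
        ax.set_xlabel("year")
        ax.set_ylabel("mean usage of novel variant")
        ax.set_ylim(-0.02, 1.02)
        return ax


class Ensemble:
    """R replicate trajectories at one configuration.

    Cross-run per-year mean ``m_y`` and standard deviation ``s_y`` (ddof=1) of
    the novel variant's mean usage summarise the model's predictive spread;
    the 95% band is ``m_y ± 1.96 s_y`` (spread of runs, not a standard error).
    """

    def __init__(self, trajectories: list[Trajectory], master_seed: int):
        if not trajectories:
            raise ValueError("an ensemble needs at least one trajectory")
        self.trajectories = trajectories
        self.master_seed = master_seed

    @property
    def R(self) -> int:
        return len(self.trajectories)

    @property
    def config(self) -> SimulationConfig:
        return self.trajectories[0].config

    @property
    def years(self) -> np.ndarray:
        return self.trajectories[0].years

    def values_at(self, year: int) -> np.ndarray:
        """Per-run novel-variant mean usage at one year."""
        return np.array([t.at_year(year) for t in self.trajectories])

    def summary(self) -> pd.DataFrame:
        """Per-year cross-run mean, sd and 95% interval (mean ± 1.96 sd)."""
        stack = np.column_stack([t.mean_novel for t in self.trajectories])
        m = stack.mean(axis=1)
        if self.R >= 2:
            s = stack.std(axis=1, ddof=1)
        else:
            s = np.full_like(m, np.nan)  # spread undefined for a single run
        return pd.DataFrame(
            {
                "year": self.years,
                "mean": m,
                "sd": s,
                "ci_lo": m - 1.96 * s,
                "ci_hi": m + 1.96 * s,
            }
        )

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)

    def plot(self, ax=None, band: bool = True, **kwargs):
        """Ensemble mean trajectory with the 95% predictive band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.summary()
        (line,) = ax.plot(s["year"], s["mean"], **kwargs)
        if band and self.R >= 2:
            ax.fill_between(s["year"], s["ci_lo"], s["ci_hi"],
                            alpha=0.2, color=line.get_color())
        ax.set_xlabel("year")
        ax.set_ylabel("mean usage of novel variant")
        return ax


# ---------------------------------------------------------------------------
# year loop
# ---------------------------------------------------------------------------

def sla_mutation_pass(
    pop: Population,
    params: LearningParams,
    sla_window_years: int,
    rng: np.random.Generator,
    entry_counts: bool = True,
) -> Population:
    """Annual SLA innovation: eligible L2 speakers mutate with probability mu.

    Eligible are L2 agents whose tenure is below the SLA window (strictly
    below when entry already consumed the tenure-0 opportunity, at most the
    window otherwise).  Each eligible agent independently becomes the pure
    novel-variant distribution with probability ``mu``; agents who already
    mutated may mutate again (a no-op on their usage).
    """
    limit = sla_window_years if entry_counts else sla_window_years + 1
    eligible = np.flatnonzero(
        (pop.speaker_class == SpeakerClass.L2.value) & (pop.tenure < limit)
    )
    if len(eligible) == 0:
        return pop
    hits = eligible[rng.random(len(eligible)) < params.mu]
    if len(hits):
        pop.probs[hits] = 0.0
        pop.probs[hits, params.novel_index - 1] = 1.0
        pop.innovations += len(hits)
    return pop


def run_year(
    pop: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    schedule: DemographicSchedule | None = None,
) -> Population:
    """One model year: T rounds, tenure increment, SLA pass, demographic step."""
    run_rounds(pop.probs, config.T, config.params.l, rng)
    pop.tenure += 1
    if config.model == "model2":
        sla_mutation_pass(
            pop, config.params, config.sla_window_years, rng,
            entry_counts=config.sla_entry_counts,
        )
    if config.regime == "fixed":
        fixed_step(pop, config.rates, config.params, rng)
    elif config.regime == "expanding":
        expanding_step(pop, config.rates, config.params, rng)
    else:
        schedule.census_step(pop, config.params, rng)
    pop.year += 1
    pop.revalidate()
    return pop


def _initial_population(
    config: SimulationConfig, schedule: DemographicSchedule | None
) -> Population:
    if config.regime == "census":
        start_year = int(schedule.years[0])
        first = config.census.frame.iloc[0]
        n_l1 = int(np.floor(first["l1_count"] / config.scale + 0.5))
        n_l2 = int(np.floor(first["l2_count"] / config.scale + 0.5))
        # pre-start L2 speakers are established: no remaining SLA opportunities
        return Population.conservative(
            n_l1, n_l2, config.n_variants,
            l2_tenure=config.sla_window_years + 1, year=start_year,
        )
    return Population.conservative(config.n0, 0, config.n_variants)


def run_simulation(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
    schedule: DemographicSchedule | None = None,
) -> Trajectory:
    """Run one simulation; a deterministic function of (config, seed).

    For the census regime a precomputed ``DemographicSchedule`` may be passed
    (e.g. to share one schedule across replicates); otherwise one is built
    from the config's census table using the same seed stream.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    if config.regime == "census" and schedule is None:
        schedule = census_to_schedule(
            config.census, mortality=config.mortality, scale=config.scale, rng=rng
        )
    pop = _initial_population(config, schedule)
    years = len(schedule) if config.regime == "census" else config.years
    novel = config.params.novel_index - 1

    records = [_record(pop, novel)]
    for _ in range(years):
        run_year(pop, config, rng, schedule)
        records.append(_record(pop, novel))
    frame = pd.DataFrame(
        records, columns=["year", "mean_novel", "n", "n_l1", "n_l2", "innovations"]
    )
    seed_repr = seed if isinstance(seed, int) else -1
    return Trajectory(frame, config, seed_repr)


def _record(pop: Population, novel: int) -> tuple:
    return (
        pop.year,
        float(pop.probs[:, novel].mean()),
        pop.size,
        pop.n_l1,
        pop.n_l2,
        pop.innovations,
    )


def run_ensemble(
    config: SimulationConfig,
    R: int,
    master_seed: int,
    schedule: DemographicSchedule | None = None,
) -> Ensemble:
    """R independent replicates with seeds spawned from one master seed."""
    if R < 1:
        raise ValueError("R must be >= 1")
    root = np.random.SeedSequence(master_seed)
    if config.regime == "census" and schedule is None:
        sched_ss, *run_seeds = root.spawn(R + 1)
        schedule = census_to_schedule(
            config.census, mortality=config.mortality, scale=config.scale,
            rng=np.random.default_rng(sched_ss),
        )
    else:
        run_seeds = root.spawn(R)
    trajectories = [run_simulation(config, ss, schedule) for ss in run_seeds]
    return Ensemble(trajectories, master_seed)


class LanguageShiftModel:
    """Front-end tying a configuration to runs, ensembles and sweeps.

    Examples
    --------
    >>> from langshift import LanguageShiftModel, RateSet, LearningParams
    >>> m = LanguageShiftModel(regime="expanding", n0=100,
    ...                        rates=RateSet(b=0.007, r=0.063, d=0.02),
    ...                        params=LearningParams(l=0.05, mu=0.05))
    >>> traj = m.simulate(seed=1)
    >>> ens = m.ensemble(R=10, master_seed=1)
    """

    def __init__(self, config: SimulationConfig | None = None, **kwargs):
        if config is None:
            config = SimulationConfig(**kwargs)
        elif kwargs:
            config = replace(config, **kwargs)
        self.config = config
        self._schedule: DemographicSchedule | None = None

    @classmethod
    def maputo(cls, census: CensusTable, **kwargs) -> "LanguageShiftModel":
        """Census-driven model over a Maputo-style L1/L2 census table."""
        return cls(SimulationConfig(regime="census", census=census, **kwargs))

    def with_params(self, **kwargs) -> "LanguageShiftModel":
        """Copy of the model with LearningParams fields replaced."""
        return LanguageShiftModel(
            replace(self.config, params=replace(self.config.params, **kwargs))
        )

    def schedule(self, seed: int = 0) -> DemographicSchedule:
        """The demographic schedule for census runs (cached per model)."""
        if self.config.regime != "census":
            raise ValueError("schedules only exist for the census regime")
        if self._schedule is None:
            self._schedule = census_to_schedule(
                self.config.census, mortality=self.config.mortality,
                scale=self.config.scale, rng=np.random.default_rng(seed),
            )
        return self._schedule

    def simulate(self, seed: int) -> Trajectory:
        sched = self.schedule() if self.config.regime == "census" else None
        return run_simulation(self.config, seed, sched)

    def ensemble(self, R: int, master_seed: int) -> Ensemble:
        sched = self.schedule() if self.config.regime == "census" else None
        return run_ensemble(self.config, R, master_seed, sched)

    def sweep(self, mu_grid, R: int, master_seed: int) -> dict[float, Ensemble]:
        """One ensemble per innovation rate on a grid (shared schedule)."""
        sched = self.schedule() if self.config.regime == "census" else None
        out = {}
        for i, mu in enumerate(mu_grid):
            model = self.with_params(mu=float(mu))
            model._schedule = sched
            out[float(mu)] = model.ensemble(R, master_seed + i)
        return out
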