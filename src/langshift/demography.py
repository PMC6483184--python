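"""Yearly demographic turnover: fixed, expanding, and census-driven regimes.

Turnover happens once per model year, after the year's interaction rounds.
Three regimes are supported:

* **fixed** — ``round(d*N)`` agents die and are replaced one-for-one, each
  replacement being an L1 birth with probability ``b / (b + r)`` and an L2
  recruit otherwise; N never changes.
* **expanding** — deaths, births and recruitments occur at per-capita rates
  ``d``, ``b``, ``r``; the growth rate is ``g = b + r - d`` (0.05 in the
  expanding study runs).
* **census** — per-year integer event counts are precomputed from a census
  table of L1/L2 speaker counts (geometric interpolation between census
  years), so that applying the schedule reproduces the (scaled) census totals
  exactly.

All newcomers are initialised from a snapshot of the population taken before
any of the year's deaths: newborns average two random distinct parents,
recruits adopt the snapshot population mean (or innovate with probability
``mu``).  Deaths are uniform over agents, independent of class, age or usage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LearningParams, Population, SpeakerClass

__all__ = [
    "RateSet",
    "CensusTable",
    "DemographicSchedule",
    "stochastic_round",
    "fixed_step",
    "expanding_step",
    "census_to_schedule",
]


@dataclass(frozen=True)
class RateSet:
    """Per-capita annual rates: births (b), recruitments (r), deaths (d)."""

    b: float = 0.0
    r: float = 0.0
    d: float = 0.0

    def __post_init__(self) -> None:
        for name in ("b", "r", "d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"rate {name} must be in [0, 1], got {v}")

    @property
    def g(self) -> float:
        """Net growth rate b + r - d."""
        return self.b + self.r - self.d


class CensusTable:
    """Census rows (year, L1 count, L2 count), years strictly increasing."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame[["year", "l1_count", "l2_count"]].copy()
        frame = frame.astype({"year": int, "l1_count": float, "l2_count": float})
        if not frame["year"].is_monotonic_increasing or frame["year"].duplicated().any():
            raise ValueError("census years must be strictly increasing")
        if (frame[["l1_count", "l2_count"]] < 0).any().any():
            raise ValueError("census counts must be non-negative")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "CensusTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out[["l1_count", "l2_count"]] = out[["l1_count", "l2_count"]].astype(int)
        out.to_csv(path, index=False)

    @property
    def years(self) -> np.ndarray:
        return self.frame["year"].to_numpy()

    def interpolate(self) -> pd.DataFrame:
        """Geometric interpolation of both class counts to every year.

        Between consecutive census rows (y0, c0) and (y1, c1) the count at
        year t is ``c0 * (c1/c0)**((t-y0)/(y1-y0))`` — constant exponential
        growth within each phase.  Zero endpoints fall back to linear
        interpolation for that phase.
        """
        rows = []
        f = self.frame
        for (y0, a0, b0), (y1, a1, b1) in zip(
            f.itertuples(index=False), f.iloc[1:].itertuples(index=False)
        ):
            for t in range(int(y0), int(y1)):
                frac = (t - y0) / (y1 - y0)
                rows.append(
                    (t, _geom_interp(a0, a1, frac), _geom_interp(b0, b1, frac))
                )
        last = f.iloc[-1]
        rows.append((int(last["year"]), last["l1_count"], last["l2_count"]))
        return pd.DataFrame(rows, columns=["year", "l1_count", "l2_count"])


def _geom_interp(c0: float, c1: float, frac: float) -> float:
    if c0 <= 0.0 or c1 <= 0.0:
        return c0 + (c1 - c0) * frac
    return c0 * (c1 / c0) ** frac


def stochastic_round(x: float | np.ndarray, rng: np.random.Generator):
    """Unbiased integer realisation: floor(x) plus Bernoulli(frac(x)).

    Keeps expected event counts exact even when per-year rates times a small
    scaled population give fractional counts.
    """
    x = np.asarray(x, dtype=float)
    lo = np.floor(x)
    out = lo + (rng.random(x.shape) < (x - lo))
    return out.astype(int) if out.ndim else int(out)


# ---------------------------------------------------------------------------
# turnover machinery shared by the regimes
# ---------------------------------------------------------------------------

def _spawn_newborns(
    snapshot_probs: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Usage rows for ``count`` newborns, each averaging two distinct parents."""
    n = len(snapshot_probs)
    if count == 0:
        return np.empty((0, snapshot_probs.shape[1]))
    if n < 2:
        # degenerate community: a single possible parent models itself twice
        return np.repeat(snapshot_probs.mean(axis=0, keepdims=True), count, axis=0)
    pa = rng.integers(0, n, size=count)
    pb = rng.integers(0, n, size=count)
    clash = pa == pb
    while np.any(clash):  # resample collisions so parents are distinct
        pb[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = pa == pb
    return 0.5 * (snapshot_probs[pa] + snapshot_probs[pb])


def _spawn_recruits(
    snapshot_mean: np.ndarray,
    count: int,
    params: LearningParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Usage rows for ``count`` L2 recruits; returns (rows, n_innovations)."""
    rows = np.tile(snapshot_mean, (count, 1))
    innovate = rng.random(count) < params.mu
    if np.any(innovate):
        rows[innovate] = 0.0
        rows[innovate, params.novel_index - 1] = 1.0
    return rows, int(innovate.sum())


def _apply_turnover(
    pop: Population,
    death_idx: np.ndarray,
    n_births: int,
    n_recruits: int,
    params: LearningParams,
    rng: np.random.Generator,
) -> Population:
    """Remove the dead, append newcomers initialised from the pre-death snapshot."""
    snapshot_probs = pop.probs  # all deaths/newcomers use the same snapshot
    snapshot_mean = pop.mean_usage()
    born = _spawn_newborns(snapshot_probs, n_births, rng)
    recruited, innovations = _spawn_recruits(snapshot_mean, n_recruits, params, rng)

    keep = np.ones(pop.size, dtype=bool)
    keep[death_idx] = False
    if not np.any(keep) and n_births + n_recruits == 0:
        raise RuntimeError("demographic schedule would empty the population")

    pop.probs = np.concatenate([pop.probs[keep], born, recruited])
    pop.speaker_class = np.concatenate(
        [
            pop.speaker_class[keep],
            np.full(n_births, SpeakerClass.L1.value, dtype=np.int8),
            np.full(n_recruits, SpeakerClass.L2.value, dtype=np.int8),
        ]
    )
    pop.tenure = np.concatenate(
        [pop.tenure[keep], np.zeros(n_births + n_recruits, dtype=np.int32)]
    )
    pop.innovations += innovations
    return pop


# ---------------------------------------------------------------------------
# regimes
# ---------------------------------------------------------------------------

def fixed_step(
    pop: Population,
    rates: RateSet,
    params: LearningParams,
    rng: np.random.Generator,
) -> Population:
    """Fixed-size turnover: round(d*N) deaths, replaced one-for-one.

    Each replacement is an L1 birth with probability ``b/(b+r)``, otherwise an
    L2 recruit.  N is unchanged.
    """
    n = pop.size
    n_deaths = int(np.floor(rates.d * n + 0.5))
    if n_deaths == 0:
        return pop
    if rates.b + rates.r == 0.0:
        raise ValueError("fixed regime with deaths requires b + r > 0")
    death_idx = rng.choice(n, size=n_deaths, replace=False)
    n_births = int(rng.binomial(n_deaths, rates.b / (rates.b + rates.r)))
    return _apply_turnover(pop, death_idx, n_births, n_deaths - n_births, params, rng)


def expanding_step(
    pop: Population,
    rates: RateSet,
    params: LearningParams,
    rng: np.random.Generator,
) -> Population:
    """Expanding-population turnover at per-capita rates d, b, r.

    Fractional expected counts d*N, b*N, r*N are realised by stochastic
    remainder rounding, keeping growth unbiased at small N.
    """
    n = pop.size
    n_deaths = min(stochastic_round(rates.d * n, rng), n)
    n_births = stochastic_round(rates.b * n, rng)
    n_recruits = stochastic_round(rates.r * n, rng)
    if n_deaths >= n and n_births + n_recruits == 0:
        raise RuntimeError(
            f"expanding step would empty the population (N={n}, deaths={n_deaths})"
        )
    if n_deaths == n_births == n_recruits == 0:
        return pop
    death_idx = rng.choice(n, size=n_deaths, replace=False)
    return _apply_turnover(pop, death_idx, n_births, n_recruits, params, rng)


# ---------------------------------------------------------------------------
# census-driven schedules
# ---------------------------------------------------------------------------

def _split_deaths(n_deaths: int, n_l1: float, n_l2: float) -> tuple[int, int]:
    """Deterministic class split of deaths, proportional to composition.

    Shared by schedule generation and application so that per-class census
    totals are reproduced exactly.
    """
    total = n_l1 + n_l2
    if total <= 0 or n_deaths == 0:
        return 0, 0
    d1 = int(np.floor(n_deaths * n_l1 / total + 0.5))
    d1 = min(d1, int(n_l1))
    d2 = min(n_deaths - d1, int(n_l2))
    d1 = n_deaths - d2
    return d1, d2


class DemographicSchedule:
    """Precomputed per-year integer event counts driving census-regime runs.

    Columns: ``year, deaths, births, recruits, deaths_l1, deaths_l2`` where
    ``deaths = deaths_l1 + deaths_l2``.  The per-class split is part of the
    schedule so that applying it to the initial counts reproduces the scaled
    census totals at every census year exactly.
    """

    COLUMNS = ["year", "deaths", "births", "recruits", "deaths_l1", "deaths_l2"]

    def __init__(self, frame: pd.DataFrame, scale: float = 1.0):
        if "deaths_l1" not in frame.columns:
            # plain dialect: split deaths later at application time
            frame = frame.copy()
            frame["deaths_l1"] = -1
            frame["deaths_l2"] = -1
        self.frame = frame[self.COLUMNS].astype(int).reset_index(drop=True)
        self.scale = scale

    @classmethod
    def from_csv(cls, path, scale: float = 1.0) -> "DemographicSchedule":
        return cls(pd.read_csv(path), scale=scale)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def years(self) -> np.ndarray:
        return self.frame["year"].to_numpy()

    def events_for_year(self, year: int) -> tuple[int, int, int, int, int]:
        """(deaths, deaths_l1, deaths_l2, births, recruits) for one year.

        deaths_l1/deaths_l2 are -1 for plain-dialect schedules, meaning the
        split is derived from composition at application time.
        """
        row = self.frame.loc[self.frame["year"] == year]
        if row.empty:
            raise KeyError(f"year {year} not covered by the schedule")
        r = row.iloc[0]
        return (
            int(r["deaths"]),
            int(r["deaths_l1"]),
            int(r["deaths_l2"]),
            int(r["births"]),
            int(r["recruits"]),
        )

    def apply_counts(self, n_l1: int, n_l2: int) -> pd.DataFrame:
        """Bookkeeping check: per-class counts after each scheduled year."""
        rows = []
        for r in self.frame.itertuples(index=False):
            d1, d2 = r.deaths_l1, r.deaths_l2
            if d1 < 0:
                d1, d2 = _split_deaths(r.deaths, n_l1, n_l2)
            n_l1 = n_l1 - d1 + r.births
            n_l2 = n_l2 - d2 + r.recruits
            rows.append((r.year + 1, n_l1, n_l2))
        return pd.DataFrame(rows, columns=["year", "l1_count", "l2_count"])

    def census_step(
        self,
        pop: Population,
        params: LearningParams,
        rng: np.random.Generator,
    ) -> Population:
        """Apply this schedule's events for ``pop.year`` (deaths uniform within class)."""
        deaths, d1, d2, births, recruits = self.events_for_year(pop.year)
        if d1 < 0:
            d1, d2 = _split_deaths(deaths, pop.n_l1, pop.n_l2)
        l1_idx = np.flatnonzero(pop.speaker_class == SpeakerClass.L1.value)
        l2_idx = np.flatnonzero(pop.speaker_class == SpeakerClass.L2.value)
        death_idx = np.concatenate(
            [
                rng.choice(l1_idx, size=min(d1, len(l1_idx)), replace=False),
                rng.choice(l2_idx, size=min(d2, len(l2_idx)), replace=False),
            ]
        )
        return _apply_turnover(pop, death_idx, births, recruits, params, rng)


def census_to_schedule(
    census: CensusTable,
    mortality: float = 0.02,
    scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> DemographicSchedule:
    """Turn a census table into per-year integer event counts.

    L1 and L2 totals are interpolated geometrically between census years,
    divided by ``scale`` and rounded (stochastic remainder, except census-year
    anchor totals which round deterministically so scale=1 is exact).  Each
    year's deaths are ``mortality * N`` (stochastically rounded), split across
    classes by current composition; births and recruits are whatever net
    change plus death replacement is needed to hit the next year's target.
    Negative implied births/recruits are clamped to zero with compensating
    extra deaths in that class.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if rng is None:
        rng = np.random.default_rng()
    interp = census.interpolate()
    census_years = set(int(y) for y in census.years)
    targets = []
    for r in interp.itertuples(index=False):
        a, b = r.l1_count / scale, r.l2_count / scale
        if r.year in census_years:
            ta, tb = int(np.floor(a + 0.5)), int(np.floor(b + 0.5))
        else:
            ta, tb = stochastic_round(a, rng), stochastic_round(b, rng)
        targets.append((int(r.year), ta, tb))
    if targets[0][1] + targets[0][2] < 1:
        raise ValueError("scaled initial population is empty; lower the scale")

    rows = []
    n_l1, n_l2 = targets[0][1], targets[0][2]
    for (year, _, _), (_, next_l1, next_l2) in zip(targets, targets[1:]):
        n_deaths = stochastic_round(mortality * (n_l1 + n_l2), rng)
        d1, d2 = _split_deaths(n_deaths, n_l1, n_l2)
        births = next_l1 - n_l1 + d1
        recruits = next_l2 - n_l2 + d2
        if births < 0:  # shrinking faster than mortality: extra deaths instead
            d1 -= births
            births = 0
        if recruits < 0:
            d2 -= recruits
            recruits = 0
        rows.append((year, d1 + d2, births, recruits, d1, d2))
        n_l1, n_l2 = next_l1, next_l2
    frame = pd.DataFrame(rows, columns=DemographicSchedule.COLUMNS)
    return DemographicSchedule(frame, scale=scale)
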