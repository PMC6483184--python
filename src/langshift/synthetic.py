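"""Synthetic fixtures: speaker-count corpora and census tables.

The corpus generator inverts the inference model: per speaker a usage
probability q_i ~ Beta(mean*c, (1-mean)*c) with concentration c = alpha+beta,
then novel_i ~ Binomial(tokens_i, q_i).  The census generator produces
phase-wise geometric growth tables, including a canned table equal to the
Maputo census (L1/L2 Portuguese speakers, 1975-2007).

``reference_corpus`` provides *synthetic* stand-ins for the two Maputo
recording corpora (third-person-plural verb agreement, destination
prepositions; 1993 and 2007): beta-binomial tables calibrated so the pooled
novel-variant proportions equal the published sample means exactly
(verbs 10.6% / 20%, prepositions 16.9% / 25.7%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import CensusTable
from .inference import SpeakerCounts

__all__ = [
    "CorpusSpec",
    "YearSpec",
    "generate_speaker_counts",
    "generate_census",
    "maputo_census",
    "reference_corpus",
    "REFERENCE_SAMPLE_MEANS",
]

#: published pooled sample means of novel-variant usage in the Maputo corpora
REFERENCE_SAMPLE_MEANS = {
    "verbs": {1993: 0.106, 2007: 0.20},
    "prepositions": {1993: 0.169, 2007: 0.257},
}


@dataclass(frozen=True)
class YearSpec:
    """One year of a corpus: speakers, tokens per speaker, target mean, concentration.

    ``tokens`` is either a fixed count or an inclusive (lo, hi) range sampled
    uniformly per speaker (uneven interview yields).
    """

    year: int
    n_speakers: int
    tokens: int | tuple[int, int] = (5, 40)
    mean: float = 0.1
    concentration: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValueError("target mean must be in [0, 1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.n_speakers < 1:
            raise ValueError("need at least one speaker")


@dataclass(frozen=True)
class CorpusSpec:
    """A multi-year corpus specification (one YearSpec per recording year)."""

    years: tuple[YearSpec, ...]

    @classmethod
    def single(cls, **kwargs) -> "CorpusSpec":
        return cls((YearSpec(**kwargs),))


def _sample_tokens(spec: YearSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.tokens, tuple):
        lo, hi = spec.tokens
        return rng.integers(lo, hi + 1, size=spec.n_speakers)
    return np.full(spec.n_speakers, int(spec.tokens))


def generate_speaker_counts(
    spec: CorpusSpec | YearSpec, seed: int | None = None
) -> SpeakerCounts:
    """Beta-binomial speaker counts for each year of the spec (seeded).

    Degenerate target means 0 and 1 short-circuit to all-zero / saturated
    counts (the beta distribution is degenerate there).
    """
    if isinstance(spec, YearSpec):
        spec = CorpusSpec((spec,))
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for ys in spec.years:
        tokens = _sample_tokens(ys, rng)
        if ys.mean in (0.0, 1.0):
            q = np.full(ys.n_speakers, ys.mean)
        else:
            q = rng.beta(
                ys.mean * ys.concentration,
                (1.0 - ys.mean) * ys.concentration,
                size=ys.n_speakers,
            )
        novel = rng.binomial(tokens, q)
        for t, x in zip(tokens, novel):
            rows.append((f"s{sid:04d}", ys.year, int(t), int(x)))
            sid += 1
    return SpeakerCounts(
        pd.DataFrame(rows, columns=SpeakerCounts.COLUMNS)
    )


def _calibrate_to_total(novel: np.ndarray, tokens: np.ndarray, target: int
                        ) -> np.ndarray:
    """Nudge per-speaker novel counts so their sum hits ``target`` exactly.

    Adds/removes single tokens round-robin, respecting 0 <= novel <= tokens;
    keeps the generated heterogeneity otherwise intact.
    """
    novel = novel.copy()
    diff = target - int(novel.sum())
    order = np.argsort(-tokens)  # adjust the largest interviews first
    i = 0
    while diff != 0:
        j = order[i % len(order)]
        if diff > 0 and novel[j] < tokens[j]:
            novel[j] += 1
            diff -= 1
        elif diff < 0 and novel[j] > 0:
            novel[j] -= 1
            diff += 1
        i += 1
    return novel


def reference_corpus(feature: str, seed: int = 2007) -> SpeakerCounts:
    """Synthetic stand-in for one of the two Maputo recording corpora.

    The real speaker-level counts are not redistributable, so this builds a
    beta-binomial table (moderate heterogeneity, uneven interview yields)
    whose pooled novel-variant proportion per recording year equals the
    published sample mean *exactly* — 1000 tokens per year, e.g. 169/1000 for
    prepositions in 1993.  Suitable wherever the published sample means are
    the quantity of interest; it does not reproduce the real corpora's
    speaker-level structure.
    """
    if feature not in REFERENCE_SAMPLE_MEANS:
        raise KeyError(f"feature must be one of {sorted(REFERENCE_SAMPLE_MEANS)}")
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for year, mean in REFERENCE_SAMPLE_MEANS[feature].items():
        n_speakers, total = 40, 1000
        tokens = rng.integers(5, 46, size=n_speakers)
        tokens[-1] += total - tokens.sum()  # exact total token count
        if tokens[-1] < 1:
            tokens = np.full(n_speakers, total // n_speakers)
        q = rng.beta(mean * 10, (1 - mean) * 10, size=n_speakers)
        novel = rng.binomial(tokens, q)
        novel = _calibrate_to_total(novel, tokens, round(mean * total))
        for t, x in zip(tokens, novel):
            rows.append((f"{feature[:4]}{sid:03d}", year, int(t), int(x)))
            sid += 1
    return SpeakerCounts(pd.DataFrame(rows, columns=SpeakerCounts.COLUMNS))


# ---------------------------------------------------------------------------
# census tables
# ---------------------------------------------------------------------------

def generate_census(
    start_counts: tuple[float, float],
    phases: list[tuple[int, float, float]],
    start_year: int = 0,
) -> CensusTable:
    """Census table from a start point and per-phase growth multipliers.

    ``phases`` is a list of (duration_years, l1_multiplier, l2_multiplier);
    each phase ends at start*multiplier, reached by geometric growth.  Only
    phase endpoints appear as census rows (interpolation is the schedule
    builder's job).
    """
    l1, l2 = float(start_counts[0]), float(start_counts[1])
    year = start_year
    rows = [(year, l1, l2)]
    for duration, m1, m2 in phases:
        if duration < 1:
            raise ValueError("phase duration must be >= 1 year")
        l1, l2 = l1 * m1, l2 * m2
        year += duration
        rows.append((year, l1, l2))
    frame = pd.DataFrame(rows, columns=["year", "l1_count", "l2_count"])
    return CensusTable(frame)


def maputo_census() -> CensusTable:
    """The Maputo census of L1/L2 Portuguese speakers, 1975-2007.

    1975 is the year of independence, taken as the all-conservative starting
    condition; the 1975 L1 figure is the published estimate accounting for
    settler emigration.
    """
    frame = pd.DataFrame(
        {
            "year": [1975, 1980, 1997, 2007],
            "l1_count": [100, 6_525, 241_709, 470_690],
            "l2_count": [20_000, 326_521, 599_438, 612_992],
        }
    )
    return CensusTable(frame)
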