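"""Interaction kernel: agent usage distributions and the pairwise learning update.

Each speaker i carries a usage distribution ``p_i = (p_i1, ..., p_in)`` over the
n variants of one linguistic feature; ``p_ik`` is the probability of uttering
variant k in an encounter.  Variant 1 is the conservative (pre-contact) form;
the designated novel variant defaults to index 2.  In one interaction round
every agent is paired with exactly one partner (uniformly random perfect
matching), both utter a variant from their *pre-round* distributions, and both
shift probability mass toward what they heard:

    p_ik' = p_ik + (1 - p_ik) * l   if the partner uttered k
    p_ik' = p_ik - p_ik * l         otherwise

with learning weight ``0 <= l <= 1``.  The update is neutral: the expected
change in the population mean usage of every variant is exactly zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "SpeakerClass",
    "LearningParams",
    "Population",
    "validate_distribution",
    "utter",
    "apply_update",
    "interaction_round",
    "population_mean",
    "init_newborn",
    "init_recruit",
    "mutate_to_novel",
    "expected_round_change",
]

logger = logging.getLogger(__name__)

#: distributions must sum to 1 within this tolerance
SUM_TOL = 1e-12
#: accumulated drift beyond this triggers renormalisation (with a warning)
RENORM_TOL = 1e-9


class SpeakerClass(Enum):
    """Native (L1) versus second-language (L2) speaker."""

    L1 = 1
    L2 = 2


@dataclass(frozen=True)
class LearningParams:
    """Parameters of the interaction/innovation kernel.

    Parameters
    ----------
    l : float
        Learning weight in [0, 1]; the size of the per-encounter shift toward
        the heard variant.
    mu : float
        Innovation probability in [0, 1]: the chance that an L2 speaker, at an
        innovation opportunity, adopts the pure novel-variant distribution.
    novel_index : int
        1-based index of the novel variant (must not be 1, the conservative
        form).  Default 2.
    """

    l: float = 0.05
    mu: float = 0.0
    novel_index: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.l <= 1.0:
            raise ValueError(f"learning weight l must be in [0, 1], got {self.l}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"innovation rate mu must be in [0, 1], got {self.mu}")
        if self.novel_index == 1:
            raise ValueError("novel_index must differ from the conservative index 1")
        if self.novel_index < 1:
            raise ValueError("novel_index is 1-based and must be >= 2")


def validate_distribution(probs: np.ndarray, name: str = "usage") -> np.ndarray:
    """Validate a usage distribution (1-D) or a stack of them (2-D).

    Entries must lie in [0, 1] and each row must sum to 1 within ``SUM_TOL``
    relative to accumulated float error; rows are renormalised (with a
    warning) only if the drift exceeds ``RENORM_TOL``.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim not in (1, 2) or probs.shape[-1] < 2:
        raise ValueError(f"{name} must have >= 2 variants, got shape {probs.shape}")
    if np.any(probs < -SUM_TOL) or np.any(probs > 1 + SUM_TOL):
        raise ValueError(f"{name} has entries outside [0, 1]")
    sums = probs.sum(axis=-1)
    drift = np.abs(sums - 1.0)
    if np.any(drift > 1e-6):
        raise ValueError(f"{name} does not sum to 1 (max drift {drift.max():.3g})")
    if np.any(drift > RENORM_TOL):
        # moderate accumulated float drift: repair, but make it visible
        logger.warning(
            "%s drifted from unit sum by up to %.3g; renormalising", name, drift.max()
        )
        probs = probs / sums[..., None]
    return probs


@dataclass
class Population:
    """A speech community as parallel arrays over agents.

    Attributes
    ----------
    probs : (N, n) float array
        Row i is agent i's usage distribution.
    speaker_class : (N,) int array
        ``SpeakerClass`` values (1 = L1, 2 = L2).
    tenure : (N,) int array
        Years since the agent entered the population (0 in the entry year;
        incremented by 1 at each year boundary).  Meaningful for L2 speakers
        under the multi-year SLA model.
    year : int
        Current model (or calendar) year.
    innovations : int
        Cumulative count of innovation events (entry-time and SLA mutations).
    """

    probs: np.ndarray
    speaker_class: np.ndarray
    tenure: np.ndarray
    year: int = 0
    innovations: int = 0

    def __post_init__(self) -> None:
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        self.speaker_class = np.asarray(self.speaker_class, dtype=np.int8)
        self.tenure = np.asarray(self.tenure, dtype=np.int32)
        if not (len(self.probs) == len(self.speaker_class) == len(self.tenure)):
            raise ValueError("probs, speaker_class and tenure must have equal length")

    # -- constructors ------------------------------------------------------
    @classmethod
    def conservative(
        cls,
        n_l1: int,
        n_l2: int = 0,
        n_variants: int = 2,
        l2_tenure: int = 0,
        year: int = 0,
    ) -> "Population":
        """All-conservative starting population (every agent has p_1 = 1)."""
        n = n_l1 + n_l2
        if n < 1:
            raise ValueError("population must contain at least one agent")
        probs = np.zeros((n, n_variants))
        probs[:, 0] = 1.0
        cls_arr = np.concatenate(
            [
                np.full(n_l1, SpeakerClass.L1.value, dtype=np.int8),
                np.full(n_l2, SpeakerClass.L2.value, dtype=np.int8),
            ]
        )
        tenure = np.concatenate(
            [np.zeros(n_l1, dtype=np.int32), np.full(n_l2, l2_tenure, dtype=np.int32)]
        )
        return cls(probs, cls_arr, tenure, year=year)

    # -- views -------------------------------------------------------------
    @property
    def size(self) -> int:
        return len(self.probs)

    @property
    def n_variants(self) -> int:
        return self.probs.shape[1]

    @property
    def n_l1(self) -> int:
        return int(np.sum(self.speaker_class == SpeakerClass.L1.value))

    @property
    def n_l2(self) -> int:
        return int(np.sum(self.speaker_class == SpeakerClass.L2.value))

    def mean_usage(self) -> np.ndarray:
        return population_mean(self)

    def revalidate(self) -> None:
        """Renormalise rows whose sum drifted beyond ``RENORM_TOL`` (warns)."""
        sums = self.probs.sum(axis=1)
        drift = np.abs(sums - 1.0)
        if np.any(drift > RENORM_TOL):
            logger.warning("renormalising %d agents (max drift %.3g)",
                           int(np.sum(drift > RENORM_TOL)), drift.max())
            self.probs /= sums[:, None]

    def copy(self) -> "Population":
        return Population(
            self.probs.copy(), self.speaker_class.copy(), self.tenure.copy(),
            year=self.year, innovations=self.innovations,
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def utter(usage: np.ndarray, rng: np.random.Generator) -> int:
    """Sample a variant index (1-based) from one usage distribution.

    Consumes exactly one uniform draw, so parallel streams stay aligned.
    """
    usage = validate_distribution(usage)
    u = rng.random()
    return int(np.searchsorted(np.cumsum(usage), u, side="right")) + 1


def apply_update(usage: np.ndarray, heard: int, l: float) -> np.ndarray:
    """Shift a usage distribution toward the heard variant by weight ``l``.

    Implements the pair of update rules: the heard variant k gains
    ``(1 - p_k) * l`` while every other variant j loses ``p_j * l``.  The two
    rules together are ``p' = (1 - l) p + l e_k``, a convex combination, so
    the unit sum is conserved algebraically.
    """
    if not 0.0 <= l <= 1.0:
        raise ValueError(f"learning weight l must be in [0, 1], got {l}")
    usage = validate_distribution(usage)
    if not 1 <= heard <= usage.shape[-1]:
        raise ValueError(f"heard variant {heard} out of range 1..{usage.shape[-1]}")
    out = usage * (1.0 - l)
    out[heard - 1] += l
    return out


def population_mean(pop: Population) -> np.ndarray:
    """Population mean usage, the element-wise mean of agent distributions."""
    if pop.size < 1:
        raise ValueError("population mean of an empty population is undefined")
    return pop.probs.mean(axis=0)


def _sample_utterances(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised variant sampling: one draw per row, 0-based indices out."""
    u = rng.random(len(probs))
    if probs.shape[1] == 2:  # hot path; all study runs use two variants
        return (u >= probs[:, 0]).astype(np.intp)
    cum = np.cumsum(probs, axis=1)
    return (u[:, None] >= cum).sum(axis=1).clip(max=probs.shape[1] - 1)


def interaction_round(
    pop: Population, params: LearningParams, rng: np.random.Generator
) -> Population:
    """One round: random perfect matching, simultaneous utter-and-update.

    Agents are paired by a uniformly random perfect matching (one uniformly
    chosen agent sits idle when N is odd).  Both partners utter from their
    pre-round distributions; both then update toward what they heard.  The
    population is modified in place and returned.
    """
    n = pop.size
    if n < 2:
        raise ValueError("an interaction round needs at least 2 agents")
    perm = rng.permutation(n)
    paired = perm[: n - (n % 2)]  # odd N: perm[-1] idle, uniform by symmetry
    utt = _sample_utterances(pop.probs[paired], rng)
    heard = np.empty_like(utt)
    heard[0::2] = utt[1::2]
    heard[1::2] = utt[0::2]
    pop.probs[paired] *= 1.0 - params.l
    pop.probs[paired, heard] += params.l
    return pop


# ---------------------------------------------------------------------------
# entry rules for newcomers
# ---------------------------------------------------------------------------

def init_newborn(parent_a: np.ndarray, parent_b: np.ndarray) -> np.ndarray:
    """Usage of a newborn L1 speaker: the average of its two parents.

    Newborns acquire the language from a small number of models — here the
    element-wise mean of two distinct, uniformly sampled parents.
    """
    pa = validate_distribution(parent_a, "parent_a")
    pb = validate_distribution(parent_b, "parent_b")
    return 0.5 * (pa + pb)


def init_recruit(
    pop_mean: np.ndarray, params: LearningParams, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Usage of a recruited L2 speaker, with entry-time innovation.

    With probability ``1 - mu`` the recruit averages the entire population
    (adopts the snapshot mean); with probability ``mu`` it instead enters with
    the pure novel-variant distribution.  Returns ``(usage, innovated)``.
    """
    pop_mean = validate_distribution(pop_mean, "population mean")
    if rng.random() < params.mu:
        out = np.zeros_like(pop_mean)
        out[params.novel_index - 1] = 1.0
        return out, True
    return pop_mean.copy(), False


def mutate_to_novel(usage: np.ndarray, novel_index: int) -> np.ndarray:
    """Replace a usage distribution by the indicator on the novel variant."""
    usage = validate_distribution(usage)
    out = np.zeros_like(usage)
    out[novel_index - 1] = 1.0
    return out


# ---------------------------------------------------------------------------
# exact neutrality enumeration
# ---------------------------------------------------------------------------

def _perfect_matchings(indices: tuple[int, ...]) -> list[list[tuple[int, int]]]:
    """All perfect matchings of an even-sized index set (recursive)."""
    if not indices:
        return [[]]
    first, rest = indices[0], indices[1:]
    out = []
    for j, partner in enumerate(rest):
        remaining = rest[:j] + rest[j + 1 :]
        for sub in _perfect_matchings(remaining):
            out.append([(first, partner)] + sub)
    return out


def expected_round_change(probs: np.ndarray, l: float) -> np.ndarray:
    """Exact expected change in population mean usage over one round.

    Enumerates every perfect matching (uniform weight) and every joint
    utterance outcome (weighted by the product of the agents' usage
    probabilities), applies the learning update, and sums.  The interaction
    dynamics are neutral — no variant is favoured — so the result is the zero
    vector up to floating-point error.  Feasible for small even N (the number
    of terms is (N-1)!! * n^N).
    """
    probs = np.atleast_2d(validate_distribution(probs))
    n_agents, n_var = probs.shape
    if n_agents % 2 or n_agents < 2:
        raise ValueError("exact enumeration requires an even number of agents >= 2")
    matchings = _perfect_matchings(tuple(range(n_agents)))
    pre_mean = probs.mean(axis=0)
    expected_post = np.zeros(n_var)
    w_match = 1.0 / len(matchings)
    for matching in matchings:
        for outcome in itertools.product(range(n_var), repeat=n_agents):
            w = w_match
            for i in range(n_agents):
                w *= probs[i, outcome[i]]
            if w == 0.0:
                continue
            post = probs.copy()
            for i, j in matching:
                post[i] = apply_update(probs[i], outcome[j] + 1, l)
                post[j] = apply_update(probs[j], outcome[i] + 1, l)
            expected_post += w * post.mean(axis=0)
    return expected_post - pre_mean
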