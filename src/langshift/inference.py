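"""Model-data comparison: beta-binomial MLE and ensemble-based fit statistics.

Observed usage data come as per-speaker token counts: speaker i produced
``x_i`` novel-variant tokens out of ``n_i`` occurrences of the variable
context.  Counts are modelled as binomial within speaker with a per-speaker
usage probability drawn from a Beta(alpha, beta) across speakers; the beta
mean ``alpha / (alpha + beta)`` is the population mean frequency of usage.
``BetaBinomialModel(...).fit()`` maximises the marginal (beta-binomial)
likelihood and bootstraps a 95% CI for the mean over speakers.

Simulated predictions come as replicate-run ensembles.  Per data year a
normal is fitted to the replicate values (mean m_y, sd s_y); the 95%
predictive interval is ``m_y ± 1.96 s_y``.  A parameter setting *fits* the
data if its interval contains the MLE point in every data year; among
candidate settings the one with minimum mean squared distance from the MLE
points is selected; and the joint probability of values at least as extreme
as the MLEs is the product over years of the per-year tail mass (years are
treated as independent given the model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, digamma, gammaln, ndtr

__all__ = [
    "SpeakerCounts",
    "BetaBinomialModel",
    "BetaBinomialResults",
    "EnsembleNormalFit",
    "betabinom_loglik",
    "fit_betabinom_mle",
    "ensemble_interval",
    "overlap_fit_check",
    "select_min_mse",
    "joint_tail_probability",
]


class SpeakerCounts:
    """Per-speaker token counts: columns speaker_id, year, tokens, novel."""

    COLUMNS = ["speaker_id", "year", "tokens", "novel"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"speaker counts missing columns {sorted(missing)}")
        frame = frame[self.COLUMNS].copy()
        frame[["tokens", "novel"]] = frame[["tokens", "novel"]].astype(int)
        bad = frame.index[(frame["novel"] < 0) | (frame["novel"] > frame["tokens"])
                          | (frame["tokens"] < 1)]
        if len(bad):
            raise ValueError(
                f"rows {list(bad)[:5]} violate 0 <= novel <= tokens, tokens >= 1"
            )
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "SpeakerCounts":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def for_year(self, year: int) -> "SpeakerCounts":
        sub = self.frame.loc[self.frame["year"] == year]
        if sub.empty:
            raise KeyError(f"no speakers recorded for year {year}")
        return SpeakerCounts(sub)

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique().tolist())

    def pooled_proportion(self) -> float:
        """Pooled sample mean: total novel tokens over total tokens."""
        return float(self.frame["novel"].sum() / self.frame["tokens"].sum())

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.frame["tokens"].to_numpy(float),
                self.frame["novel"].to_numpy(float))


def betabinom_loglik(counts: SpeakerCounts, alpha: float, beta: float) -> float:
    """Beta-binomial log-likelihood of the speaker counts.

    Sum over speakers of ``log [ C(n_i, x_i) B(x_i + a, n_i - x_i + b) / B(a, b) ]``
    via log-gamma for numerical stability.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("beta shape parameters must be positive")
    n, x = counts.arrays()
    return float(np.sum(_loglik_terms(n, x, alpha, beta)))


def _loglik_terms(n, x, alpha, beta):
    comb = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    return comb + betaln(x + alpha, n - x + beta) - betaln(alpha, beta)


def _neg_loglik_grad(theta: np.ndarray, n: np.ndarray, x: np.ndarray):
    """Negative log-likelihood and its gradient in theta = (log a, log b).

    d betaln(p, q) / dp = psi(p) - psi(p + q), so the score in the shape
    parameters is a sum of digamma terms; the log reparameterisation keeps
    the optimisation unconstrained.
    """
    a, b = np.exp(theta)
    ll = np.sum(_loglik_terms(n, x, a, b))
    k = len(n)
    psi_nab = digamma(n + a + b)
    da = np.sum(digamma(x + a) - psi_nab) - k * (digamma(a) - digamma(a + b))
    db = np.sum(digamma(n - x + b) - psi_nab) - k * (digamma(b) - digamma(a + b))
    return -float(ll), -np.array([da * a, db * b])


def _mle_point(
    n: np.ndarray, x: np.ndarray, start: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """Multi-start simplex MLE on log-shape parameters -> (a, b, loglik).

    ``start`` (alpha, beta) replaces the multi-start sweep with a single warm
    start — used by bootstrap refits, which stay near the full-data optimum.
    """
    if start is not None:
        thetas = [np.log(start)]
    else:
        pooled = x.sum() / n.sum()
        pooled = min(max(pooled, 1e-3), 1 - 1e-3)
        thetas = [
            np.log([m0 * c0, (1 - m0) * c0])
            for m0, c0 in [(pooled, 10.0), (pooled, 2.0), (pooled, 50.0), (0.5, 2.0)]
        ]
    best = None
    for theta0 in thetas:
        res = minimize(
            _neg_loglik_grad, theta0, args=(n, x), method="L-BFGS-B", jac=True,
            bounds=[(-20.0, 20.0)] * 2,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    return float(a), float(b), -float(best.fun)


@dataclass
class BetaBinomialResults:
    """MLE of the beta-binomial usage model.

    Attributes
    ----------
    alpha, beta : float
        Fitted shape parameters (NaN for boundary fits).
    mean : float
        Estimated population mean usage alpha / (alpha + beta); exactly 0 or 1
        for boundary data (all counts zero or all saturated).
    ci_lo, ci_hi : float
        95% percentile bootstrap interval over speakers.
    loglik : float
        Log-likelihood at the optimum.
    boundary : bool
        True when the data sit on the boundary and no interior fit exists.
    n_speakers : int
    """

    alpha: float
    beta: float
    mean: float
    ci_lo: float
    ci_hi: float
    loglik: float
    boundary: bool
    n_speakers: int

    @property
    def concentration(self) -> float:
        return self.alpha + self.beta

    def summary(self) -> str:
        lines = [
            "Beta-binomial usage model (MLE)",
            "=" * 39,
            f"speakers            {self.n_speakers:>12d}",
            f"alpha               {self.alpha:>12.4f}",
            f"beta                {self.beta:>12.4f}",
            f"mean usage          {self.mean:>12.4f}",
            f"95% CI (bootstrap)  [{self.ci_lo:.4f}, {self.ci_hi:.4f}]",
            f"log-likelihood      {self.loglik:>12.4f}",
        ]
        if self.boundary:
            lines.append("NOTE: boundary fit (all counts at 0 or saturation)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "beta": self.beta, "mean": self.mean,
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi, "loglik": self.loglik,
            "boundary": self.boundary, "n_speakers": self.n_speakers,
        }


class BetaBinomialModel:
    """Beta-binomial model of overdispersed per-speaker usage counts.

    Parameters
    ----------
    counts : SpeakerCounts or DataFrame
        Speaker-level counts (one year's worth; use ``SpeakerCounts.for_year``
        to slice a multi-year table).

    Examples
    --------
    >>> model = BetaBinomialModel.from_dataframe(df)
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(self, counts: SpeakerCounts | pd.DataFrame):
        if isinstance(counts, pd.DataFrame):
            counts = SpeakerCounts(counts)
        if len(counts.frame) < 2:
            raise ValueError("need at least 2 speakers to fit")
        self.counts = counts

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "BetaBinomialModel":
        return cls(SpeakerCounts(frame))

    @classmethod
    def from_csv(cls, path) -> "BetaBinomialModel":
        return cls(SpeakerCounts.from_csv(path))

    def loglik(self, alpha: float, beta: float) -> float:
        return betabinom_loglik(self.counts, alpha, beta)

    def fit(self, bootstrap_reps: int = 500, seed: int | None = None
            ) -> BetaBinomialResults:
        """Maximise the likelihood; bootstrap speakers for a 95% mean CI."""
        n, x = self.counts.arrays()
        if x.sum() == 0 or (n - x).sum() == 0:
            m = 0.0 if x.sum() == 0 else 1.0
            return BetaBinomialResults(
                alpha=np.nan, beta=np.nan, mean=m, ci_lo=m, ci_hi=m,
                loglik=0.0, boundary=True, n_speakers=len(n),
            )
        a, b, ll = _mle_point(n, x)
        mean = a / (a + b)
        lo = hi = mean
        if bootstrap_reps > 0:
            rng = np.random.default_rng(seed)
            means = np.empty(bootstrap_reps)
            ns = len(n)
            for r in range(bootstrap_reps):
                idx = rng.integers(0, ns, size=ns)
                nb, xb = n[idx], x[idx]
                if xb.sum() == 0:
                    means[r] = 0.0
                elif (nb - xb).sum() == 0:
                    means[r] = 1.0
                else:
                    ab, bb, _ = _mle_point(nb, xb, start=(a, b))
                    means[r] = ab / (ab + bb)
            lo, hi = np.percentile(means, [2.5, 97.5])
        return BetaBinomialResults(
            alpha=a, beta=b, mean=float(mean), ci_lo=float(min(lo, mean)),
            ci_hi=float(max(hi, mean)), loglik=ll, boundary=False,
            n_speakers=len(n),
        )


def fit_betabinom_mle(
    counts: SpeakerCounts, bootstrap_reps: int = 500,
    seed: int | None = None,
) -> BetaBinomialResults:
    """Functional wrapper around ``BetaBinomialModel(...).fit()``."""
    return BetaBinomialModel(counts).fit(bootstrap_reps=bootstrap_reps, seed=seed)


# ---------------------------------------------------------------------------
# ensemble statistics
# ---------------------------------------------------------------------------

def ensemble_interval(values: Iterable[float]) -> tuple[float, float, float]:
    """(mean, lo, hi) with lo/hi = mean ∓ 1.96 × sd of the replicate values.

    The interval describes the spread of runs (a predictive band), not the
    standard error of their mean.
    """
    v = np.asarray(list(values), dtype=float)
    if len(v) < 2:
        raise ValueError("ensemble interval needs at least 2 replicate values")
    m, s = v.mean(), v.std(ddof=1)
    return float(m), float(m - 1.96 * s), float(m + 1.96 * s)


@dataclass(frozen=True)
class EnsembleNormalFit:
    """Per-year normal fit to replicate values: year -> (m_y, s_y)."""

    moments: Mapping[int, tuple[float, float]]

    @classmethod
    def from_ensemble(cls, ensemble, years: Iterable[int]) -> "EnsembleNormalFit":
        """Fit normals to an engine Ensemble's replicate values at data years."""
        moments = {}
        for y in years:
            v = ensemble.values_at(int(y))
            if len(v) < 2:
                raise ValueError("normal fit needs >= 2 replicates")
            moments[int(y)] = (float(v.mean()), float(v.std(ddof=1)))
        return cls(moments)

    @property
    def years(self) -> list[int]:
        return sorted(self.moments)

    def interval(self, year: int) -> tuple[float, float]:
        m, s = self.moments[year]
        return m - 1.96 * s, m + 1.96 * s


def overlap_fit_check(
    fit: EnsembleNormalFit, mle_points: Mapping[int, float]
) -> bool:
    """True iff the MLE point lies inside the 95% band for *every* data year."""
    for year, mle in mle_points.items():
        if int(year) not in fit.moments:
            raise KeyError(f"ensemble fit does not cover data year {year}")
        lo, hi = fit.interval(int(year))
        if not (lo <= mle <= hi):
            return False
    return True


def select_min_mse(
    candidates: Mapping, mle_points: Mapping[int, float]
):
    """Setting whose per-year means have minimal MSE against the MLE points.

    ``candidates`` maps a parameter setting (e.g. mu) to an EnsembleNormalFit
    or an engine Ensemble.  Ties break toward the smaller key.
    """
    if not candidates:
        raise ValueError("no candidate settings supplied")
    years = sorted(int(y) for y in mle_points)
    best_key, best_mse = None, np.inf
    for key in sorted(candidates):
        fit = candidates[key]
        if not isinstance(fit, EnsembleNormalFit):
            fit = EnsembleNormalFit.from_ensemble(fit, years)
        mse = float(
            np.mean([(fit.moments[y][0] - mle_points[y]) ** 2 for y in years])
        )
        if mse < best_mse - 1e-15:
            best_key, best_mse = key, mse
    return best_key, best_mse


def joint_tail_probability(
    fit: EnsembleNormalFit,
    mle_points: Mapping[int, float],
    tails: str = "two",
) -> float:
    """Probability of simulated values at least as extreme as the MLE points.

    Per year, ``z_y = (MLE_y - m_y) / s_y``; the two-sided tail mass is
    ``2 min(Phi(z_y), 1 - Phi(z_y))`` (one-sided drops the factor 2).  Years
    are independent given the model, so the joint probability is the product.
    """
    if tails not in ("two", "one"):
        raise ValueError("tails must be 'two' or 'one'")
    prob = 1.0
    for year, mle in mle_points.items():
        m, s = fit.moments[int(year)]
        if not s > 0:
            raise ValueError(f"degenerate ensemble spread at year {year} (s={s})")
        z = (mle - m) / s
        tail = min(ndtr(z), 1.0 - ndtr(z))
        prob *= min(2.0 * tail, 1.0) if tails == "two" else tail
    return float(prob)
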