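# Methods

## Interaction dynamics

A speech community is a set of agents, each holding a usage distribution over
the n variants of a single linguistic feature (all shipped experiments use
n = 2: conservative vs novel).  One round pairs all agents by a uniformly
random perfect matching; with an odd population one uniformly chosen agent
sits idle.  Within a pair both utterances are sampled from the *pre-round*
distributions and both agents then update simultaneously, moving a fraction
*l* of probability mass toward the heard variant (`p' = (1−l)p + l·e_k`).
This convex-combination form conserves the unit sum algebraically and makes
the dynamics neutral: conditioning on any matching, the expected post-round
mean equals the pre-round mean, because each agent's expected update pulls it
toward its partner's mean and the matching is symmetric.  The package
verifies this by exact enumeration over matchings and joint utterance
outcomes (`expected_round_change`), feasible for small even N ((N−1)!!·nᴺ
terms).

Two points are genuinely underdetermined by the verbal description of the
model and were fixed as design choices: (i) both partners update
(bidirectional learning), and (ii) updates are simultaneous, so outcomes do
not depend on within-pair order.  Both choices preserve exact neutrality.

## Demography

Turnover happens once per model year, after T = 365 rounds (configurable).
All newcomers are initialised from a snapshot taken before any of the year's
deaths (batch turnover): newborn L1 speakers average two distinct uniformly
chosen parents; L2 recruits adopt the snapshot population mean, or, with
probability μ, enter using the novel variant exclusively.  Death is uniform
over agents, blind to class, age and usage — the neutral null.  Three
regimes:

* **fixed** — round(d·N) agents die and are replaced; a replacement is an L1
  birth with probability b/(b+r).  For the fixed-population sweeps the
  turnover rate defaults to d = b + r, so the absolute birth/recruit flows
  match the expanding runs at the same b and r.
* **expanding** — deaths, births, recruitments at per-capita rates d, b, r;
  fractional expected counts are realised by stochastic remainder rounding
  (floor plus a Bernoulli on the fraction), which keeps growth unbiased at
  small N.  The study's expanding runs use b = .007, r = .063, d = .02
  (g = 0.05).
* **census** — a schedule of integer per-year events is precompiled from a
  census table of L1/L2 counts.  Counts are interpolated geometrically
  between census years (constant within-phase growth rates); per-year deaths
  are mortality·N with a deterministic proportional split across classes;
  births and recruits are whatever net change plus death replacement hits the
  next year's target.  Because the class split of deaths is deterministic and
  shared between schedule generation and application, applying the schedule
  reproduces the census totals at every census year exactly at scale 1.
  Mortality is a parameter (default 0.02/yr — a plausible crude death rate
  for the period; the sensitivity of the comparison results to it has not
  been mapped).  For desk-scale runs the counts are divided by `scale`
  (default 100, giving a peak Maputo population of ~10,800 agents);
  census-year anchors round deterministically, interpolated years
  stochastically.

The built-in Maputo table is: 1975: 100 L1 / 20,000 L2; 1980: 6,525 /
326,521; 1997: 241,709 / 599,438; 2007: 470,690 / 612,992.  Runs start in
1975 with every agent using only the conservative variant.  Pre-1975 L2
speakers are treated as established (no remaining SLA innovation
opportunities): innovation windows are counted from entry into the
population, and the starting condition asserts the novel variant was absent
in 1975.

## Innovation models

**Model 1**: the only innovation opportunity is the moment of recruitment.
**Model 2 (SLA)**: additionally, at the start of each year every L2 speaker
still inside the SLA window (default 7 years) mutates to the pure
novel-variant distribution with probability μ.  Entry counts as the tenure-0
opportunity and the annual pass covers tenures 1–6, giving exactly seven
opportunities per recruit; a switch (`sla_entry_counts=False`) yields the
alternative reading of eight.  The pass re-applies the indicator even to
agents who already mutated (a no-op on usage) — the simplest literal rule.
Event order within the year boundary is: interactions → tenure increment →
SLA pass → demographic step; with a one-year window this makes Model 2
reduce to Model 1 exactly (path-identical under a shared seed), which the
tests exploit.

## Model–data comparison

Observed counts (xᵢ of nᵢ tokens novel, per speaker) are modelled
binomial-within-speaker with Beta(α, β) rates across speakers.  The
beta-binomial log-likelihood is computed via log-gamma; the MLE is found by
multi-start L-BFGS-B on (log α, log β) with the analytic digamma score
(convergence ftol 1e-12; starts at the pooled proportion with concentrations
2/10/50 plus a diffuse start).  All-zero or all-saturated data are reported
as boundary fits (mean exactly 0 or 1) rather than errors.  The 95% CI for
the mean is a percentile bootstrap over speakers (default 500 replicates).

Simulated ensembles (default R = 10 per setting) are summarised per year by
the cross-run mean m_y and standard deviation s_y; the "95% confidence
interval" is the predictive band m_y ± 1.96·s_y — the spread of runs, not a
standard error, which with R = 10 would be implausibly narrow for an
overlap criterion.  A setting fits when the band contains the MLE point in
every data year.  Minimum-MSE selection compares the per-year ensemble means
with the MLE points; the shipped protocol scans μ = .01–.10 in steps of .01
and then refines once around the coarse optimum in steps of .002, because
the optimum generically falls between coarse grid points (at the Maputo
settings the refined Model 2 selection lands at μ ≈ .018).  The selected
setting is re-run with 100 replicates, and the joint tail probability is the
product over data years of the two-sided normal tail mass
2·min(Φ(z_y), 1−Φ(z_y)), z_y = (MLE_y − m_y)/s_y, treating years as
independent given the model.  Two-sidedness is a choice; a one-sided variant
is exposed (`tails="one"`).

## Synthetic data

The corpus generator inverts the inference model: per speaker a rate
q ~ Beta(mean·c, (1−mean)·c) with concentration c = α+β (default 10,
moderate heterogeneity), then novel ~ Binomial(tokens, q), with tokens per
speaker uniform on 5–40 to mimic uneven interview yields.  It emulates the
overdispersion structure the estimator assumes — not transcript-level
context, speaker demographics, or any repeat-speaker structure of real
interview corpora — so generator-based tests certify the estimator's
calibration under its own model, not robustness to misspecification.

The `reference_corpus` tables are synthetic stand-ins for the two Maputo
recording corpora, calibrated so the pooled novel-variant proportions equal
the published sample means exactly (verbs 10.6%/20%; prepositions
16.9%/25.7%, at 1000 tokens per year).  They carry no information about the
real corpora beyond those pooled means.

## Numerical and performance notes

Distributions are validated to sum to 1 within 1e-12; accumulated float
drift is tolerated to 1e-9 and renormalised (with a warning) beyond that;
inputs off by more than 1e-6 are rejected.  The per-year interaction loop is
RNG-bound and runs in a numba-compiled kernel with an inline xorshift64*
generator, seeded per call from the run's numpy seed stream; the readable
numpy implementation of a single round is retained and used by the
enumeration and kernel-level tests.  Runs are deterministic functions of
(config, seed) on a given installation; replicate seeds are spawned from one
master `SeedSequence`.

Problem sizes in the shipped tests: desk-scale Maputo runs use scale 100;
grid ensembles use R = 10 and tail probabilities 100 replicates; sweeps run
the full 100-year, 365-round horizon at N₀ = 100.  A scale-100 Maputo run
completes in well under a minute on one CPU.

## Known limitations

Homogeneous learning weight and well-mixed interactions (no network
structure, no class-dependent accommodation); no selection or bias terms —
the model is deliberately neutral; single feature with one designated novel
variant; census interpolation and the Maputo mortality rate are assumptions,
not published values; scaled-down census runs inflate drift variance
relative to full-scale runs, which widens predictive bands and shifts tail
probabilities — comparisons at scale 100 are therefore reported as
scaled-down reproductions, not exact ones.
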