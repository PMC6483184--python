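# langshift

Agent-based modelling of contact-induced language change under language
shift, with a simulation–data comparison pipeline for speaker-level usage
counts.

## The problem

When a community shifts to a new language, large numbers of second-language
(L2) speakers enter the speech community, and the language is widely believed
to change faster as a result: L2 speakers are thought to introduce novel
variants during second-language acquisition (SLA), which then spread to
everyone.  `langshift` implements a neutral drift–mutation model of this
process and the statistical machinery to confront it with diachronic corpus
data — the motivating case being the shift from Bantu languages to Portuguese
in Maputo, Mozambique after 1975, where census data give the L1/L2 speaker
counts and two comparable recording campaigns (1993, 2007) give per-speaker
usage of conservative versus novel variants of two grammatical features.

## The model

Each speaker *i* carries a usage distribution *p*ᵢ = (*p*ᵢ₁, …, *p*ᵢₙ) over
the *n* variants of one linguistic feature (variant 1 is the conservative
form; the novel variant defaults to index 2).  In each interaction round every
agent is paired with one partner by a uniformly random perfect matching; both
utter a variant from their pre-round distributions and both update toward what
they heard:

    p'ᵢₖ = pᵢₖ + (1 − pᵢₖ)·l   if the partner uttered k
    p'ᵢₖ = pᵢₖ − pᵢₖ·l          otherwise

with learning weight 0 ≤ *l* ≤ 1.  The dynamics are neutral — the expected
change in the population mean usage of every variant is exactly zero
(verifiable here by exact enumeration) — so all directional change comes from
demography and mutation.  A year is *T* = 365 rounds followed by demographic
turnover: newborn L1 speakers average two random parents' distributions; each
recruited L2 speaker adopts the population mean, except that with innovation
probability *μ* it enters using the novel variant exclusively.  Demography can
be fixed-size, exponentially expanding (growth *g* = *b* + *r* − *d*), or
driven by a census table (the built-in Maputo table, 1975–2007, geometric
interpolation between censuses, rescalable for desk-size runs).  Two
innovation models are provided: **Model 1** (innovation at entry only) and
**Model 2** (additionally, every L2 speaker within a seven-year SLA window
mutates with probability *μ* at the start of each year).

On the data side, speaker counts (xᵢ novel tokens of nᵢ contexts) are
modelled as binomial within speaker with Beta(α, β) rates across speakers;
the beta-binomial MLE of the mean α/(α+β) estimates the population mean
usage, with a speaker-level bootstrap CI.  Replicate simulation ensembles are
summarised by per-year normal fits (m_y, s_y); a parameter setting *fits* if
its 95% band m_y ± 1.96·s_y contains the MLE in every data year, settings are
selected by minimum MSE against the MLE points, and a joint two-sided tail
probability (independent years) quantifies how extreme the data are under the
model.

## Worked example

```python
import langshift as ls

m = ls.LanguageShiftModel(
    regime="expanding", n0=100,
    rates=ls.RateSet(b=0.007, r=0.063, d=0.02),   # g = 0.05
    params=ls.LearningParams(l=0.05, mu=0.05),
)
ens = m.ensemble(R=10, master_seed=42)
print(ens.summary().iloc[[0, 25, 50, 75, 100]].to_string(index=False))
```

```
 year     mean       sd     ci_lo    ci_hi
    0 0.000000 0.000000  0.000000 0.000000
   25 0.036923 0.038574 -0.038682 0.112528
   50 0.109342 0.040325  0.030305 0.188379
   75 0.196029 0.050477  0.097095 0.294963
  100 0.252010 0.055433  0.143362 0.360658
```

Starting from a population using only the conservative variant, recurrent
introduction by L2 recruits (μ = 0.05 at recruitment rate r = 0.063) drives
the novel variant's mean usage to ~25% after 100 years; `sd` is the spread
across the ten replicate runs and `ci_lo`/`ci_hi` the 95% predictive band.

Fitting speaker counts (here a synthetic corpus at true mean 0.169):

```python
counts = ls.generate_speaker_counts(
    ls.CorpusSpec.single(year=1993, n_speakers=50, tokens=20,
                         mean=0.169, concentration=10.0), seed=1)
print(ls.BetaBinomialModel(counts).fit(seed=0).summary())
```

```
Beta-binomial usage model (MLE)
=======================================
speakers                      50
alpha                     2.5949
beta                     15.9450
mean usage                0.1400
95% CI (bootstrap)  [0.1140, 0.1737]
log-likelihood         -104.0062
```

The full Maputo comparison (both models, μ grid, overlap check, min-MSE
selection, joint tail probabilities) is available as
`langshift.ModelComparison` or from the shell:

```
langshift synth --kind reference --feature prepositions --out prep.csv
langshift compare --counts prep.csv --out results/
```

Other subcommands: `simulate` (ensemble from a YAML config), `sweep` (one
summary per innovation rate), `fit-mle`, `synth` (synthetic corpora and
census tables).

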