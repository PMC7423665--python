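# paleotrait

Tools for asking whether extinction in the fossil record was *selective*:
did lineages with particular functional traits — or lineages that were
functionally redundant — die out faster than the average? The package
pairs a Bayesian **multi-trait-dependent extinction (MTE) model** with a
**functional-diversity time-series** toolkit (functional entities,
redundancy, convex-hull functional richness), plus a simulator that
generates assemblages with known trait effects so every part of the method
can be validated end to end. It is aimed at paleobiologists working with
species-level longevity estimates (origination time *t*<sub>s</sub>,
extinction time *t*<sub>e</sub>, in Ma) and categorical trait tables.

## The model

Each lineage *i* in a pool of *S* species gets an extinction rate built
from a mean rate μ₀ and trait-state multipliers *m*:

```
μ_i = μ0 · (∏_v m_{v_i}) · S / Σ_j (∏_v m_{v_j})
```

The normalization makes the *arithmetic mean* of the lineage rates equal
μ₀ exactly, so the multipliers only redistribute risk among states and the
estimated relative effects do not depend on how many species occupy a
state. Durations of extinct lineages are exponential with rate μ_i
(likelihood μ_i·e^(−μ_i t_i)); lineages surviving past the window's recent
boundary are right-censored (likelihood e^(−μ_j t_j)).

Each trait's multiplier simplex is a softmax of free parameters *y*
(first component pinned at 0) with prior *y* ~ N(0, τ⁻¹),
τ ~ Gamma(1.5, β), β ~ Gamma(1, 0.1) — a shrinkage hierarchy that pulls
multipliers toward uniform unless the data push back, with τ and β
sampled by conjugate Gibbs steps. On top of that, a per-trait inclusion
indicator I_v with prior P(I=1) = 0.05 switches the trait's effect on or
off (Bayesian variable selection). Posterior inclusion frequencies map to
Bayes factors: with this prior, a frequency above **51.4%** corresponds
to 2·lnBF > 6, i.e. strong support for a trait effect.

The functional-diversity side groups species into **functional entities**
(unique trait-state combinations), and per 1-Myr time bin reports species
richness, FE count, redundancy (mean species per FE), over-redundancy
(% of species in FEs filled above the mean), and functional richness
(convex-hull volume of the assemblage in a Gower-distance/PCoA trait
space, as % of the whole pool's hull), with richness-matched null
envelopes.

## Worked example

`examples/simulate_and_fit.py` simulates 1000 species in which small-bodied
species go extinct three times faster than large ones (multipliers
0.75/0.25, μ₀ = 0.3 events/lineage/Myr), alongside a three-state trait with
no effect, and refits the model:

```
simulated 1000 species, 822 extinct within the window

posterior mean mu0 = 0.296 (true 0.3)

Trait inclusion (frequency > 51.4% = strong support, 2lnBF > 6):
trait  posterior_frequency  two_ln_bf     support
 size             1.000000  20.879962 very_strong
 diet             0.007222  -3.957810        none

State multipliers (null value = 1/N, i.e. no effect):
trait      state     mean   ci_low  ci_high  null_value  above_null  below_null
 size      small 0.743242 0.716834 0.767625    0.500000        True       False
 size      large 0.256758 0.232375 0.283166    0.500000       False      True
```

The effect trait is recovered (frequency 1.0, very strong support; the
small-state multiplier's credible interval sits entirely above the 0.5
null line), the null trait stays at its prior, and μ₀ is recovered within
2%. The other scripts in `examples/` walk through the
functional-diversity time series, the Bayes-factor scale, and dating
uncertainty propagation. A thin CLI (`paleotrait simulate|bin|fd|mte|
ages-resample`) wraps the same functions for shell pipelines.

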