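"""Simulate an assemblage with a known trait effect and recover it.

Builds 1000 species scored for a binary "size" trait whose states differ
threefold in extinction rate (multipliers 0.75/0.25) plus a three-state
trait with no effect, draws exponential lineage durations over a 23-0 Ma
window, fits the multi-trait-dependent extinction model by MCMC, and
prints the posterior inclusion frequencies, Bayes factors and state
multipliers next to the truth.
"""

import numpy as np

from paleotrait import (
    MTEConfig,
    SimulationConfig,
    run_mte_mcmc,
    simulate_dataset,
    summarize_state_effects,
    summarize_trait_inclusion,
)
from paleotrait.traits import Trait, TraitScheme

scheme = TraitScheme(
    (Trait("size", ("small", "large")), Trait("diet", ("grazer", "predator", "suspension")))
)
config = SimulationConfig(
    scheme=scheme,
    n_species=1000,
    mu0_true=0.3,  # events / lineage / Myr
    true_multipliers={"size": np.array([0.75, 0.25])},  # small goes extinct 3x faster
    included_traits=("size",),
    seed=5,
)
data = simulate_dataset(config)
print(
    f"simulated {config.n_species} species, "
    f"{int(data.longevities.extinct.sum())} extinct within the window"
)

samples = run_mte_mcmc(
    data.longevities,
    data.traits,
    MTEConfig(iterations=200_000, sampling_freq=100, seed=12),
)

print(f"\nposterior mean mu0 = {samples.mu0.mean():.3f} (true {config.mu0_true})")
print("\nTrait inclusion (frequency > 51.4% = strong support, 2lnBF > 6):")
print(summarize_trait_inclusion(samples).to_string(index=False))
print("\nState multipliers (null value = 1/N, i.e. no effect):")
print(summarize_state_effects(samples).to_string(index=False))
print(
    "\nRead: the 'size' trait is (correctly) included with strong support;"
    "\nits small-state multiplier sits near the true 0.75, meaning small"
    "\nspecies die out about three times faster than large ones. The 'diet'"
    "\ntrait stays near the 5% prior: no spurious effect."
)
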