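"""Functional-diversity time series with a richness-matched null model.

Simulates a 300-species assemblage over 23-0 Ma, bins lineage longevities
into 23 one-Myr bins, and reports per bin: species richness, number of
functional entities (unique trait combinations), functional redundancy
(mean species per FE), over-redundancy (% of species in FEs filled above
the mean) and functional richness (% of the global convex-hull volume of
the Gower/PCoA trait space).  A null model re-draws each bin's richness
from the global pool to flag bins whose redundancy departs from random
assembly.
"""


from paleotrait import (
    SimulationConfig,
    bin_presence,
    fd_timeseries,
    null_expectation,
    simulate_dataset,
)
from paleotrait.traits import Trait, TraitScheme

scheme = TraitScheme(
    tuple(
        Trait(name, tuple(f"s{k}" for k in range(4)))
        for name in ("body_size", "life_habit", "locomotion", "environment", "diet")
    )
)
data = simulate_dataset(
    SimulationConfig(scheme=scheme, n_species=300, mu0_true=0.25, seed=3)
)
presence = bin_presence(data.longevities, bin_width=1.0)

ts = fd_timeseries(presence, data.traits)
print("Functional diversity per 1-Myr bin (oldest first):")
print(ts.round(2).to_string(index=False))

null = null_expectation(
    "redundancy", presence, data.traits, n_iter=199, seed=7
)
flagged = null[null["significant"]]
print(f"\n{len(flagged)} of {len(null)} bins depart from the richness-matched null")
print(
    "\nRead: redundancy > 1 means several species share a functional role;"
    "\nfunctional richness near 100% means the bin's species span nearly"
    "\nthe whole trait space. Under random assembly (this simulation),"
    "\nalmost no bin should be flagged against the null."
)
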