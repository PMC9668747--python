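"""Simulate EC3 persistent activity as two-state Markov chains.

Runs the homogeneous (uniform), environment-A and environment-B chain
configurations, checks the closed-form period laws, and measures the
spatial structure each configuration produces.
"""

import numpy as np

import plateaulearn as pl

# uniform configuration: homogeneous P01 = 0.04 s^-1, P10 = 0.25 s^-1
pop = pl.simulate_chains(pl.build_config("uniform"), seed=1)
stats = pl.dwell_statistics(pop)
print(f"active fraction {pop.states.mean():.3f} "
      f"(closed form P01/(P01+P10) = {0.04 / 0.29:.3f})")
print(f"mean active period {stats['active']['mean']:.1f} s (1/P10 = 4.0), "
      f"CV {stats['active']['cv']:.2f} (exponential -> 1)")

# environment A: 1400 of 2000 chains get a 1-s P01 boost to 0.20 s^-1 at a
# fixed within-lap phase, phases tiling the whole lap -> moderate spatial
# tuning uniformly distributed over the belt
pop_a = pl.simulate_chains(pl.build_config("A"), seed=2)
metrics = pl.chain_metrics(pl.map_time_to_space(pop_a)[:1000])
print(f"env A: median odd-even lap correlation "
      f"{metrics['odd_even_r'].median():.2f}, "
      f"{metrics['well_correlated'].mean():.0%} well-correlated chains")

# environment B: boost phases concentrated around the predictive cue at
# 40 cm -> chain activity peaks pile up at the cue
pop_b = pl.simulate_chains(pl.build_config("B"), seed=3)
zone = pl.zone_bins(40.0)
mb = pl.chain_metrics(pl.map_time_to_space(pop_b))
mu = pl.chain_metrics(pl.map_time_to_space(pop)).copy()
hb = pl.peak_histogram(mb["peak_bin"].to_numpy(), zone=zone)
hu = pl.peak_histogram(mu["peak_bin"].to_numpy(), zone=zone)
print(f"env B: {hb['zone_fraction']:.0%} of chain peaks in the cue zone vs "
      f"{hu['zone_fraction']:.0%} for uniform chains "
      f"({hb['zone_fraction'] / hu['zone_fraction']:.1f}-fold enrichment)")
# ~3-fold: the configuration reproduces the elevated density of axons
# peaking at the reward-predictive cue.
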