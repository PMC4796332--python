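"""Forward-simulate the selection scenario grid.

A single locus is followed through a two-population split (lowland Ne 5000,
selected highland Ne 1000) with additive selection of scaled strength
sigma = 118 applied only in the highland population, across three split
times (2800 / 10,000 / 30,000 years at 30 y/generation) and three starting
frequencies.
"""

from hapalt.forward_sim import scenario_grid

grid = scenario_grid(
    p0_values=[0.01, 0.05, 0.1],
    split_years_values=[2800, 10000, 30000],
    sigma=118.0,
    replicates=100,
    seed=5,
)
print(grid.round(3).to_string(index=False))
# Reading: under the 30,000-year split the derived allele fixes in nearly
# every replicate when it starts at >= 5% — so an old split would have
# driven it to fixation, while the 2800-year split leaves it in the
# 0.4-0.6 range observed in present-day highland populations, favouring a
# recent episode of selection from standing variation at 5-10%.
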