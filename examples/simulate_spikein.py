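"""Composition independence of Scaled Abundance, demonstrated by simulation.

Simulates five stool-like backgrounds (distinct Dirichlet compositions and
total loads) that all carry the same four spike-in taxa and internal
standard, then compares the precision of relative abundance and Scaled
Abundance for the spikes between backgrounds.
"""

from scaledabund import (
    relative_abundance,
    scaled_abundance,
    scenario_spikein_backgrounds,
    simulate_scenario,
    spikein_precision,
)

spec = scenario_spikein_backgrounds(
    n_backgrounds=5, n_replicates=3, depth=500_000, seed=7
)
table, bundle = simulate_scenario(spec)
ra = relative_abundance(table)
sa = scaled_abundance(ra, bundle.is_spec)

prec = spikein_precision(ra, sa, bundle.spike_truth, bundle.metadata)
between = prec[prec.scope == "between_backgrounds"]
print("Between-background precision of the four spiked taxa:")
print(
    between[["taxon_id", "cv_ra_percent", "cv_sa_percent"]]
    .round(1)
    .to_string(index=False)
)
# The spikes were added at identical concentrations everywhere, yet their
# relative abundances swing wildly between backgrounds (CVs of tens of
# percent) because the backgrounds differ in composition and total load.
# Scaled Abundance cancels that compositional denominator: its CVs stay
# near the technical-replicate noise floor.

within = prec[prec.scope == "within_replicates"]
print(
    "\nTechnical-replicate SA CV range: "
    f"{within.cv_sa_percent.min():.1f}-{within.cv_sa_percent.max():.1f}%"
)
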