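"""Simulate one mitogenome sample and call its haplotype profile.

Generates a synthetic rCRS-like reference, draws one individual with a
point heteroplasmy spectrum, simulates a 1000x pileup, and runs the
threshold-based caller (100x minimum depth, 5% variant frequency, 1%
strand balance).
"""

import numpy as np

from mitohap import call_profile, format_variant
from mitohap.simulate import SimConfig, generate_reference, simulate_pileup, simulate_population

reference = generate_reference()
config = SimConfig(seed=42, n_individuals=1, php_individual_rate=1.0,
                   length_het_region_rates=(), depth_mean=1000)
_, truth = simulate_population(config, reference)
sample = truth.samples[0]

pileup = simulate_pileup(sample, reference, config, np.random.default_rng(1))
profile, metrics = call_profile(pileup, reference, sample_id="demo")

print(f"called {len(profile.variants)} variants "
      f"({len(profile.php_variants())} point heteroplasmies):")
print(" ", " ".join(format_variant(v) for v in profile.variants))
print(f"mean depth {metrics.average_read_depth:.0f}x; "
      f"major base frequency excluding heteroplasmy "
      f"{100 * metrics.average_major_base_frequency_excl_het:.2f}%")
print("truth PHPs:", [(p, f"{vf:.2f}") for p, _, _, vf in sample.phps])
# Each variant names a difference from the reference; an IUPAC code such
# as Y marks two bases both above the 5% threshold at one position.
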