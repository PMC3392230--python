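"""Simulate a reciprocal F2 intercross family with a distal sex locus.

Builds the default 145-fish design (four chromosomes, the last carrying a
sex-associated region near its telomere with penetrance 1.0 / 0.16 / 0.0
for grandsire-hom / het / granddam-hom genotypes) and prints what the
generator produced.
"""

import numpy as np

from radsexscan import SimulationConfig, simulate_cross

config = SimulationConfig()
sim = simulate_cross(config, np.random.default_rng(1))

gm = sim.genotypes
print(f"markers: {len(gm.markers)} on {gm.markers['chrom'].nunique()} chromosomes")
print(f"F2 individuals: {len(gm.sample_ids)}")
print(sim.sample_sheet["sex"].value_counts().to_string())
depth = sim.read_counts[["n_A", "n_C", "n_G", "n_T"]].sum(axis=1)
print(f"mean read depth: {depth.mean():.1f} (zeros: {(depth == 0).mean():.1%})")
sar = config.resolved_sex_model().loci[0]
print(f"sex locus simulated at {sar[0]}:{sar[1]}")

# The sex ratio reflects the penetrance table: hom-grandsire fish (1/4 of the
# family) are always male, heterozygotes (1/2) are male 16% of the time, so
# roughly a third of the family develops as male.
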