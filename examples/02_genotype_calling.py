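"""Call genotypes from read counts with the bounded error-rate likelihood.

Shows the profile-likelihood machinery on single sites, then calls a whole
simulated read-count table and reports accuracy against the simulation
truth.
"""

import numpy as np

from radsexscan import SimulationConfig, call_genotype, simulate_cross
from radsexscan.genotyper import call_matrix

# Single sites: 19 A reads + 1 C read is decisively homozygous, while 3:1 at
# low depth cannot separate A/A from A/C (likelihood-ratio 1.9 < 6.63).
for counts in ([19, 1, 0, 0], [3, 1, 0, 0], [12, 11, 0, 0]):
    call = call_genotype(counts)
    print(f"counts {counts}: genotype={call.best_genotype} LR={call.lr_stat:.2f} "
          f"called={call.called}")

sim = simulate_cross(SimulationConfig(n_f2=80), np.random.default_rng(2))
calls, _ = call_matrix(sim.read_counts)
called = calls[calls["called"]]
print(f"\ncall rate: {len(called) / len(calls):.1%} of {len(calls)} site-individual pairs")

gm = sim.genotypes
a1, a2 = gm.markers["allele1"].to_numpy(), gm.markers["allele2"].to_numpy()
truth = {}
for i, marker in enumerate(gm.markers["marker_id"]):
    for k, sample in enumerate(gm.sample_ids):
        g1 = a1[i] if gm.maternal[i, k] == 0 else a2[i]
        g2 = a1[i] if gm.paternal[i, k] == 0 else a2[i]
        truth[(marker, sample)] = "/".join(sorted([g1, g2]))
wrong = sum(truth[(m, s)] != g for m, s, g in
            zip(called["marker_id"], called["sample_id"], called["genotype"]))
print(f"miscall rate among called genotypes: {wrong / len(called):.3%}")
# At 30x negative-binomial depth with 1% sequencing error the caller calls
# most sites and miscalls well under 1% of them.
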