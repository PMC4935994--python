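"""Iterative satellite discovery on a simulated genome.

Builds a 300-kb genome carrying one clustered satellite family (1.5% of
the genome, 60-bp monomer), simulates low-coverage paired-end reads and
runs the subtract-and-recluster mining loop. Prints the per-iteration
progress and the consensus monomer recovered.
"""

import numpy as np

from satkit.catalog import pairwise_identity
from satkit.mining import satminer_loop
from satkit.simdata import FamilySpec, simulate_genome, simulate_reads

rng = np.random.default_rng(42)
monomer = "".join(rng.choice(list("ACGT"), 60))
spec = FamilySpec("planted", monomer, genome_proportion=1.5,
                  layout="clustered", n_loci=2, per_copy_divergence=0.02)

genome, truth = simulate_genome([spec], 300_000, seed=1)
pairs = simulate_reads(genome, 5_000, seed=2)
print(f"planted: {truth.realized_proportion['planted']:.3f}% of the genome, "
      f"{len(truth.loci)} loci")

state = satminer_loop(pairs, schedule=[2500, 2500], seed=3)
for h in state.history:
    print(f"iteration {h['iteration']}: {2 * h['reads_used']} reads, "
          f"{h['clusters_examined']} candidate clusters, "
          f"{h['new_satellites']} new satellite(s)")

for sat in state.known_satellites:
    ident = pairwise_identity(sat.seq, monomer)
    print(f"recovered monomer: {sat.length} bp, A+T {sat.at_content:.1f}%, "
          f"{ident:.1f}% identical to the planted monomer")
# The identity is rotation- and strand-invariant: 100% means the planted
# repeat unit was recovered exactly, up to phase and orientation.
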