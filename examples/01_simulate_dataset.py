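"""Generate a synthetic plasmid and single-molecule R-loop footprints.

Builds a 1.6 kb gene region with two initiation clusters, planted
start/end 4-mers and ~600 footprints, then prints summary statistics.
"""

import numpy as np

import rloopgram as rg

spec = rg.spec_for_topology("supercoiled", seed=1)
plasmid, footprints = rg.generate_sample(spec)

lengths = np.array([rec.length for rec in footprints])
starts = np.array([rec.i for rec in footprints])
print(f"plasmid: {len(plasmid.seq)} nt, gene region {plasmid.gene_region}")
print(f"footprints: {len(footprints)}")
print(f"median length: {np.median(lengths):.0f} nt "
      f"(all multiples of k={spec.k}: {bool(np.all(lengths % spec.k == 0))})")
print(f"initiation quartiles: {np.percentile(starts, [25, 50, 75]).round(0)}")

# Each footprint is one [i, j] interval on the non-template strand; the
# quartiles reflect the two planted initiation clusters, and lengths are
# multiples of k so every footprint tiles into k-mer parsing blocks.
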