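"""Build the k-mer symbol dictionary and inspect the weight tables.

Harvests k-mers around footprint initiation/termination sites, ranks them
by weight w_i(s) = n_i(s) / (N * m_s), applies the entropy-threshold
cutoff and assigns grammar symbols.
"""

import rloopgram as rg
from rloopgram.dictionary import region_weight_tables, weight_table_frame

spec = rg.spec_for_topology("supercoiled", seed=1)
plasmid, footprints = rg.generate_sample(spec)

tables = region_weight_tables(footprints, plasmid, k=4, p=13)
r4 = tables["r4"]
print("top of the r4 (post-termination) weight table:")
print(weight_table_frame(r4).head(6).round(5).to_string(index=False))
print(f"entropy cutoff at rank {r4.cutoff_rank} of {len(r4.rows)}")

dic = rg.assign_symbols(tables, k=4, p=13)
print(f"\ndeterminate fraction of all 256 4-mers: {dic.determinate_fraction():.1%}")
for s in spec.start_kmers + spec.end_kmers:
    print(f"planted {s}: outside -> {dic.outside[s]}, inside -> {dic.inside[s]}")

# Planted start-favoring k-mers should map to (sig, tauH) — unstable DNA
# duplex outside an R-loop, stable RNA:DNA hybrid inside — and planted
# end-favoring k-mers to (sigH, tau), the reverse stability pattern.
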