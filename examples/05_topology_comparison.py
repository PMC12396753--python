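"""Rule probabilities across DNA topologies.

Trains small ensembles on synthetic linear / supercoiled /
hyper-negatively supercoiled datasets and summarizes how the main
production-rule probabilities shift with topology.
"""

import rloopgram as rg

ensembles = {}
for topology in ("linear", "supercoiled", "hyper_negative"):
    spec = rg.spec_for_topology(topology, seed=5)
    plasmid, footprints = rg.generate_sample(spec)
    train, _ = rg.split_train_holdout(footprints, seed=1)
    _, models = rg.ensemble_predict(
        {plasmid.name: train}, {plasmid.name: plasmid},
        k=4, p=13, n_models=10, seed=2, return_models=True,
    )
    ensembles[topology] = models

report = rg.rule_probability_report(ensembles)
print(report.pivot(index="rule", columns="topology", values="median").round(4))
print("\npairwise t-tests (Bonferroni-adjusted), smallest p per rule:")
tests = report.attrs["pairwise_tests"]
print(tests.groupby("rule")["p_adjusted"].min().round(4))

# In footprint data, increasing negative supercoiling shifts initiation
# upstream; the grammar absorbs such shifts as changes in rule
# probabilities (e.g. the balance between stable and unstable elongation).
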