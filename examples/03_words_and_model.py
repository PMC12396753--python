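"""Encode footprints as grammar words and fit rule probabilities.

Shows one footprint's parsing blocks and word, then the fitted
probabilities of the six main production rules.
"""

import numpy as np

import rloopgram as rg
from rloopgram.evaluate import MAIN_RULES
from rloopgram.predict import encode_dataset_words

spec = rg.spec_for_topology("supercoiled", seed=1)
plasmid, footprints = rg.generate_sample(spec)
dic = rg.build_dictionary(footprints, plasmid, k=4, p=13)

rec = footprints.records[0]
blocks = rg.parse_blocks(plasmid, rec.i, rec.j, 4)
word = rg.encode_word(blocks, plasmid, dic)
print(f"footprint [{rec.i}, {rec.j}] ({rec.length} nt) ->")
print(f"  word ({len(word.symbols())} symbols): {word.pretty()}")
print(f"  alpha block {word.alpha_len} nt, omega block {word.omega_len} nt")

words = encode_dataset_words(footprints, plasmid, dic)
model = rg.fit_rule_probabilities(words, k=4, p=13)
print(f"\nmodel fitted on {len(words)} words; main rule probabilities:")
for rule in MAIN_RULES:
    print(f"  {str(rule):<16} {model.prob(rule):.4f}")
print(f"word probability of the example: {rg.word_probability(word, model):.3e}")

# The word reads 5'->3': outside symbols, one alpha, inside symbols, one
# omega, outside symbols.  Rule probabilities are relative frequencies of
# rule applications over the unique derivations of all training words.
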