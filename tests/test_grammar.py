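import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rloopgram as rg
from rloopgram.dictionary import INSIDE_SYMBOLS, OUTSIDE_SYMBOLS
from rloopgram.grammar import (
    ALL_RULES,
    ALPHABET,
    Q_RULES,
    R_RULES,
    RULES_BY_LHS,
    S_RULES,
    ProductionRule,
    replay_rules,
    rule_from_string,
    sample_word,
    word_from_symbols,
)

from conftest import homogeneous_dictionary


class TestRuleInventory:
    def test_alphabet_has_ten_symbols(self):
        assert len(ALPHABET) == 10
        assert len(set(ALPHABET)) == 10

    def test_eight_rules_per_family(self):
        assert len(S_RULES) == len(R_RULES) == len(Q_RULES) == 8
        assert len(ALL_RULES) == 24

    def test_rule_string_round_trip(self):
        for rule in ALL_RULES:
            assert rule_from_string(str(rule)) == rule


class TestParseBlocks:
    def test_hand_tiling(self):
        pl = rg.PlasmidSequence("p", "ACGT" * 5, gene_region=(1, 20))
        blocks = rg.parse_blocks(pl, i=6, j=13, k=4)
        spans = [(blk.start, blk.end, blk.role) for blk in blocks]
        assert spans == [
            (1, 4, "pre"), (5, 5, "alpha"),
            (6, 9, "inside"), (10, 13, "inside"),
            (14, 16, "omega"), (17, 20, "post"),
        ]
        assert sum(blk.length for blk in blocks) == 20

    def test_alpha_omega_empty_when_aligned(self):
        pl = rg.PlasmidSequence("p", "ACGT" * 5, gene_region=(1, 20))
        blocks = rg.parse_blocks(pl, i=5, j=16, k=4)
        alpha = next(blk for blk in blocks if blk.role == "alpha")
        omega = next(blk for blk in blocks if blk.role == "omega")
        assert alpha.length == 0 and omega.length == 0

    def test_blocks_tile_region_exactly(self, tiny_plasmid):
        b, e = tiny_plasmid.gene_region
        for i, j in [(10, 13), (9, 16), (12, 19)]:
            blocks = rg.parse_blocks(tiny_plasmid, i, j, 4)
            assert blocks[0].start == b and blocks[-1].end == e
            for prev, nxt in zip(blocks, blocks[1:]):
                assert nxt.start == prev.end + 1

    def test_length_not_multiple_errors(self, tiny_plasmid):
        with pytest.raises(ValueError, match="multiple"):
            rg.parse_blocks(tiny_plasmid, 10, 14, 4)


class TestEncodeWord:
    def test_homogeneous_dictionary_pattern(self, tiny_plasmid):
        dic = homogeneous_dictionary(4)
        blocks = rg.parse_blocks(tiny_plasmid, 10, 17, 4)
        word = rg.encode_word(blocks, tiny_plasmid, dic)
        assert set(word.pre) == {"sigH"} and set(word.post) == {"sigH"}
        assert set(word.inside) == {"tauH"}
        assert word.symbols().count("alpha") == 1

    def test_word_symbols_structure(self, small_model):
        plasmid, dic, _ = small_model
        b, e = plasmid.gene_region
        word = rg.encode_word(rg.parse_blocks(plasmid, b + 8, b + 19, 4), plasmid, dic)
        syms = word.symbols()
        a, o = syms.index("alpha"), syms.index("omega")
        assert all(s in OUTSIDE_SYMBOLS for s in syms[:a])
        assert all(s in INSIDE_SYMBOLS for s in syms[a + 1 : o])
        assert all(s in OUTSIDE_SYMBOLS for s in syms[o + 1 :])


class TestDeriveRules:
    def test_minimal_word(self):
        word = word_from_symbols(["sig", "alpha", "tauH", "omega", "sig"])
        rules = rg.derive_rule_sequence(word)
        assert [str(r) for r in rules] == [
            "S->sig alpha R", "R->tauH omega Q", "Q->sig",
        ]

    def test_longer_word_replays_exactly(self):
        word = word_from_symbols(
            ["sigH", "sig", "alpha", "tau", "omega", "sigH", "sig"]
        )
        rules = rg.derive_rule_sequence(word)
        assert [str(r) for r in rules] == [
            "S->sigH S", "S->sig alpha R", "R->tau omega Q", "Q->sigH Q", "Q->sig",
        ]
        assert replay_rules(rules) == word

    def test_two_alphas_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            word_from_symbols(["sig", "alpha", "alpha", "tau", "omega", "sig"])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        pre=st.lists(st.sampled_from(OUTSIDE_SYMBOLS), min_size=1, max_size=8),
        inside=st.lists(st.sampled_from(INSIDE_SYMBOLS), min_size=1, max_size=8),
        post=st.lists(st.sampled_from(OUTSIDE_SYMBOLS), min_size=1, max_size=8),
    )
    def test_round_trip_random_words(self, pre, inside, post):
        word = rg.RLoopWord(pre=tuple(pre), inside=tuple(inside), post=tuple(post))
        assert replay_rules(rg.derive_rule_sequence(word)) == word


class TestFitProbabilities:
    def test_single_word_mle(self):
        word = word_from_symbols(["sig", "alpha", "tauH", "omega", "sig"])
        model = rg.fit_rule_probabilities([word])
        used = {
            ProductionRule("S", "sig", True),
            ProductionRule("R", "tauH", True),
            ProductionRule("Q", "sig", True),
        }
        for rule in ALL_RULES:
            assert model.prob(rule) == (1.0 if rule in used else 0.0)

    def test_hand_counted_frequencies(self):
        w1 = word_from_symbols(["sig", "sig", "alpha", "tau", "omega", "sig"])
        w2 = word_from_symbols(["sig", "alpha", "tau", "omega", "sig"])
        model = rg.fit_rule_probabilities([w1, w2])
        # S applied 3 times: S->sig S once, S->sig alpha R twice
        assert model.prob(ProductionRule("S", "sig", False)) == pytest.approx(1 / 3)
        assert model.prob(ProductionRule("S", "sig", True)) == pytest.approx(2 / 3)

    def test_pseudocount_uniform_limit(self):
        word = word_from_symbols(["sig", "alpha", "tauH", "omega", "sig"])
        model = rg.fit_rule_probabilities([word], pseudocount=1e9)
        for rule in ALL_RULES:
            assert model.prob(rule) == pytest.approx(1 / 8, rel=1e-6)

    def test_normalization_per_lhs(self, small_sample):
        spec, plasmid, ds = small_sample
        dic = rg.build_dictionary(ds, plasmid, 4, 7)
        words = [
            rg.encode_word(rg.parse_blocks(plasmid, r.i, r.j, 4), plasmid, dic)
            for r in ds.records
        ]
        model = rg.fit_rule_probabilities(words)
        for lhs, rules in RULES_BY_LHS.items():
            assert sum(model.prob(r) for r in rules) == pytest.approx(1.0, abs=1e-12)


class TestWordProbability:
    def test_product_of_rule_probabilities(self):
        word = word_from_symbols(["sig", "alpha", "tauH", "omega", "sig"])
        probs = {
            ProductionRule("S", "sig", True): 0.3,
            ProductionRule("R", "tauH", True): 0.5,
            ProductionRule("Q", "sig", True): 0.7,
        }
        model = rg.GrammarModel(rule_probs=probs)
        assert rg.word_probability(word, model) == pytest.approx(0.3 * 0.5 * 0.7)

    def test_zero_rule_absorbs(self):
        word = word_from_symbols(["sig", "alpha", "tauH", "omega", "sig"])
        model = rg.GrammarModel(
            rule_probs={ProductionRule("S", "sig", True): 0.0}
        )
        assert rg.word_probability(word, model) == 0.0

    def test_all_used_rules_one(self):
        # each rule is used exactly once, so the MLE puts probability 1 on it
        word = word_from_symbols(["sig", "alpha", "tau", "omega", "sig"])
        model = rg.fit_rule_probabilities([word])
        assert rg.word_probability(word, model) == 1.0


def test_generative_consistency():
    """Refitting on words sampled from a model recovers its probabilities."""
    rng = np.random.default_rng(12)
    truth = {
        "S": [0.2, 0.15, 0.05, 0.0, 0.45, 0.1, 0.05, 0.0],
        "R": [0.25, 0.3, 0.0, 0.05, 0.2, 0.15, 0.0, 0.05],
        "Q": [0.3, 0.1, 0.1, 0.0, 0.25, 0.15, 0.1, 0.0],
    }
    probs = {}
    for lhs, rules in RULES_BY_LHS.items():
        for rule, p in zip(rules, truth[lhs]):
            probs[rule] = p
    model = rg.GrammarModel(rule_probs=probs)
    words = [sample_word(model, rng) for _ in range(10_000)]
    refit = rg.fit_rule_probabilities(words)
    for rule in ALL_RULES:
        assert refit.prob(rule) == pytest.approx(model.prob(rule), abs=0.02)


def test_model_tsv_round_trip(tmp_path, small_model):
    _, _, model = small_model
    path = tmp_path / "model.tsv"
    model.to_tsv(path)
    back = rg.GrammarModel.from_tsv(path)
    for rule in ALL_RULES:
        assert back.prob(rule) == pytest.approx(model.prob(rule), abs=1e-15)
    assert back.k == model.k and back.n_words == model.n_words
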