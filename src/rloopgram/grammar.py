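"""The R-loop grammar: terminals, production rules, words and models.

The grammar is right-linear with three nonterminals.  ``S`` generates the
duplex DNA upstream of the R-loop and hands over to ``R`` through the
initiation block alpha; ``R`` generates the RNA:DNA hybrid interior and
hands over to ``Q`` through the termination block omega; ``Q`` generates
the downstream duplex and stops.

    S -> x S | x alpha R      x in {sig, sigH, gamma, delta}
    R -> y R | y omega Q      y in {tau, tauH, rho, beta}
    Q -> x Q | x              x in {sig, sigH, gamma, delta}

Terminal spelling: ``sigH``/``tauH`` are the stable variants (sigma-hat,
tau-hat), ``gamma``/``rho`` indeterminate, ``delta``/``beta`` ambiguous.
alpha and omega are variable-length (0..k-1 nt) branch-migration blocks
marking initiation and termination; every word contains exactly one of
each even at length 0.  Because each terminal determines its rule, every
word has a unique derivation and maximum-likelihood fitting reduces to
relative-frequency counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .dictionary import INSIDE_SYMBOLS, OUTSIDE_SYMBOLS, SymbolDictionary
from .io import PlasmidSequence

#: the ten terminal symbols of the grammar
ALPHABET = ("alpha", "omega", "sig", "sigH", "tau", "tauH", "gamma", "rho", "beta", "delta")

#: pretty-printing map to the conventional Greek spelling
UNICODE_SYMBOLS = {
    "alpha": "α", "omega": "ω",
    "sig": "σ", "sigH": "σ̂",
    "tau": "τ", "tauH": "τ̂",
    "gamma": "γ", "rho": "ρ",
    "beta": "β", "delta": "δ",
}


class ProductionRule(NamedTuple):
    """One rewrite rule, identified by its left side, emitted terminal and
    whether it is the transition rule of its family (S -> x alpha R,
    R -> y omega Q, or the terminal rule Q -> x)."""

    lhs: str
    terminal: str
    transition: bool

    def __str__(self) -> str:
        if self.lhs == "S":
            return f"S->{self.terminal} alpha R" if self.transition else f"S->{self.terminal} S"
        if self.lhs == "R":
            return f"R->{self.terminal} omega Q" if self.transition else f"R->{self.terminal} R"
        return f"Q->{self.terminal}" if self.transition else f"Q->{self.terminal} Q"


S_RULES = tuple(
    ProductionRule("S", x, tr) for tr in (False, True) for x in OUTSIDE_SYMBOLS
)
R_RULES = tuple(
    ProductionRule("R", y, tr) for tr in (False, True) for y in INSIDE_SYMBOLS
)
Q_RULES = tuple(
    ProductionRule("Q", x, tr) for tr in (False, True) for x in OUTSIDE_SYMBOLS
)
ALL_RULES = S_RULES + R_RULES + Q_RULES
RULES_BY_LHS = {"S": S_RULES, "R": R_RULES, "Q": Q_RULES}

_RULE_BY_STR = {str(r): r for r in ALL_RULES}


def rule_from_string(text: str) -> ProductionRule:
    try:
        return _RULE_BY_STR[text]
    except KeyError:
        raise ValueError(f"unknown production rule {text!r}") from None


@dataclass(frozen=True)
class Block:
    """One parsing block: a nucleotide span with a structural role."""

    start: int
    end: int  # inclusive; end = start - 1 encodes an empty alpha/omega block
    role: str  # pre | alpha | inside | omega | post

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RLoopWord:
    """A word of the grammar plus the genomic blocks it annotates."""

    pre: tuple[str, ...]
    inside: tuple[str, ...]
    post: tuple[str, ...]
    alpha_len: int = 0
    omega_len: int = 0
    blocks: tuple[Block, ...] = ()

    def __post_init__(self) -> None:
        if not (self.pre and self.inside and self.post):
            raise ValueError(
                "a word needs at least one terminal before alpha, between "
                "alpha and omega, and after omega"
            )
        bad_out = [s for s in self.pre + self.post if s not in OUTSIDE_SYMBOLS]
        bad_in = [s for s in self.inside if s not in INSIDE_SYMBOLS]
        if bad_out or bad_in:
            raise ValueError(f"terminals in wrong context: {bad_out + bad_in}")

    def symbols(self) -> tuple[str, ...]:
        return self.pre + ("alpha",) + self.inside + ("omega",) + self.post

    def __str__(self) -> str:
        return " ".join(self.symbols())

    def pretty(self) -> str:
        return "".join(UNICODE_SYMBOLS[s] for s in self.symbols())


def word_from_symbols(symbols: Sequence[str]) -> RLoopWord:
    """Build a word from a flat terminal sequence, validating the
    one-alpha/one-omega structure."""
    syms = list(symbols)
    if syms.count("alpha") != 1 or syms.count("omega") != 1:
        raise ValueError("word must contain exactly one alpha and one omega")
    a, o = syms.index("alpha"), syms.index("omega")
    if a > o:
        raise ValueError("alpha must precede omega")
    return RLoopWord(
        pre=tuple(syms[:a]), inside=tuple(syms[a + 1 : o]), post=tuple(syms[o + 1 :])
    )


def parse_blocks(plasmid: PlasmidSequence, i: int, j: int, k: int) -> list[Block]:
    """Tile the gene region [b, e] into parsing blocks around R-loop [i, j].

    ``[b, i-1]`` becomes full k-blocks from b followed by an alpha block of
    length ``(i - b) mod k`` ending at i-1; ``[i, j]`` becomes
    ``(j - i + 1) / k`` k-blocks; ``[j+1, e]`` starts with an omega block
    of length ``(e - j) mod k`` followed by k-blocks ending at e.  The
    blocks tile [b, e] exactly.
    """
    b, e = plasmid.gene_region
    if not (b <= i < j <= e):
        raise ValueError(f"R-loop [{i}, {j}] outside gene region [{b}, {e}]")
    if (j - i + 1) % k != 0:
        raise ValueError(f"R-loop length {j - i + 1} is not a multiple of k={k}")
    blocks: list[Block] = []
    n_pre = (i - b) // k
    for t in range(n_pre):
        blocks.append(Block(b + t * k, b + t * k + k - 1, "pre"))
    alpha_len = (i - b) % k
    blocks.append(Block(i - alpha_len, i - 1, "alpha"))
    for start in range(i, j, k):
        blocks.append(Block(start, start + k - 1, "inside"))
    omega_len = (e - j) % k
    blocks.append(Block(j + 1, j + omega_len, "omega"))
    for start in range(j + omega_len + 1, e, k):
        blocks.append(Block(start, start + k - 1, "post"))
    return blocks


def encode_word(
    blocks: Sequence[Block], plasmid: PlasmidSequence, dic: SymbolDictionary
) -> RLoopWord:
    """Translate parsing blocks into a grammar word via the dictionary."""
    pre: list[str] = []
    inside: list[str] = []
    post: list[str] = []
    alpha_len = omega_len = 0
    for blk in blocks:
        if blk.role == "alpha":
            alpha_len = blk.length
            continue
        if blk.role == "omega":
            omega_len = blk.length
            continue
        kmer = plasmid.kmer_at(blk.start, dic.k)
        if blk.role == "pre":
            pre.append(dic.lookup(kmer, "outside"))
        elif blk.role == "inside":
            inside.append(dic.lookup(kmer, "inside"))
        else:
            post.append(dic.lookup(kmer, "outside"))
    return RLoopWord(
        pre=tuple(pre),
        inside=tuple(inside),
        post=tuple(post),
        alpha_len=alpha_len,
        omega_len=omega_len,
        blocks=tuple(blocks),
    )


def derive_rule_sequence(word: RLoopWord) -> list[ProductionRule]:
    """The unique sequence of rules generating the word.

    Every pre-alpha terminal applies an S-rule (the last one carries
    alpha), every inside terminal an R-rule (the last carries omega), and
    every post-omega terminal a Q-rule (the last is the stopping rule).
    Concatenating the right-hand sides reproduces the word exactly.
    """
    rules: list[ProductionRule] = []
    for t, sym in enumerate(word.pre):
        rules.append(ProductionRule("S", sym, t == len(word.pre) - 1))
    for t, sym in enumerate(word.inside):
        rules.append(ProductionRule("R", sym, t == len(word.inside) - 1))
    for t, sym in enumerate(word.post):
        rules.append(ProductionRule("Q", sym, t == len(word.post) - 1))
    return rules


def replay_rules(rules: Sequence[ProductionRule]) -> RLoopWord:
    """Apply a rule sequence from S, returning the generated word."""
    symbols: list[str] = []
    state = "S"
    for rule in rules:
        if rule.lhs != state:
            raise ValueError(f"rule {rule} not applicable in state {state}")
        symbols.append(rule.terminal)
        if rule.lhs == "S":
            if rule.transition:
                symbols.append("alpha")
                state = "R"
        elif rule.lhs == "R":
            if rule.transition:
                symbols.append("omega")
                state = "Q"
        else:
            if rule.transition:
                state = "done"
    if state != "done":
        raise ValueError("rule sequence does not terminate the derivation")
    return word_from_symbols(symbols)


@dataclass
class GrammarModel:
    """Probability assignment for every production rule."""

    rule_probs: dict[ProductionRule, float]
    k: int = 0
    p: int = 0
    n_words: int = 0
    provenance: str = ""

    def prob(self, rule: ProductionRule) -> float:
        return self.rule_probs.get(rule, 0.0)

    def log_prob(self, rule: ProductionRule) -> float:
        p = self.prob(rule)
        return math.log(p) if p > 0 else -math.inf

    def validate(self, tol: float = 1e-12) -> None:
        for lhs, rules in RULES_BY_LHS.items():
            total = sum(self.prob(r) for r in rules)
            if abs(total - 1.0) > tol:
                raise ValueError(f"{lhs}-rule probabilities sum to {total}, not 1")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# k={self.k}\tp={self.p}\tn_words={self.n_words}\t"
                f"provenance={self.provenance}\n"
            )
            fh.write("rule\tprobability\n")
            for rule in ALL_RULES:
                fh.write(f"{rule}\t{self.prob(rule):.17g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GrammarModel":
        probs: dict[ProductionRule, float] = {}
        meta = {"k": 0, "p": 0, "n_words": 0, "provenance": ""}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for part in line[1:].split("\t"):
                        key, _, val = part.strip().partition("=")
                        if key in ("k", "p", "n_words"):
                            meta[key] = int(val)
                        elif key == "provenance":
                            meta["provenance"] = val
                    continue
                if not line or line.startswith("rule\t"):
                    continue
                text, prob = line.rsplit("\t", 1)
                probs[rule_from_string(text)] = float(prob)
        return cls(rule_probs=probs, **meta)


def fit_rule_probabilities(
    words: Iterable[RLoopWord],
    pseudocount: float = 0.0,
    k: int = 0,
    p: int = 0,
    provenance: str = "",
) -> GrammarModel:
    """Maximum-likelihood rule probabilities from observed words.

    P(X -> v) = (count of X -> v + pseudocount) /
                (count of X applications + pseudocount * |X-rules|).

    The derivation of each word is unique, so counting rule applications
    is exact; with pseudocount 0 unobserved rules keep probability 0.
    """
    counts: dict[ProductionRule, int] = {r: 0 for r in ALL_RULES}
    n_words = 0
    for word in words:
        n_words += 1
        for rule in derive_rule_sequence(word):
            counts[rule] += 1
    if n_words == 0:
        raise ValueError("cannot fit a model on an empty word list")
    probs: dict[ProductionRule, float] = {}
    for lhs, rules in RULES_BY_LHS.items():
        total = sum(counts[r] for r in rules) + pseudocount * len(rules)
        for r in rules:
            probs[r] = (counts[r] + pseudocount) / total if total > 0 else 0.0
    return GrammarModel(rule_probs=probs, k=k, p=p, n_words=n_words, provenance=provenance)


def word_probability(word: RLoopWord, model: GrammarModel) -> float:
    """Probability of a word: the product over its unique rule sequence."""
    prob = 1.0
    for rule in derive_rule_sequence(word):
        prob *= model.prob(rule)
        if prob == 0.0:
            return 0.0
    return prob


def sample_word(
    model: GrammarModel, rng: np.random.Generator, max_symbols: int = 10_000
) -> RLoopWord:
    """Forward-sample one word from a fitted model (for simulation tests)."""
    symbols: list[str] = []
    state = "S"
    while state != "done":
        if len(symbols) > max_symbols:
            raise RuntimeError("sampled word exceeded max_symbols; model nearly non-terminating")
        rules = RULES_BY_LHS[state]
        probs = np.array([model.prob(r) for r in rules])
        total = probs.sum()
        if total <= 0:
            raise ValueError(f"no probability mass on {state}-rules")
        rule = rules[int(rng.choice(len(rules), p=probs / total))]
        symbols.append(rule.terminal)
        if rule.lhs == "S" and rule.transition:
            symbols.append("alpha")
            state = "R"
        elif rule.lhs == "R" and rule.transition:
            symbols.append("omega")
            state = "Q"
        elif rule.lhs == "Q" and rule.transition:
            state = "done"
    return word_from_symbols(symbols)
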