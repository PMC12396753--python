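"""Per-nucleotide R-loop probability landscapes.

A trained model assigns a probability to every *candidate* R-loop word on
a plasmid — every interval [i, j] in the gene region whose length is a
multiple of k and which leaves at least one full k-block on each side (the
start and stop rule families each emit at least one terminal).  Candidate
probabilities are normalized to a distribution over words, and the
probability that nucleotide t lies inside an R-loop is the total mass of
candidates covering t.

The hot path scores all candidates with log-space prefix sums over three
fixed block grids (upstream blocks anchored at b, downstream blocks
anchored at e, interior blocks on the k phase grids), which makes scoring
O(L^2 / k) for a gene region of length L.  A direct per-candidate
enumeration is retained as ``normalized_word_distribution_brute`` and
serves as the reference implementation in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dictionary import SymbolDictionary, build_dictionary, merge_union_dictionary
from .grammar import (
    GrammarModel,
    ProductionRule,
    encode_word,
    fit_rule_probabilities,
    parse_blocks,
    word_probability,
)
from .io import Dataset, PlasmidSequence, subsample

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """All admissible R-loop intervals on a plasmid for a given k."""

    plasmid: str
    k: int
    pairs: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ProbabilityTrack:
    """Per-nucleotide probability of R-loop membership over [b, e]."""

    plasmid: str
    b: int
    e: int
    mean: np.ndarray
    sem: np.ndarray
    n_models: int = 1
    metadata: dict = field(default_factory=dict)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.b, self.e + 1)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tmean\tsem\n")
            for pos, m, s in zip(self.positions, self.mean, self.sem):
                fh.write(f"{pos}\t{m:.10g}\t{s:.10g}\n")

    def to_bedgraph(self, path: str | Path) -> None:
        """bedGraph export (0-based half-open intervals of one nucleotide)."""
        with open(path, "w") as fh:
            for pos, m in zip(self.positions, self.mean):
                fh.write(f"{self.plasmid}\t{pos - 1}\t{pos}\t{m:.10g}\n")


def enumerate_candidates(
    plasmid: PlasmidSequence,
    k: int,
    min_len: int | None = None,
    max_len: int | None = None,
) -> CandidateSet:
    """All (i, j) with length a multiple of k, i - b >= k and e - j >= k."""
    b, e = plasmid.gene_region
    if min_len is None:
        min_len = k
    if min_len < k or min_len % k != 0:
        raise ValueError("min_len must be a positive multiple of k")
    if max_len is None:
        max_len = e - b + 1
    pairs: list[tuple[int, int]] = []
    for i in range(b + k, e + 1):
        j_lo = i + min_len - 1
        j_hi = min(i + max_len - 1, e - k)
        for j in range(j_lo, j_hi + 1, k):
            pairs.append((i, j))
    if not pairs:
        logger.warning(
            "gene region [%d, %d] too short for any candidate at k=%d", b, e, k
        )
    return CandidateSet(plasmid=plasmid.name, k=k, pairs=pairs)


def _position_log_arrays(
    plasmid: PlasmidSequence, dic: SymbolDictionary, model: GrammarModel
) -> dict[str, np.ndarray]:
    """Log rule probabilities for the k-mer starting at each gene position.

    Arrays are indexed by offset t = start - b for starts in
    [b, e - k + 1]; each entry is the log probability of the rule emitting
    the symbol of that k-mer in the relevant family/role.
    """
    b, e = plasmid.gene_region
    k = dic.k
    n = e - k + 1 - b + 1
    out = {
        name: np.full(n, -np.inf)
        for name in ("S_loop", "S_trans", "R_loop", "R_trans", "Q_loop", "Q_term")
    }
    for t in range(n):
        kmer = plasmid.kmer_at(b + t, k)
        o = dic.outside[kmer]
        i = dic.inside[kmer]
        out["S_loop"][t] = model.log_prob(ProductionRule("S", o, False))
        out["S_trans"][t] = model.log_prob(ProductionRule("S", o, True))
        out["R_loop"][t] = model.log_prob(ProductionRule("R", i, False))
        out["R_trans"][t] = model.log_prob(ProductionRule("R", i, True))
        out["Q_loop"][t] = model.log_prob(ProductionRule("Q", o, False))
        out["Q_term"][t] = model.log_prob(ProductionRule("Q", o, True))
    return out


def _cum_with_zeros(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative sums that survive -inf entries (zero-probability rules).

    Returns ``(csum, czero)`` with a leading 0 so that the sum over a slice
    [a, b) is ``csum[b] - csum[a]`` when ``czero[b] == czero[a]`` and -inf
    otherwise.  Plain cumulative sums would turn -inf - -inf into NaN.
    """
    finite = np.isfinite(values)
    csum = np.concatenate([[0.0], np.cumsum(np.where(finite, values, 0.0))])
    czero = np.concatenate([[0], np.cumsum(~finite)])
    return csum, czero


def candidate_log_probs(
    cands: CandidateSet,
    plasmid: PlasmidSequence,
    dic: SymbolDictionary,
    model: GrammarModel,
) -> np.ndarray:
    """Unnormalized log probability of every candidate word (prefix-sum DP)."""
    b, e = plasmid.gene_region
    k = dic.k
    logs = _position_log_arrays(plasmid, dic, model)

    # upstream blocks on the grid b, b+k, ...: a candidate with n_pre blocks
    # scores the sum of the first n_pre - 1 S-loop terms plus the S-transition
    # term at the last grid block.
    n_up = (e - b + 1) // k
    up_idx = np.arange(n_up) * k
    cumS, cntS = _cum_with_zeros(logs["S_loop"][up_idx])

    # downstream blocks anchored at e: grid starts e-k+1, e-2k+1, ...; the
    # block ending at e takes the terminal Q-rule, the rest Q-loop rules.
    down_starts = np.array([e - (m + 1) * k + 1 - b for m in range(n_up)])
    q_loop_down = logs["Q_loop"][down_starts]
    q_term_last = logs["Q_term"][down_starts[0]]
    cum_q, cnt_q = _cum_with_zeros(q_loop_down[1:])

    # interior blocks: for phase r = (i - b) mod k, cumulative R-loop sums
    # along starts b+r, b+r+k, ...
    cumR_by_phase = []
    for r in range(k):
        starts = np.arange(r, e - k + 1 - b + 1, k)
        cumR_by_phase.append(_cum_with_zeros(logs["R_loop"][starts]))

    neg_inf = -np.inf
    out = np.empty(len(cands.pairs))
    for idx, (i, j) in enumerate(cands.pairs):
        n_pre = (i - b) // k
        if cntS[n_pre - 1] > 0:
            out[idx] = neg_inf
            continue
        pre = cumS[n_pre - 1] + logs["S_trans"][(n_pre - 1) * k]
        r = (i - b) % k
        gi = (i - b - r) // k       # grid index of the block starting at i
        gj = (j - k + 1 - b - r) // k  # grid index of the closing block
        cumR, cntR = cumR_by_phase[r]
        if cntR[gj] > cntR[gi]:
            out[idx] = neg_inf
            continue
        interior = (cumR[gj] - cumR[gi]) + logs["R_trans"][j - k + 1 - b]
        n_post = (e - j) // k
        if cnt_q[n_post - 1] > 0:
            out[idx] = neg_inf
            continue
        post = q_term_last + cum_q[n_post - 1]
        out[idx] = pre + interior + post
    return out


def normalized_word_distribution(
    cands: CandidateSet,
    plasmid: PlasmidSequence,
    dic: SymbolDictionary,
    model: GrammarModel,
) -> dict[tuple[int, int], float]:
    """Distribution over candidate words, P(w) normalized to sum to 1.

    If every candidate has probability zero under the model, a uniform
    distribution is returned with a warning (rather than NaNs).
    """
    if not cands.pairs:
        raise ValueError("empty candidate set")
    logp = candidate_log_probs(cands, plasmid, dic, model)
    return _normalize(cands, logp)


def _normalize(
    cands: CandidateSet, logp: np.ndarray
) -> dict[tuple[int, int], float]:
    finite = np.isfinite(logp)
    if not finite.any():
        logger.warning(
            "all %d candidate words have zero probability; falling back to "
            "a uniform distribution", len(cands.pairs),
        )
        u = 1.0 / len(cands.pairs)
        return {pair: u for pair in cands.pairs}
    m = logp[finite].max()
    weights = np.where(finite, np.exp(logp - m), 0.0)
    weights /= weights.sum()
    return {pair: float(w) for pair, w in zip(cands.pairs, weights)}


def normalized_word_distribution_brute(
    cands: CandidateSet,
    plasmid: PlasmidSequence,
    dic: SymbolDictionary,
    model: GrammarModel,
) -> dict[tuple[int, int], float]:
    """Reference implementation: encode and score each candidate word."""
    if not cands.pairs:
        raise ValueError("empty candidate set")
    logp = np.empty(len(cands.pairs))
    for idx, (i, j) in enumerate(cands.pairs):
        word = encode_word(parse_blocks(plasmid, i, j, dic.k), plasmid, dic)
        prob = word_probability(word, model)
        logp[idx] = math.log(prob) if prob > 0 else -math.inf
    return _normalize(cands, logp)


def per_nucleotide_track(
    dist: Mapping[tuple[int, int], float],
    plasmid: PlasmidSequence,
) -> ProbabilityTrack:
    """q(t) = sum of word probabilities over candidates covering t."""
    b, e = plasmid.gene_region
    diff = np.zeros(e - b + 2)
    for (i, j), p in dist.items():
        diff[i - b] += p
        diff[j - b + 1] -= p
    q = np.cumsum(diff[:-1])
    q = np.clip(q, 0.0, 1.0)  # guard tiny negative round-off
    return ProbabilityTrack(
        plasmid=plasmid.name, b=b, e=e, mean=q, sem=np.zeros_like(q), n_models=1
    )


def predict_track(
    plasmid: PlasmidSequence,
    dic: SymbolDictionary,
    model: GrammarModel,
    min_len: int | None = None,
    max_len: int | None = None,
) -> ProbabilityTrack:
    """Candidate enumeration + word distribution + coverage track."""
    cands = enumerate_candidates(plasmid, dic.k, min_len=min_len, max_len=max_len)
    dist = normalized_word_distribution(cands, plasmid, dic, model)
    return per_nucleotide_track(dist, plasmid)


def encode_dataset_words(
    ds: Dataset, plasmid: PlasmidSequence, dic: SymbolDictionary
) -> list:
    """Encode every footprint as a grammar word.

    Footprints leaving less than one full k-block between themselves and a
    gene-region boundary have no derivation in the grammar (the start and
    stop rule families each emit at least one terminal) and are skipped
    with a warning.
    """
    b, e = plasmid.gene_region
    k = dic.k
    words = []
    n_skipped = 0
    for rec in ds.records:
        if rec.i - b < k or e - rec.j < k:
            n_skipped += 1
            continue
        words.append(encode_word(parse_blocks(plasmid, rec.i, rec.j, k), plasmid, dic))
    if n_skipped:
        logger.warning(
            "%d record(s) too close to the gene-region boundary to encode as "
            "words at k=%d; skipped", n_skipped, k,
        )
    return words


def train_one_model(
    training: Mapping[str, Dataset],
    plasmids: Mapping[str, PlasmidSequence],
    k: int,
    p: int,
    dict_mode: str = "stochastic",
    rng: np.random.Generator | None = None,
    pseudocount: float = 0.0,
) -> tuple[SymbolDictionary, GrammarModel]:
    """Build per-plasmid dictionaries, merge, encode words and fit rules.

    ``training`` maps plasmid name -> training Dataset.  With one plasmid
    no merge is needed; with two the union dictionary resolves conflicts
    according to ``dict_mode``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    names = sorted(training)
    dicts = [build_dictionary(training[n], plasmids[n], k, p) for n in names]
    if len(dicts) == 1:
        dic = dicts[0]
    else:
        dic = dicts[0]
        for other in dicts[1:]:
            dic = merge_union_dictionary(dic, other, mode=dict_mode, seed=rng)
    words = []
    for name in names:
        words.extend(encode_dataset_words(training[name], plasmids[name], dic))
    model = fit_rule_probabilities(
        words, pseudocount=pseudocount, k=k, p=p,
        provenance=f"train:{'+'.join(names)}",
    )
    return dic, model


def ensemble_predict(
    full_training: Mapping[str, Dataset],
    plasmids: Mapping[str, PlasmidSequence],
    k: int,
    p: int,
    n_models: int = 30,
    subsample_frac: float = 0.10,
    dict_mode: str = "stochastic",
    seed: int = 0,
    min_len: int | None = None,
    max_len: int | None = None,
    pseudocount: float = 0.0,
    return_models: bool = False,
):
    """Ensemble of models, each trained on a fresh subsample per plasmid.

    For each of ``n_models`` rounds a ``subsample_frac`` fraction of each
    plasmid's full training dataset is drawn without replacement,
    per-plasmid dictionaries are built and merged, R-loops are encoded as
    words, rule probabilities are fitted and a per-nucleotide track is
    predicted for every plasmid.  The returned tracks carry the
    per-position ensemble mean and the standard error of the mean
    (sample standard deviation / sqrt(n_models)).  Fully reproducible
    under a fixed seed.

    Returns a dict plasmid name -> ProbabilityTrack (and the list of
    fitted models when ``return_models`` is set).
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    names = sorted(full_training)
    for name in names:
        if len(full_training[name]) < 1:
            raise ValueError(f"empty training dataset for {name}")
        if subsample_frac * len(full_training[name]) < 1:
            logger.warning(
                "subsample of %s rounds up to a single record", name
            )
    seed_seq = np.random.SeedSequence(seed)
    tracks: dict[str, list[np.ndarray]] = {n: [] for n in names}
    models: list[GrammarModel] = []
    for child in seed_seq.spawn(n_models):
        rng = np.random.default_rng(child)
        sub = {n: subsample(full_training[n], subsample_frac, rng) for n in names}
        dic, model = train_one_model(
            sub, plasmids, k, p, dict_mode=dict_mode, rng=rng,
            pseudocount=pseudocount,
        )
        models.append(model)
        for n in names:
            tr = predict_track(plasmids[n], dic, model, min_len=min_len, max_len=max_len)
            tracks[n].append(tr.mean)
    out: dict[str, ProbabilityTrack] = {}
    for n in names:
        stack = np.vstack(tracks[n])
        mean = stack.mean(axis=0)
        if n_models > 1:
            sem = stack.std(axis=0, ddof=1) / math.sqrt(n_models)
        else:
            sem = np.zeros_like(mean)
        b, e = plasmids[n].gene_region
        out[n] = ProbabilityTrack(
            plasmid=n, b=b, e=e, mean=mean, sem=sem, n_models=n_models,
            metadata={"k": k, "p": p, "subsample_frac": subsample_frac,
                      "dict_mode": dict_mode, "seed": seed},
        )
    if return_models:
        return out, models
    return out
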