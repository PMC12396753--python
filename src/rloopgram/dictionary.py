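"""K-mer harvesting, weighting, entropy thresholding and symbol assignment.

For every R-loop ``[i, j]`` four regions of interest are scanned with a
sliding window of width ``k``: ``r1`` just upstream of initiation, ``r2``
just downstream of initiation, ``r3`` just upstream of termination and
``r4`` just downstream of termination.  Each region spans ``k + p``
nucleotides, where the padding ``p`` absorbs the experimental uncertainty
in footprint boundaries.

Each harvested k-mer s receives, per region, the weight

    w_i(s) = n_i(s) / (N * m_s)

with ``n_i(s)`` the number of occurrences of s in region ``r_i`` across
all N R-loops of the training set (with multiplicity) and ``m_s`` the
number of (overlapping) occurrences of s in the gene region.  Ranked
weights are cut off at the global maximum of the running average entropy
of the rescaled weights; the surviving "highly weighted" k-mers drive the
assignment of grammar symbols.

Weights are kept as exact rationals so that rank groups (ties) and the
cross-region maxima used by the symbol assignment are never split or
merged by floating-point noise.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Dataset, PlasmidSequence

logger = logging.getLogger(__name__)

REGIONS = ("r1", "r2", "r3", "r4")

#: regions flanking/holding the R-loop start vs the R-loop end
START_REGIONS = ("r1", "r2")
END_REGIONS = ("r3", "r4")

# terminal symbols, ASCII spelling (sigH = sigma-hat, tauH = tau-hat)
OUTSIDE_SYMBOLS = ("sig", "sigH", "gamma", "delta")
INSIDE_SYMBOLS = ("tauH", "tau", "rho", "beta")


@dataclass
class RegionKmerCollection:
    """Multiset of k-mers harvested from one region across a training set."""

    region_id: str
    k: int
    p: int
    counts: Counter

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class WeightRow:
    """One rank group of the per-region weight table (k-mers tied by weight)."""

    rank: int
    kmers: tuple[str, ...]
    weight: Fraction
    rescaled: float = 0.0
    entropy: float = 0.0
    avg_entropy: float = 0.0


@dataclass
class RegionWeightTable:
    region_id: str
    rows: list[WeightRow]
    n_rloops: int
    cutoff_rank: int | None = None

    def highly_weighted(self) -> dict[str, Fraction]:
        """k-mer -> weight for ranks up to the entropy cutoff (ties whole)."""
        if self.cutoff_rank is None:
            raise ValueError("entropy threshold has not been applied")
        out: dict[str, Fraction] = {}
        for row in self.rows[: self.cutoff_rank]:
            for s in row.kmers:
                out[s] = row.weight
        return out


@dataclass
class SymbolDictionary:
    """Total map from (k-mer, context) to a terminal symbol.

    ``context`` is "outside" (the k-mer sits before initiation or after
    termination) or "inside" (within the R-loop).  Outside symbols are
    drawn from {sig, sigH, gamma, delta}; inside symbols from
    {tauH, tau, rho, beta}.
    """

    k: int
    p: int
    outside: dict[str, str]
    inside: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        n = 4 ** self.k
        if len(self.outside) != n or len(self.inside) != n:
            raise ValueError(f"dictionary must be total over all {n} {self.k}-mers")

    def lookup(self, kmer: str, context: str) -> str:
        if context == "outside":
            return self.outside[kmer]
        if context == "inside":
            return self.inside[kmer]
        raise ValueError(f"unknown context {context!r}")

    def determinate_fraction(self) -> float:
        """Fraction of k-mers carrying an informative (non-gamma/rho) symbol."""
        n = 4 ** self.k
        det = sum(1 for s in self.outside.values() if s != "gamma")
        return det / n

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# k={self.k}\tp={self.p}\tprovenance={self.provenance}\n")
            fh.write("kmer\toutside_symbol\tinside_symbol\n")
            for s in sorted(self.outside):
                fh.write(f"{s}\t{self.outside[s]}\t{self.inside[s]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SymbolDictionary":
        outside: dict[str, str] = {}
        inside: dict[str, str] = {}
        k = p = None
        prov = ""
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for part in line[1:].split("\t"):
                        key, _, val = part.strip().partition("=")
                        if key == "k":
                            k = int(val)
                        elif key == "p":
                            p = int(val)
                        elif key == "provenance":
                            prov = val
                    continue
                if line.startswith("kmer\t") or not line:
                    continue
                s, o, i = line.split("\t")
                outside[s] = o
                inside[s] = i
        if k is None or p is None:
            raise ValueError(f"{path}: missing k/p header")
        return cls(k=k, p=p, outside=outside, inside=inside, provenance=prov)


def region_windows(i: int, j: int, k: int, p: int) -> dict[str, list[int]]:
    """Start positions of all sliding windows per region for R-loop [i, j].

    r1 slides the window ``[i-k, i-1]`` leftwards p times; r2 slides
    ``[i, i+k-1]`` rightwards; r3 slides ``[j-k+1, j]`` leftwards; r4
    slides ``[j+1, j+k]`` rightwards.  Windows are returned regardless of
    gene-region bounds; the caller filters.
    """
    return {
        "r1": [i - k - t for t in range(p + 1)],
        "r2": [i + t for t in range(p + 1)],
        "r3": [j - k + 1 - t for t in range(p + 1)],
        "r4": [j + 1 + t for t in range(p + 1)],
    }


def extract_region_kmers(
    ds: Dataset, plasmid: PlasmidSequence, k: int, p: int
) -> dict[str, RegionKmerCollection]:
    """Harvest k-mers around initiation/termination of every R-loop.

    Windows extending beyond the gene region [b, e] are discarded;
    multiplicities are retained.
    """
    if k < 1 or p < 0:
        raise ValueError("require k >= 1 and p >= 0")
    b, e = plasmid.gene_region
    counts = {r: Counter() for r in REGIONS}
    for rec in ds.records:
        for region, starts in region_windows(rec.i, rec.j, k, p).items():
            for start in starts:
                if start < b or start + k - 1 > e:
                    continue
                counts[region][plasmid.kmer_at(start, k)] += 1
    for region in REGIONS:
        if not counts[region]:
            logger.warning("region %s produced no k-mers", region)
    return {
        r: RegionKmerCollection(region_id=r, k=k, p=p, counts=counts[r])
        for r in REGIONS
    }


def genome_multiplicity(plasmid: PlasmidSequence, k: int) -> Counter:
    """Overlapping k-mer occurrence counts over the gene region only."""
    gene = plasmid.gene_seq()
    return Counter(gene[t : t + k] for t in range(len(gene) - k + 1))


def compute_weights(
    coll: RegionKmerCollection,
    plasmid: PlasmidSequence,
    n_rloops: int,
    multiplicity: Counter | None = None,
) -> RegionWeightTable:
    """Rank the region's k-mers by exact weight n_i(s) / (N * m_s)."""
    if n_rloops <= 0:
        raise ValueError("n_rloops must be positive")
    if multiplicity is None:
        multiplicity = genome_multiplicity(plasmid, coll.k)
    weights: dict[str, Fraction] = {}
    for s, n_s in coll.counts.items():
        m_s = multiplicity[s]
        if m_s == 0:
            raise ValueError(
                f"k-mer {s} observed in region {coll.region_id} but absent "
                "from the gene region"
            )
        weights[s] = Fraction(n_s, n_rloops * m_s)
    by_weight: dict[Fraction, list[str]] = {}
    for s, w in weights.items():
        by_weight.setdefault(w, []).append(s)
    rows = [
        WeightRow(rank=rank, kmers=tuple(sorted(group)), weight=w)
        for rank, (w, group) in enumerate(
            sorted(by_weight.items(), key=lambda kv: kv[0], reverse=True), start=1
        )
    ]
    return RegionWeightTable(region_id=coll.region_id, rows=rows, n_rloops=n_rloops)


def entropy_curve(weights: Sequence[float | Fraction]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rescaled weights, per-rank entropies and running average entropies.

    ``weights`` is one raw weight per rank group, strictly decreasing.
    Rescaling divides by the top weight; the entropy of rank n is
    ``H_n = -w'_n * log10(w'_n)`` and ``h_n`` is the mean of H_1..H_n.
    """
    if len(weights) == 0:
        raise ValueError("empty weight list")
    w = [Fraction(x) if not isinstance(x, Fraction) else x for x in weights]
    top = w[0]
    rescaled = np.array([float(x / top) for x in w])
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(rescaled > 0, -rescaled * np.log10(rescaled), 0.0)
    H[0] = 0.0  # top rank rescales to 1 exactly
    h = np.cumsum(H) / np.arange(1, len(H) + 1)
    return rescaled, H, h


def entropy_threshold(table: RegionWeightTable) -> RegionWeightTable:
    """Apply the entropy-reduction cutoff to a ranked weight table.

    Fills the rescaled/entropy/average-entropy columns and sets
    ``cutoff_rank`` to the first rank attaining the global maximum of the
    running average entropy.  k-mers at ranks up to the cutoff form the
    highly weighted list; tied groups are kept whole.
    """
    if not table.rows:
        raise ValueError("cannot threshold an empty weight table")
    rescaled, H, h = entropy_curve([row.weight for row in table.rows])
    for row, wp, Hn, hn in zip(table.rows, rescaled, H, h):
        row.rescaled = float(wp)
        row.entropy = float(Hn)
        row.avg_entropy = float(hn)
    table.cutoff_rank = int(np.argmax(h)) + 1
    return table


def region_weight_tables(
    ds: Dataset, plasmid: PlasmidSequence, k: int, p: int
) -> dict[str, RegionWeightTable]:
    """Harvest, weight and threshold all four regions for one training set."""
    colls = extract_region_kmers(ds, plasmid, k, p)
    mult = genome_multiplicity(plasmid, k)
    tables: dict[str, RegionWeightTable] = {}
    for r, coll in colls.items():
        if not coll.counts:
            tables[r] = RegionWeightTable(region_id=r, rows=[], n_rloops=len(ds.records))
            tables[r].cutoff_rank = 0
            continue
        tables[r] = entropy_threshold(
            compute_weights(coll, plasmid, len(ds.records), mult)
        )
    return tables


def assign_symbols(
    tables: Mapping[str, RegionWeightTable], k: int, p: int, provenance: str = ""
) -> SymbolDictionary:
    """Build the total symbol map C(l, s) from the highly weighted lists.

    For each k-mer s let ``w*_i(s)`` be its weight in region i if s made
    that region's highly weighted list, else 0, and let w*(s) be the
    maximum over regions.  Then:

    * w*(s) = 0 everywhere -> indeterminate: outside gamma, inside rho;
    * the maximum is attained both in a start region {r1, r2} and an end
      region {r3, r4} -> ambiguous: outside delta, inside beta;
    * maximum from {r1, r2} -> outside sig (unstable DNA duplex signal at
      R-loop starts), inside tauH (stable RNA:DNA hybrid);
    * maximum from {r3, r4} -> outside sigH, inside tau.
    """
    hw = {r: tables[r].highly_weighted() if tables[r].rows else {} for r in REGIONS}
    zero = Fraction(0)
    outside: dict[str, str] = {}
    inside: dict[str, str] = {}
    for tup in itertools.product("ACGT", repeat=k):
        s = "".join(tup)
        w = {r: hw[r].get(s, zero) for r in REGIONS}
        w_star = max(w.values())
        if w_star == 0:
            outside[s], inside[s] = "gamma", "rho"
            continue
        in_start = any(w[r] == w_star for r in START_REGIONS)
        in_end = any(w[r] == w_star for r in END_REGIONS)
        if in_start and in_end:
            outside[s], inside[s] = "delta", "beta"
        elif in_start:
            outside[s], inside[s] = "sig", "tauH"
        else:
            outside[s], inside[s] = "sigH", "tau"
    return SymbolDictionary(k=k, p=p, outside=outside, inside=inside, provenance=provenance)


def build_dictionary(
    ds: Dataset, plasmid: PlasmidSequence, k: int, p: int
) -> SymbolDictionary:
    """Convenience: weight tables + thresholding + symbol assignment."""
    tables = region_weight_tables(ds, plasmid, k, p)
    return assign_symbols(tables, k, p, provenance=f"single:{plasmid.name}")


_AMBIGUOUS = {"outside": "delta", "inside": "beta"}
_INDETERMINATE = {"outside": "gamma", "inside": "rho"}


def _resolve_deterministic(sym1: str, sym2: str, context: str) -> str:
    if sym1 == sym2:
        return sym1
    indet = _INDETERMINATE[context]
    if sym1 == indet:
        return sym2
    if sym2 == indet:
        return sym1
    return _AMBIGUOUS[context]


def merge_union_dictionary(
    d1: SymbolDictionary,
    d2: SymbolDictionary,
    mode: str = "deterministic",
    seed: int | np.random.Generator = 0,
) -> SymbolDictionary:
    """Merge two per-plasmid dictionaries into the union-training-set map.

    Agreeing entries are copied.  Conflicts are resolved either
    deterministically — a determinate symbol beats an indeterminate one
    (gamma/rho), and two determinate symbols collapse to the ambiguity
    symbol of the context (delta outside, beta inside) — or
    stochastically, picking one side's symbol uniformly at random per
    (k-mer, context), reproducibly under the seed.
    """
    if (d1.k, d1.p) != (d2.k, d2.p):
        raise ValueError(
            f"cannot merge dictionaries with (k, p)=({d1.k}, {d1.p}) and "
            f"({d2.k}, {d2.p})"
        )
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown merge mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    outside: dict[str, str] = {}
    inside: dict[str, str] = {}
    for s in sorted(d1.outside):
        for context, out in (("outside", outside), ("inside", inside)):
            s1 = d1.lookup(s, context)
            s2 = d2.lookup(s, context)
            if s1 == s2:
                out[s] = s1
            elif mode == "deterministic":
                out[s] = _resolve_deterministic(s1, s2, context)
            else:
                out[s] = s1 if rng.integers(2) == 0 else s2
    return SymbolDictionary(
        k=d1.k,
        p=d1.p,
        outside=outside,
        inside=inside,
        provenance=f"union:{mode}",
    )


def weight_table_frame(table: RegionWeightTable):
    """Export a thresholded table in the rank/kmers/w/w'/H/h layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rank": [r.rank for r in table.rows],
            "kmers": [",".join(r.kmers) for r in table.rows],
            "weight": [float(r.weight) for r in table.rows],
            "rescaled": [r.rescaled for r in table.rows],
            "entropy": [r.entropy for r in table.rows],
            "avg_entropy": [r.avg_entropy for r in table.rows],
        }
    )
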