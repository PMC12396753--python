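"""Synthetic plasmids and R-loop footprint datasets with planted structure.

The generator emulates the statistical features of single-molecule R-loop
footprint data on a plasmid gene region: footprints cluster in one or two
positional modes, initiation sites are enriched for a small set of planted
"start-favoring" k-mers (standing in for the G-rich initiation signal of
real substrates), termination sites for a disjoint "end-favoring" set, and
footprint lengths are multiples of k with a geometric profile.  DNA
topology is emulated purely through the initiation-position distribution:
higher negative supercoiling shifts the clusters toward the transcription
start, which is how the effect manifests in the footprint data the
grammar trains on.

Planted loci sit on the k-grid anchored at the gene start so that a
footprint running from one start locus to just before an end locus
automatically has a length that is a multiple of k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import Dataset, PlasmidSequence, RLoopRecord, write_bed

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic plasmid + footprint dataset.

    Defaults describe a supercoiled-like condition on a gene region of
    1.6 kb inside a 2 kb plasmid, with ~600 footprints in two positional
    clusters and a mean footprint length of ~300 nt.
    """

    name: str = "synthetic"
    gene_length: int = 1600
    flank: int = 200
    k: int = 4
    # planted sets are chosen with pairwise non-overlapping 3-mer content:
    # k-mers sharing (k-1)-mers would hand the same signal to a smaller-k
    # dictionary and blur tuple-size identifiability
    start_kmers: tuple[str, ...] = ("GCGA", "AGGT")
    end_kmers: tuple[str, ...] = ("CTTC", "TCAC")
    cluster_means: tuple[float, ...] = (0.25, 0.55)  # fraction of gene length
    cluster_weights: tuple[float, ...] = (0.45, 0.55)
    cluster_sd: float = 80.0  # nt
    mean_length: int = 300  # nt, geometric in units of k
    n_rloops: int = 600
    planted_per_cluster: int = 8
    planted_span: float = 200.0  # nt around each cluster mean
    purity: float = 0.9  # fraction of footprints snapped to planted loci
    jitter_blocks: int = 3  # boundary imprecision, +/- blocks of k nt
    gc_skew: float = 0.0  # excess G+C probability on the background
    topology: str = "supercoiled"
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.start_kmers) & set(self.end_kmers):
            raise ValueError("planted start and end k-mer sets must be disjoint")
        for s in self.start_kmers + self.end_kmers:
            if len(s) != self.k:
                raise ValueError(f"planted k-mer {s} has length != k={self.k}")
        if self.gene_length <= 3 * self.k:
            raise ValueError("gene region too short")
        if not 0 <= self.purity <= 1:
            raise ValueError("purity must lie in [0, 1]")


#: leftward shift of the initiation clusters per topology (fraction of gene)
TOPOLOGY_SHIFT = {"linear": 0.0, "supercoiled": -0.05, "hyper_negative": -0.15}


def spec_for_topology(topology: str, **overrides) -> SyntheticSpec:
    """A spec whose cluster positions emulate the given starting topology."""
    base = SyntheticSpec(topology=topology, **overrides)
    shift = TOPOLOGY_SHIFT[topology]
    means = tuple(max(0.08, m + shift) for m in base.cluster_means)
    return replace(base, cluster_means=means)


def _grid_positions(spec: SyntheticSpec, b: int, e: int) -> np.ndarray:
    """k-grid candidate loci (1-based) leaving a one-block margin."""
    return np.arange(b + spec.k, e - 2 * spec.k + 1, spec.k)


def generate_plasmid(spec: SyntheticSpec) -> PlasmidSequence:
    """Random background sequence with planted start/end k-mers.

    Start k-mers are planted on the k-grid around each initiation-cluster
    mean; end k-mers are planted downstream, displaced by the mean
    footprint length.  Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    total = spec.gene_length + 2 * spec.flank
    b, e = spec.flank + 1, spec.flank + spec.gene_length
    probs = np.array([
        0.25 - spec.gc_skew / 2, 0.25 + spec.gc_skew / 2,
        0.25 + spec.gc_skew / 2, 0.25 - spec.gc_skew / 2,
    ])
    seq = rng.choice(BASES, size=total, p=probs)
    grid = _grid_positions(spec, b, e)
    occupied: set[int] = set()

    def plant(kmers: Sequence[str], center: float, count: int) -> None:
        if not kmers:
            return
        near = grid[np.abs(grid - center) <= spec.planted_span]
        if near.size == 0:
            raise ValueError("planted k-mers fall outside the gene region")
        chosen = rng.choice(near, size=min(count, near.size), replace=False)
        for c, pos in enumerate(np.sort(chosen)):
            if pos in occupied:
                continue
            occupied.add(int(pos))
            kmer = kmers[c % len(kmers)]
            seq[pos - 1 : pos - 1 + spec.k] = list(kmer)

    for m in spec.cluster_means:
        center = b + m * spec.gene_length
        plant(spec.start_kmers, center, spec.planted_per_cluster)
        plant(spec.end_kmers, center + spec.mean_length, spec.planted_per_cluster)
    return PlasmidSequence(name=spec.name, seq="".join(seq), gene_region=(b, e))


def _planted_loci(spec: SyntheticSpec, plasmid: PlasmidSequence, kmers: Sequence[str]) -> np.ndarray:
    """Grid positions at which one of the given k-mers actually occurs."""
    grid = _grid_positions(spec, *plasmid.gene_region)
    hits = [
        pos for pos in grid if plasmid.kmer_at(int(pos), spec.k) in set(kmers)
    ]
    return np.array(hits, dtype=int)


def generate_rloops(
    spec: SyntheticSpec,
    plasmid: PlasmidSequence,
    bed_path: str | Path | None = None,
) -> Dataset:
    """Sample footprints whose starts/ends are enriched at planted loci.

    Each footprint draws an initiation position from the cluster mixture;
    with probability ``purity`` it snaps to the nearest grid locus
    carrying a planted start k-mer, and its termination snaps to the
    nearest planted end locus near the sampled length, so that regions
    r2 (first k-mer inside) and r4 (first k-mer after the end) are
    enriched for the planted sets.  The remainder are background
    footprints on the k-grid.  All records satisfy the candidate
    constraints (one free k-block on each side of the gene region).
    """
    rng = np.random.default_rng(spec.seed + 1)
    b, e = plasmid.gene_region
    k = spec.k
    grid = _grid_positions(spec, b, e)
    start_loci = _planted_loci(spec, plasmid, spec.start_kmers)
    end_loci = _planted_loci(spec, plasmid, spec.end_kmers)
    means = np.array([b + m * spec.gene_length for m in spec.cluster_means])
    weights = np.array(spec.cluster_weights, dtype=float)
    weights /= weights.sum()
    mean_blocks = max(2, round(spec.mean_length / k))

    records: list[RLoopRecord] = []
    while len(records) < spec.n_rloops:
        comp = rng.choice(len(means), p=weights)
        raw_i = rng.normal(means[comp], spec.cluster_sd)
        n_blocks = 1 + rng.geometric(1.0 / (mean_blocks - 1))
        planted = rng.random() < spec.purity
        if planted and start_loci.size:
            i = int(start_loci[np.argmin(np.abs(start_loci - raw_i))])
        else:
            i = int(grid[np.argmin(np.abs(grid - raw_i))])
        target_end = i + n_blocks * k  # position just after the footprint
        if planted and end_loci.size:
            ahead = end_loci[end_loci >= i + 2 * k]
            if ahead.size:
                target_end = int(ahead[np.argmin(np.abs(ahead - target_end))])
        j = target_end - 1
        # footprint-boundary imprecision: observed ends wander around the
        # true ones in units of whole blocks (the sliding-window padding is
        # designed to absorb exactly this)
        if spec.jitter_blocks > 0:
            i += k * int(rng.integers(-spec.jitter_blocks, spec.jitter_blocks + 1))
            j += k * int(rng.integers(-spec.jitter_blocks, spec.jitter_blocks + 1))
            i = max(i, b + k)
        j = min(j, e - k)
        j = i - 1 + ((j - i + 1) // k) * k
        if j - i + 1 < 2 * k:
            j = i - 1 + 2 * k
        if j > e - k:
            continue
        records.append(RLoopRecord(plasmid.name, spec.topology, i, j))
    ds = Dataset(records, plasmid.name, spec.topology, provenance=f"synthetic:seed={spec.seed}")
    if bed_path is not None:
        write_bed(ds, bed_path)
    return ds


def generate_sample(spec: SyntheticSpec) -> tuple[PlasmidSequence, Dataset]:
    """Plasmid plus matching footprint dataset for one spec."""
    plasmid = generate_plasmid(spec)
    return plasmid, generate_rloops(spec, plasmid)
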