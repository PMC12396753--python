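"""Plasmid sequences and single-molecule R-loop interval data.

Coordinates are 1-based inclusive throughout the library: an R-loop
occupying nucleotides ``i`` through ``j`` of the non-template strand is the
interval ``[i, j]`` with ``j > i``.  BED input/output uses the standard
0-based half-open convention and is converted on the boundary.

All sequence analysis runs on the non-template strand read 5'->3' (the
strand displaced inside an R-loop, identical in sequence to the
transcript).  Plasmid FASTA files that store the template strand are
reverse-complemented on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

TOPOLOGIES = ("linear", "supercoiled", "hyper_negative")


@dataclass(frozen=True)
class PlasmidSequence:
    """A plasmid on the non-template strand with a designated gene region.

    Parameters
    ----------
    name
        Identifier (must match the chrom column of associated BED records).
    seq
        Nucleotide string over {A, C, G, T}, non-template strand 5'->3'.
    gene_region
        Inclusive 1-based interval ``(b, e)`` delimiting the transcribed
        region on which all k-mer analysis operates.
    """

    name: str
    seq: str
    gene_region: tuple[int, int]

    def __post_init__(self) -> None:
        b, e = self.gene_region
        if not (1 <= b < e <= len(self.seq)):
            raise ValueError(
                f"gene region [{b}, {e}] outside sequence of length {len(self.seq)}"
            )
        for pos, base in enumerate(self.seq, start=1):
            if base not in VALID_BASES:
                raise ValueError(
                    f"invalid base {base!r} at position {pos} of {self.name}: "
                    "only A/C/G/T are accepted"
                )

    @property
    def b(self) -> int:
        return self.gene_region[0]

    @property
    def e(self) -> int:
        return self.gene_region[1]

    @property
    def gene_length(self) -> int:
        return self.e - self.b + 1

    def gene_seq(self) -> str:
        """Sequence of the gene region (1-based inclusive slice)."""
        return self.seq[self.b - 1 : self.e]

    def kmer_at(self, start: int, k: int) -> str:
        """k-mer whose first nucleotide sits at 1-based position ``start``."""
        return self.seq[start - 1 : start - 1 + k]


@dataclass(frozen=True)
class RLoopRecord:
    """One single-molecule R-loop footprint, 1-based inclusive [i, j]."""

    plasmid: str
    topology: str
    i: int
    j: int
    read_id: str | None = None

    def __post_init__(self) -> None:
        if self.j <= self.i:
            raise ValueError(f"require j > i, got [{self.i}, {self.j}]")

    @property
    def length(self) -> int:
        return self.j - self.i + 1


@dataclass
class Dataset:
    """A collection of R-loop records sharing a plasmid and topology."""

    records: list[RLoopRecord]
    plasmid: str
    topology: str
    provenance: str = "raw"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def intervals(self) -> list[tuple[int, int]]:
        return [(r.i, r.j) for r in self.records]


def read_fasta(
    path: str | Path,
    gene_region: tuple[int, int],
    strand_mode: str = "non_template",
    record_name: str | None = None,
) -> PlasmidSequence:
    """Load a plasmid sequence from FASTA.

    ``strand_mode="template"`` reverse-complements the stored sequence so
    that the returned object is always the non-template strand 5'->3'.
    ``gene_region`` is given in coordinates of the returned (non-template)
    orientation.
    """
    if strand_mode not in ("non_template", "template"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_name is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_name]
        if not matches:
            raise ValueError(f"record {record_name!r} not found in {path}")
        rec = matches[0]
    seq = str(rec.seq).upper()
    if strand_mode == "template":
        seq = str(Seq(seq).reverse_complement())
    return PlasmidSequence(name=rec.id, seq=seq, gene_region=gene_region)


def write_fasta(plasmid: PlasmidSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{plasmid.name}\n")
        for off in range(0, len(plasmid.seq), width):
            fh.write(plasmid.seq[off : off + width] + "\n")


def read_bed(
    path: str | Path,
    plasmid: PlasmidSequence,
    topology: str,
) -> Dataset:
    """Read R-loop intervals from a BED file (>= 3 columns).

    BED's 0-based half-open ``[start, end)`` becomes the internal 1-based
    inclusive ``[start + 1, end]``.  An optional 4th column is kept as a
    read identifier (several intervals may share one read).  Records
    partially outside the gene region are clipped to it; empty or
    reversed intervals are rejected with a logged reason.
    """
    records: list[RLoopRecord] = []
    b, e = plasmid.gene_region
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = cols[0], cols[1], cols[2]
            if chrom != plasmid.name:
                raise ValueError(
                    f"{path}:{lineno}: chrom {chrom!r} does not match plasmid "
                    f"{plasmid.name!r}"
                )
            start, end = int(start_s), int(end_s)
            if start >= end:
                logger.warning(
                    "%s:%d: rejected interval with start >= end (%d >= %d)",
                    path, lineno, start, end,
                )
                continue
            i, j = start + 1, end
            if i < b or j > e:
                ci, cj = max(i, b), min(j, e)
                if cj <= ci:
                    logger.warning(
                        "%s:%d: rejected interval [%d, %d] outside gene region",
                        path, lineno, i, j,
                    )
                    continue
                logger.warning(
                    "%s:%d: clipped interval [%d, %d] to gene region [%d, %d]",
                    path, lineno, i, j, ci, cj,
                )
                i, j = ci, cj
            read_id = cols[3] if len(cols) > 3 else None
            records.append(
                RLoopRecord(plasmid.name, topology, i, j, read_id=read_id)
            )
    return Dataset(records, plasmid.name, topology, provenance="raw")


def write_bed(ds: Dataset, path: str | Path) -> None:
    """Write records as BED (0-based half-open), inverse of :func:`read_bed`."""
    with open(path, "w") as fh:
        for rec in ds.records:
            cols = [rec.plasmid, str(rec.i - 1), str(rec.j)]
            if rec.read_id is not None:
                cols.append(rec.read_id)
            fh.write("\t".join(cols) + "\n")


def split_multi_rloop_reads(raw: Dataset) -> Dataset:
    """Treat every footprint interval as an independent molecule.

    A small fraction of single-molecule reads carry more than one R-loop;
    the single-loop grammar handles them by promoting each interval to its
    own record (the shared read identifier is dropped).
    """
    records = [replace(rec, read_id=None) for rec in raw.records]
    return Dataset(records, raw.plasmid, raw.topology, provenance="split")


def adjust_length_to_multiple_of_k(
    rec: RLoopRecord, k: int, gene_region: tuple[int, int]
) -> RLoopRecord | None:
    """Round an R-loop's length to the nearest multiple of k.

    The termination index ``j`` moves so that ``j - i + 1`` becomes
    ``k * round(length / k)`` with ties rounded up; a length that would
    round to zero is promoted to ``k``.  The new ``j`` is clipped to the
    gene-region end ``e`` and, if clipping breaks divisibility, reduced to
    the largest valid position.  Returns None (with a logged reason) when
    no valid adjustment exists.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    b, e = gene_region
    length = rec.length
    n_blocks = (2 * length + k) // (2 * k)  # round half up
    if n_blocks == 0:
        n_blocks = 1
    new_j = rec.i - 1 + n_blocks * k
    if new_j > e:
        # largest multiple of k that fits inside the gene region
        n_fit = (e - rec.i + 1) // k
        if n_fit < 1:
            logger.warning(
                "rejected record [%d, %d]: no room for a length-%d block", rec.i, rec.j, k
            )
            return None
        new_j = rec.i - 1 + n_fit * k
    if new_j <= rec.i:
        logger.warning("rejected record [%d, %d]: adjusted length too short", rec.i, rec.j)
        return None
    return replace(rec, j=new_j)


def preprocess(ds: Dataset, plasmid: PlasmidSequence, k: int) -> Dataset:
    """Full pre-processing: split multi-loop reads, round lengths to k."""
    split = split_multi_rloop_reads(ds)
    out: list[RLoopRecord] = []
    for rec in split.records:
        adj = adjust_length_to_multiple_of_k(rec, k, plasmid.gene_region)
        if adj is not None:
            out.append(adj)
    return Dataset(out, ds.plasmid, ds.topology, provenance="preprocessed")


def split_train_holdout(
    ds: Dataset, holdout_frac: float = 1 / 3, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Randomly reserve a fraction of records as a holdout set.

    Returns ``(training, holdout)``; holdout size is ``round(frac * n)``.
    Deterministic under a fixed seed.
    """
    if not 0 < holdout_frac < 1:
        raise ValueError("holdout_frac must lie in (0, 1)")
    n = len(ds.records)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    n_holdout = int(round(holdout_frac * n))
    n_holdout = min(max(n_holdout, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    hold_idx = set(order[:n_holdout].tolist())
    train = [ds.records[t] for t in range(n) if t not in hold_idx]
    hold = [ds.records[t] for t in range(n) if t in hold_idx]
    return (
        Dataset(train, ds.plasmid, ds.topology, provenance="train"),
        Dataset(hold, ds.plasmid, ds.topology, provenance="holdout"),
    )


def subsample(ds: Dataset, frac: float, rng: np.random.Generator) -> Dataset:
    """Draw a fraction of records without replacement (at least one)."""
    n = len(ds.records)
    m = max(1, int(round(frac * n)))
    idx = rng.choice(n, size=m, replace=False)
    recs = [ds.records[t] for t in sorted(idx.tolist())]
    return Dataset(recs, ds.plasmid, ds.topology, provenance="subsample")
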