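"""Splice-junction (intron) extraction from spliced alignments and grouping into bunches.

An *intron* is the genomic gap skipped between two exonic alignment blocks,
evidenced by an ``N`` operation in a read's CIGAR string. Introns are stored
1-based inclusive over the intronic bases: ``start`` is the first skipped base
and ``end`` the last skipped base. A *bunch* is a maximal connected group of
introns sharing a splice-site coordinate (start or end) on the same chromosome;
it is the unit within which splicing ratios compete.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

# CIGAR operation codes that consume the reference
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X
_MATCH_OPS = {0, 7, 8}  # M, =, X


@dataclass(frozen=True)
class Intron:
    """A splice junction: 1-based inclusive interval over the skipped bases."""

    chrom: str
    start: int
    end: int
    strand: str = "?"  # '+', '-', or '?' (unknown)
    counts: tuple = ()  # per-sample read counts; empty until samples merged

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"intron start {self.start} > end {self.end}")

    @property
    def key(self):
        return (self.chrom, self.start, self.end, self.strand)

    def __str__(self):
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass
class Bunch:
    """A connected component of introns sharing splice-site coordinates."""

    id: str
    introns: list = field(default_factory=list)
    anchor: str = ""

    @property
    def size(self) -> int:
        return len(self.introns)


@dataclass
class CountMatrix:
    """Feature-by-sample junction read counts backed by a DataFrame.

    Rows are indexed by intron key tuples ``(chrom, start, end, strand)``;
    columns are sample ids; entries are non-negative integers.
    """

    data: pd.DataFrame

    def __post_init__(self):
        if (self.data.values < 0).any():
            raise ValueError("count matrix contains negative entries")

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def features(self) -> list:
        return list(self.data.index)

    def counts_for(self, key) -> np.ndarray:
        return self.data.loc[[key]].to_numpy()[0].astype(np.int64)


def _read_strand(read) -> str:
    try:
        xs = read.get_tag("XS")
        if xs in ("+", "-"):
            return xs
    except KeyError:
        pass
    return "?"


def extract_junctions(
    alignment_file: str,
    min_anchor: int = 8,
    min_count: int = 1,
) -> list:
    """Extract introns from a SAM/BAM file by scanning CIGAR ``N`` operations.

    A read supports a junction only if both flanking aligned segments
    (the exonic anchors, counted in matched bases adjacent to the gap)
    are at least ``min_anchor`` long. Junctions with total read count
    below ``min_count`` are dropped.

    Returns a list of :class:`Intron` sorted by coordinate, each with a
    single-element ``counts`` tuple holding the read count in this file.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    counts: dict = {}
    n_skipped = 0
    with pysam.AlignmentFile(alignment_file, "r") as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            if read.cigartuples is None:
                n_skipped += 1
                continue
            strand = _read_strand(read)
            # walk the CIGAR, tracking the reference position (0-based)
            ref = read.reference_start
            cig = read.cigartuples
            for i, (op, length) in enumerate(cig):
                if op == 3:  # N: skipped region
                    left = _anchor_len(cig, i, step=-1)
                    right = _anchor_len(cig, i, step=+1)
                    if left >= min_anchor and right >= min_anchor:
                        # ref is 0-based first skipped base -> 1-based start
                        start = ref + 1
                        end = ref + length
                        key = (read.reference_name, start, end, strand)
                        counts[key] = counts.get(key, 0) + 1
                if op in _REF_CONSUMING:
                    ref += length
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} records without CIGAR strings")
    introns = [
        Intron(chrom=c, start=s, end=e, strand=st, counts=(n,))
        for (c, s, e, st), n in counts.items()
        if n >= min_count
    ]
    introns.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))
    return introns


def _anchor_len(cig, i, step) -> int:
    """Matched bases in the exonic block adjacent to the gap at CIGAR index i."""
    total = 0
    j = i + step
    while 0 <= j < len(cig):
        op, length = cig[j]
        if op == 3:  # next gap ends the block
            break
        if op in _MATCH_OPS:
            total += length
        elif op == 2:  # deletion: part of the block but not a matched anchor base
            pass
        else:  # I, S, H, P do not consume reference; stop at clips
            if op in (4, 5):
                break
        j += step
    return total


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _strand_compatible(a: str, b: str) -> bool:
    return a == "?" or b == "?" or a == b


def build_bunches(introns: list) -> list:
    """Group introns into bunches: connected components of the shared-site graph.

    Two introns are linked when they lie on the same chromosome with
    compatible strands and share a start or an end coordinate. Connectivity
    is transitive, so a bunch may contain introns with no direct shared site.
    """
    uf = _UnionFind(len(introns))
    # index introns by (chrom, coordinate) for both endpoints
    by_site: dict = {}
    for idx, iv in enumerate(introns):
        for coord in (("s", iv.start), ("e", iv.end)):
            by_site.setdefault((iv.chrom, coord), []).append(idx)
    for members in by_site.values():
        # site groups are tiny; link every strand-compatible pair
        for ai, a in enumerate(members):
            for b in members[ai + 1:]:
                if _strand_compatible(introns[a].strand, introns[b].strand):
                    uf.union(a, b)
    groups: dict = {}
    for idx in range(len(introns)):
        groups.setdefault(uf.find(idx), []).append(idx)
    bunches = []
    for root in sorted(groups, key=lambda r: (introns[r].chrom, introns[r].start)):
        members = sorted(
            (introns[i] for i in groups[root]),
            key=lambda iv: (iv.start, iv.end, iv.strand),
        )
        chrom = members[0].chrom
        # shared splice sites: coordinates used by more than one intron
        site_use: dict = {}
        for iv in members:
            for c in (iv.start, iv.end):
                site_use[c] = site_use.get(c, 0) + 1
        anchor_sites = sorted(c for c, n in site_use.items() if n > 1)
        bid = f"{chrom}:{members[0].start}-{max(iv.end for iv in members)}"
        bunches.append(
            Bunch(id=bid, introns=members, anchor=",".join(map(str, anchor_sites)))
        )
    return bunches


def merge_samples(per_sample_junctions: list) -> CountMatrix:
    """Merge per-sample junction lists into one feature-by-sample count matrix.

    ``per_sample_junctions`` is a list of ``(sample_id, [Intron, ...])`` pairs.
    The feature set is the union of intron coordinates across samples; a
    missing sample/intron combination gets count 0.
    """
    sample_ids = [sid for sid, _ in per_sample_junctions]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    table: dict = {}
    for j, (sid, introns) in enumerate(per_sample_junctions):
        for iv in introns:
            row = table.setdefault(iv.key, np.zeros(len(sample_ids), dtype=np.int64))
            row[j] += int(sum(iv.counts)) if iv.counts else 0
    keys = sorted(table)
    df = pd.DataFrame(
        np.vstack([table[k] for k in keys]) if keys else np.zeros((0, len(sample_ids)), dtype=np.int64),
        index=pd.Index(keys if keys else [], tupleize_cols=False),
        columns=sample_ids,
    )
    return CountMatrix(df)


def introns_from_matrix(matrix: CountMatrix) -> list:
    """Materialize Intron objects (with full per-sample counts) from a matrix."""
    out = []
    for key in matrix.features:
        chrom, start, end, strand = key
        out.append(
            Intron(chrom=chrom, start=start, end=end, strand=strand,
                   counts=tuple(int(v) for v in matrix.data.loc[[key]].to_numpy()[0]))
        )
    return out


# ---------------------------------------------------------------------------
# plain-text I/O

def write_junction_tsv(introns: list, path: str) -> None:
    """One sample: chrom, start, end, strand, count."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tcount\n")
        for iv in introns:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{sum(iv.counts)}\n")


def read_junction_tsv(path: str) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    return [
        Intron(chrom=r.chrom, start=int(r.start), end=int(r.end),
               strand=str(r.strand), counts=(int(r.count),))
        for r in df.itertuples()
    ]


def write_count_matrix(matrix: CountMatrix, path: str) -> None:
    """Merged counts: chrom, start, end, strand, then one column per sample."""
    rows = []
    for key in matrix.features:
        chrom, start, end, strand = key
        rows.append([chrom, start, end, strand] + list(matrix.data.loc[[key]].to_numpy()[0]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"] + matrix.samples)
    df.to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    samples = [c for c in df.columns if c not in ("chrom", "start", "end", "strand")]
    keys = [
        (r.chrom, int(r.start), int(r.end), str(r.strand)) for r in df.itertuples()
    ]
    mat = pd.DataFrame(
        df[samples].to_numpy(dtype=np.int64),
        index=pd.Index(keys, tupleize_cols=False),
        columns=samples,
    )
    return CountMatrix(mat)
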