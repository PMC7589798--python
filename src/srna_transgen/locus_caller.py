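"""Small-RNA locus identification from pooled mapped reads.

Loci are coverage islands: reads from all libraries are pooled, and two
reads belong to the same locus whenever the gap between them (next start
minus previous end) is at most ``pad``, transitively.  Islands whose total
read weight falls below ``min_reads`` are dropped.  Per-sample counts and
the read-length profile of every locus are computed against the fixed
pooled locus set, mirroring a single locus definition shared by all
libraries in a study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GenomicInterval, ReadAlignment, READ_LENGTH_MIN, READ_LENGTH_MAX

DEFAULT_PAD = 75
DEFAULT_MIN_READS = 5.0


@dataclass
class ReadLengthProfile:
    """Summed read weight per read length (15–35 nt) for one locus."""

    counts_by_length: dict[int, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.counts_by_length.values()))

    def add(self, length: int, weight: float = 1.0) -> None:
        if not (READ_LENGTH_MIN <= length <= READ_LENGTH_MAX):
            raise ValueError(f"read length {length} outside [15, 35]")
        if weight < 0:
            raise ValueError("weight must be non-negative")
        self.counts_by_length[length] = self.counts_by_length.get(length, 0.0) + weight

    @classmethod
    def from_reads(cls, reads: Iterable[ReadAlignment]) -> "ReadLengthProfile":
        prof = cls()
        for r in reads:
            prof.add(r.length, r.weight)
        return prof


@dataclass
class SRNALocus:
    """A called sRNA locus with its length profile and per-sample counts."""

    id: str
    interval: GenomicInterval
    profile: ReadLengthProfile
    counts: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.interval.length


def profile_locus(reads: Iterable[ReadAlignment]) -> ReadLengthProfile:
    """Sum member read weights by read length (end − start)."""
    return ReadLengthProfile.from_reads(reads)


def rpm(count: float, library_size: float) -> float:
    """Reads per million mapped reads for one sample."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / library_size * 1e6


def mean_rpm(counts: Mapping[str, float], library_sizes: Mapping[str, float]) -> float:
    """Mean RPM of a locus across samples (the abundance-filter statistic)."""
    vals = [rpm(counts.get(s, 0.0), library_sizes[s]) for s in library_sizes]
    return float(np.mean(vals)) if vals else 0.0


def call_loci(
    reads: Sequence[ReadAlignment],
    pad: int = DEFAULT_PAD,
    min_reads: float = DEFAULT_MIN_READS,
) -> list[SRNALocus]:
    """Merge pooled reads into gap-separated loci and profile each one.

    Parameters
    ----------
    reads
        Alignments from all samples, in any order.
    pad
        Maximum gap (bp) between consecutive reads of one locus.
    min_reads
        Minimum total read weight for a locus to be retained.

    Returns
    -------
    Loci sorted by (chrom, start), ids ``chrom:start-end``.  Empty input
    yields an empty list.
    """
    if pad < 0:
        raise ValueError("pad must be non-negative")
    if min_reads <= 0:
        raise ValueError("min_reads must be positive")

    by_chrom: dict[str, list[ReadAlignment]] = {}
    for r in reads:
        by_chrom.setdefault(r.interval.chrom, []).append(r)

    loci: list[SRNALocus] = []
    for chrom in sorted(by_chrom):
        chrom_reads = sorted(by_chrom[chrom], key=lambda r: (r.interval.start, r.interval.end))
        cluster: list[ReadAlignment] = []
        cluster_end = -1
        for r in chrom_reads:
            if cluster and r.interval.start - cluster_end > pad:
                loci.extend(_finish_cluster(chrom, cluster, min_reads))
                cluster = []
            cluster.append(r)
            cluster_end = max(cluster_end, r.interval.end)
        if cluster:
            loci.extend(_finish_cluster(chrom, cluster, min_reads))
    return loci


def _finish_cluster(
    chrom: str, members: list[ReadAlignment], min_reads: float
) -> list[SRNALocus]:
    total = sum(r.weight for r in members)
    if total < min_reads:
        return []
    start = min(r.interval.start for r in members)
    end = max(r.interval.end for r in members)
    counts: dict[str, float] = {}
    for r in members:
        counts[r.sample_id] = counts.get(r.sample_id, 0.0) + r.weight
    locus = SRNALocus(
        id=f"{chrom}:{start}-{end}",
        interval=GenomicInterval(chrom, start, end),
        profile=profile_locus(members),
        counts=counts,
    )
    return [locus]
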