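"""Readers, writers and genomic containers for the sRNA pipeline.

Every coordinate held in memory is 0-based and half-open.  GFF3 (1-based,
end-inclusive) is converted at the file boundary and nowhere else; BED and
the tabular DMR dialect used here are already 0-based half-open and pass
through unchanged.  Strand is carried on every interval but deliberately
ignored by overlap and distance computations; only tRNA-fragment side
classification consults it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")
FEATURE_KINDS = ("gene", "CDS", "TE", "tRNA")

#: global bounds on small-RNA read length (nt); alignments outside are rejected
READ_LENGTH_MIN = 15
READ_LENGTH_MAX = 35


class CoordinateError(ValueError):
    """An interval violates the 0-based half-open convention."""


class GFF3ParseError(ValueError):
    """A GFF3 line could not be parsed; message carries the line number."""


class ValidationError(ValueError):
    """A record violates a dataset-level invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, with a 3-symbol strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise CoordinateError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise CoordinateError(
                f"end must exceed start: [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int | None:
        """Edge-to-edge gap in bp; 0 when overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(other.start - self.end, self.start - other.end, 0)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GenomicFeature:
    """An annotated feature: gene, CDS, transposable element or tRNA gene.

    tRNA features must carry ``anticodon`` (e.g. ``"CAA"``), ``amino_acid``
    (e.g. ``"Leu"``) and ``anticodon_interval`` (a :class:`GenomicInterval`
    strictly inside the tRNA) in ``attrs``.
    """

    interval: GenomicInterval
    kind: str
    id: str
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}: {self.kind!r}")
        if self.kind == "tRNA":
            ac = self.attrs.get("anticodon_interval")
            if not isinstance(ac, GenomicInterval):
                raise ValidationError(
                    f"tRNA {self.id!r} lacks an anticodon_interval"
                )
            if not (
                ac.chrom == self.interval.chrom
                and self.interval.start < ac.start
                and ac.end < self.interval.end
            ):
                raise ValidationError(
                    f"tRNA {self.id!r}: anticodon must lie strictly inside the gene"
                )


@dataclass(frozen=True)
class DMRRecord:
    """A region differentially methylated in progeny of wounded plants."""

    interval: GenomicInterval
    direction: str  # methylation change: "up" or "down"
    context: str = "any"  # CG / CHG / CHH / any

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError(f"DMR direction must be up/down: {self.direction!r}")
        if self.context not in ("CG", "CHG", "CHH", "any"):
            raise ValidationError(f"bad methylation context: {self.context!r}")


@dataclass(frozen=True)
class DEGRecord:
    """A gene scored for differential expression in progeny of wounded plants."""

    gene_id: str
    direction: str  # "up", "down" or "none" (not differentially expressed)
    mean_expression: float  # control-condition mean, arbitrary units

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "none"):
            raise ValidationError(f"DEG direction must be up/down/none: {self.direction!r}")
        if self.mean_expression < 0:
            raise ValidationError("mean_expression must be non-negative")


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped small-RNA read; weight < 1 supports pre-resolved multi-mappers."""

    interval: GenomicInterval
    sample_id: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValidationError("read weight must be positive")
        n = self.interval.length
        if not (READ_LENGTH_MIN <= n <= READ_LENGTH_MAX):
            raise ValidationError(
                f"read length {n} outside [{READ_LENGTH_MIN}, {READ_LENGTH_MAX}]"
            )

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class SampleMeta:
    """Library-level metadata for one sequenced sample."""

    sample_id: str
    generation: str  # parent / offspring
    treatment: str  # wounded / control
    timepoint: str | None = None  # 1h / 72h, parent generation only
    leaf_pair: str = "second"  # second / third
    maternal_line: str | None = None  # offspring generation only
    library_size: int | None = None  # mapped reads; column sums if absent

    def __post_init__(self) -> None:
        if self.generation not in ("parent", "offspring"):
            raise ValidationError(f"generation must be parent/offspring: {self.generation!r}")
        if self.treatment not in ("wounded", "control"):
            raise ValidationError(f"treatment must be wounded/control: {self.treatment!r}")
        if self.leaf_pair not in ("second", "third"):
            raise ValidationError(f"leaf_pair must be second/third: {self.leaf_pair!r}")
        if self.generation == "offspring" and not self.maternal_line:
            raise ValidationError(f"offspring sample {self.sample_id} lacks maternal_line")
        if self.generation == "parent" and self.timepoint not in ("1h", "72h"):
            raise ValidationError(f"parent sample {self.sample_id} lacks a timepoint")
        if self.library_size is not None and self.library_size <= 0:
            raise ValidationError("library_size must be positive")


class FeatureSet:
    """Genes/CDS/TEs/tRNAs plus DMR and DEG tables, indexed for interval queries.

    Overlap queries run on per-kind interval trees; nearest-feature queries
    use sorted coordinate arrays.  Both are checked against brute-force
    all-pairs scans in the test suite.
    """

    def __init__(
        self,
        features: Iterable[GenomicFeature],
        dmrs: Iterable[DMRRecord] = (),
        degs: Iterable[DEGRecord] = (),
    ) -> None:
        self.features: list[GenomicFeature] = list(features)
        self.dmrs: list[DMRRecord] = list(dmrs)
        self.degs: list[DEGRecord] = list(degs)

        seen: set[str] = set()
        for f in self.features:
            if f.id in seen:
                raise ValidationError(f"duplicate feature id {f.id!r}")
            seen.add(f.id)

        gene_ids = {f.id for f in self.features if f.kind == "gene"}
        for d in self.degs:
            if d.gene_id not in gene_ids:
                raise ValidationError(f"DEG gene_id {d.gene_id!r} not in gene set")

        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for f in self.features:
            key = (f.kind, f.interval.chrom)
            self._trees.setdefault(key, IntervalTree()).addi(
                f.interval.start, f.interval.end, f
            )
        self._coords: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list]] = {}

    def of_kind(self, kind: str) -> list[GenomicFeature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def genes(self) -> list[GenomicFeature]:
        return self.of_kind("gene")

    @property
    def trnas(self) -> list[GenomicFeature]:
        return self.of_kind("tRNA")

    def overlapping(
        self, interval: GenomicInterval, kinds: Sequence[str] | None = None
    ) -> list[GenomicFeature]:
        """All features of the requested kinds sharing ≥1 base with `interval`."""
        kinds = FEATURE_KINDS if kinds is None else kinds
        hits: list[GenomicFeature] = []
        for kind in kinds:
            tree = self._trees.get((kind, interval.chrom))
            if tree is not None:
                hits.extend(iv.data for iv in tree.overlap(interval.start, interval.end))
        return hits

    def _kind_coords(self, kind: str, chrom: str):
        key = (kind, chrom)
        if key not in self._coords:
            feats = [
                f for f in self.features if f.kind == kind and f.interval.chrom == chrom
            ]
            starts = np.array([f.interval.start for f in feats], dtype=np.int64)
            ends = np.array([f.interval.end for f in feats], dtype=np.int64)
            self._coords[key] = (starts, ends, feats)
        return self._coords[key]

    def nearest(
        self, interval: GenomicInterval, kind: str = "gene"
    ) -> tuple[GenomicFeature | None, int | None]:
        """Nearest feature of `kind` by edge-to-edge gap (0 when overlapping)."""
        starts, ends, feats = self._kind_coords(kind, interval.chrom)
        if len(feats) == 0:
            return None, None
        gaps = np.maximum(
            np.maximum(starts - interval.end, interval.start - ends), 0
        )
        i = int(np.argmin(gaps))
        return feats[i], int(gaps[i])


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF3_TYPE_TO_KIND = {
    "gene": "gene",
    "CDS": "CDS",
    "transposable_element": "TE",
    "tRNA": "tRNA",
}
_KIND_TO_GFF3_TYPE = {v: k for k, v in _GFF3_TYPE_TO_KIND.items()}
# tRNA anticodon bookkeeping keys; ac_start/ac_end are written 1-based inclusive
_RESERVED_ATTRS = {"ID", "Parent", "anticodon", "amino_acid", "ac_start", "ac_end"}


def _parse_gff3_attrs(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"bad attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> FeatureSet:
    """Read genes/CDS/TEs/tRNAs from GFF3 into a :class:`FeatureSet`.

    1-based inclusive coordinates become 0-based half-open.  tRNA anticodons
    may be encoded either as ``anticodon=XXX;ac_start=..;ac_end=..``
    attributes or as a child feature of type ``anticodon``.  Feature types
    outside the recognised set are skipped.
    """
    features: list[GenomicFeature] = []
    pending_trnas: list[tuple[GenomicInterval, str, dict]] = []
    anticodon_children: list[tuple[str, GenomicInterval, dict]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GFF3ParseError(f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise CoordinateError(f"line {lineno}: end {end1} < start {start1}")
            if strand not in STRANDS:
                raise GFF3ParseError(f"line {lineno}: bad strand {strand!r}")
            try:
                attrs = _parse_gff3_attrs(attr_s)
            except ValueError as exc:
                raise GFF3ParseError(f"line {lineno}: {exc}") from exc
            interval = GenomicInterval(chrom, start1 - 1, end1, strand)
            if ftype == "anticodon":
                if "Parent" not in attrs:
                    raise GFF3ParseError(f"line {lineno}: anticodon without Parent")
                anticodon_children.append((attrs["Parent"], interval, attrs))
                continue
            kind = _GFF3_TYPE_TO_KIND.get(ftype)
            if kind is None:
                continue
            fid = attrs.get("ID")
            if fid is None:
                raise GFF3ParseError(f"line {lineno}: feature without ID")
            extra = {k: v for k, v in attrs.items() if k not in ("ID",)}
            if kind == "tRNA" and "ac_start" in attrs and "ac_end" in attrs:
                ac = GenomicInterval(
                    chrom, int(attrs["ac_start"]) - 1, int(attrs["ac_end"]), strand
                )
                extra = {
                    k: v for k, v in extra.items() if k not in ("ac_start", "ac_end")
                }
                extra["anticodon_interval"] = ac
            if kind == "tRNA":
                # construct after anticodon children have been attached
                pending_trnas.append((interval, fid, extra))
            else:
                features.append(GenomicFeature(interval, kind, fid, extra))

    trna_attrs = {fid: attrs for _, fid, attrs in pending_trnas}
    for parent_id, interval, attrs in anticodon_children:
        if parent_id not in trna_attrs:
            raise GFF3ParseError(f"anticodon child references unknown tRNA {parent_id!r}")
        trna_attrs[parent_id]["anticodon_interval"] = interval
        for key in ("anticodon", "amino_acid"):
            if key in attrs:
                trna_attrs[parent_id].setdefault(key, attrs[key])
    for interval, fid, extra in pending_trnas:
        features.append(GenomicFeature(interval, "tRNA", fid, extra))
    return FeatureSet(features)


def write_gff3(path: str | Path, feature_set: FeatureSet) -> None:
    """Write a FeatureSet as canonical GFF3 (anticodons as attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(
            feature_set.features, key=lambda f: (f.interval.chrom, f.interval.start, f.id)
        ):
            attrs = [f"ID={f.id}"]
            if f.kind == "tRNA":
                ac: GenomicInterval = f.attrs["anticodon_interval"]
                attrs.append(f"anticodon={f.attrs.get('anticodon', '')}")
                attrs.append(f"amino_acid={f.attrs.get('amino_acid', '')}")
                attrs.append(f"ac_start={ac.start + 1}")
                attrs.append(f"ac_end={ac.end}")
            for k, v in f.attrs.items():
                if k not in _RESERVED_ATTRS and k != "anticodon_interval":
                    attrs.append(f"{k}={v}")
            if "Parent" in f.attrs:
                attrs.append(f"Parent={f.attrs['Parent']}")
            iv = f.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "srna_transgen",
                        _KIND_TO_GFF3_TYPE[f.kind],
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED reads
# ---------------------------------------------------------------------------


@dataclass
class BedReads:
    """Result of reading a BED6 alignment file: accepted reads + rejects log."""

    reads: list[ReadAlignment]
    n_rejected: int
    rejected_lines: list[int] = field(default_factory=list)


def read_reads_bed(
    path: str | Path, sample_id: str, use_score_as_weight: bool = False
) -> BedReads:
    """Read BED6 small-RNA alignments (0-based half-open, as written).

    Records whose length falls outside [15, 35] are rejected and counted,
    not raised; an empty file yields an empty collection.
    """
    reads: list[ReadAlignment] = []
    rejected: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValidationError(f"{path}: line {lineno}: expected ≥3 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            strand = cols[5] if len(cols) >= 6 and cols[5] in STRANDS else "."
            weight = 1.0
            if use_score_as_weight and len(cols) >= 5 and cols[4] not in (".", ""):
                weight = float(cols[4])
            n = end - start
            if not (READ_LENGTH_MIN <= n <= READ_LENGTH_MAX):
                rejected.append(lineno)
                continue
            reads.append(
                ReadAlignment(GenomicInterval(chrom, start, end, strand), sample_id, weight)
            )
    return BedReads(reads, len(rejected), rejected)


def write_reads_bed(path: str | Path, reads: Iterable[ReadAlignment]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.sample_id}\t{r.weight:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Tabular inputs: counts, metadata, DMRs, DEGs, results
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, samples: Sequence[SampleMeta] | None = None):
    """Read a loci × samples TSV of non-negative integer counts.

    First column is the locus id.  When `samples` is given, the table's
    columns must be a subset-free match of the metadata sample ids and
    library sizes come from the metadata; otherwise they are column sums.
    """
    from .diffabund import CountMatrix  # deferred: avoids an import cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate locus id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
        if bad.any():
            locus = df.index[int(np.argmax(bad.to_numpy()))]
            raise ValidationError(
                f"count for locus {locus!r}, sample {col!r} is not a non-negative integer"
            )
    counts = df.astype(np.int64)
    meta: list[SampleMeta]
    if samples is not None:
        by_id = {s.sample_id: s for s in samples}
        unknown = [c for c in counts.columns if c not in by_id]
        if unknown:
            raise ValidationError(f"unknown sample column {unknown[0]!r}")
        meta = [by_id[c] for c in counts.columns]
    else:
        meta = []
    return CountMatrix(counts=counts, samples=meta)


def write_count_table(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="locus_id")


def write_results(path: str | Path, results: pd.DataFrame) -> None:
    """Write a per-locus contrast result table (locus_id, stratum, baseMean, lfc, p, q)."""
    results.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_dmrs(path: str | Path) -> list[DMRRecord]:
    """Read a DMR TSV: chrom, start, end, direction[, context]; 0-based half-open."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        context = getattr(row, "context", "any")
        out.append(
            DMRRecord(
                GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                str(row.direction),
                str(context),
            )
        )
    return out


def write_dmrs(path: str | Path, dmrs: Iterable[DMRRecord]) -> None:
    rows = [
        {
            "chrom": d.interval.chrom,
            "start": d.interval.start,
            "end": d.interval.end,
            "direction": d.direction,
            "context": d.context,
        }
        for d in dmrs
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "context"]).to_csv(
        path, sep="\t", index=False
    )


def read_degs(path: str | Path) -> list[DEGRecord]:
    """Read a DEG TSV: gene_id, direction (up/down/none), mean_expression."""
    df = pd.read_csv(path, sep="\t")
    return [
        DEGRecord(str(r.gene_id), str(r.direction), float(r.mean_expression))
        for r in df.itertuples(index=False)
    ]


def write_degs(path: str | Path, degs: Iterable[DEGRecord]) -> None:
    rows = [
        {"gene_id": d.gene_id, "direction": d.direction, "mean_expression": d.mean_expression}
        for d in degs
    ]
    pd.DataFrame(rows, columns=["gene_id", "direction", "mean_expression"]).to_csv(
        path, sep="\t", index=False
    )


_META_COLS = [
    "sample_id",
    "generation",
    "treatment",
    "timepoint",
    "leaf_pair",
    "maternal_line",
    "library_size",
]


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        lib = getattr(r, "library_size", "")
        out.append(
            SampleMeta(
                sample_id=r.sample_id,
                generation=r.generation,
                treatment=r.treatment,
                timepoint=r.timepoint or None,
                leaf_pair=r.leaf_pair,
                maternal_line=r.maternal_line or None,
                library_size=int(float(lib)) if lib not in ("", "NA") else None,
            )
        )
    return out


def write_sample_meta(path: str | Path, samples: Iterable[SampleMeta]) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "generation": s.generation,
                "treatment": s.treatment,
                "timepoint": s.timepoint or "",
                "leaf_pair": s.leaf_pair,
                "maternal_line": s.maternal_line or "",
                "library_size": s.library_size if s.library_size is not None else "",
            }
        )
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)
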