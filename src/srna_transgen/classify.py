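"""Locus classification: dicer size classes, genomic context, tRNA fragments.

A locus is dicer-derived (siRNA) when at least 80% of its read weight falls
on 20–24 nt reads; its size class is the modal dicer length (ties broken
toward the longer length, biasing toward the 24-nt RdDM-associated class).
miRNA labels come from upstream annotation and take precedence.  Everything
else is a non-dicer sRNA (nd-sRNA) locus.

For analysis the seven labels collapse into four strata: miRNA, pooled
20–23 nt siRNA, 24 nt siRNA and nd-sRNA — the groups with distinct
mean-variance behaviour in the differential-abundance tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import FeatureSet, GenomicFeature, GenomicInterval, ReadAlignment
from .locus_caller import ReadLengthProfile, SRNALocus

DICER_LENGTHS = (20, 21, 22, 23, 24)
DICER_THRESHOLD = 0.8
NEAR_BP = 5000

CLASS_LABELS = (
    "miRNA",
    "siRNA20",
    "siRNA21",
    "siRNA22",
    "siRNA23",
    "siRNA24",
    "ndsRNA",
)

#: analysis strata: pooled 20–23 nt dicer classes, 24 nt apart
STRATA = ("miRNA", "siRNA20_23", "siRNA24", "ndsRNA")


class UnclassifiableError(ValueError):
    """A locus with zero total read weight cannot be classified."""


@dataclass(frozen=True)
class SRNAClass:
    label: str
    dicer_fraction: float
    dicer_call: int | None  # modal dicer length for siRNA loci, else None

    @property
    def stratum(self) -> str:
        return stratum_of(self.label)


def stratum_of(label: str) -> str:
    if label in ("siRNA20", "siRNA21", "siRNA22", "siRNA23"):
        return "siRNA20_23"
    if label in ("miRNA", "siRNA24", "ndsRNA"):
        return label
    raise ValueError(f"unknown class label {label!r}")


def is_dicer(label: str) -> bool:
    """True for the siRNA size classes (dicer-derived)."""
    return label.startswith("siRNA")


def classify_locus(
    profile: ReadLengthProfile,
    mirna_flag: bool = False,
    dicer_threshold: float = DICER_THRESHOLD,
) -> SRNAClass:
    """Assign a locus to miRNA / siRNA size class / nd-sRNA.

    The boundary case (dicer fraction exactly at the threshold) is
    classified siRNA; modal-size ties go to the longer length.
    """
    total = profile.total
    if total <= 0:
        raise UnclassifiableError("cannot classify a locus with zero read weight")
    dicer_weight = sum(profile.counts_by_length.get(n, 0.0) for n in DICER_LENGTHS)
    frac = dicer_weight / total
    if mirna_flag:
        return SRNAClass("miRNA", frac, None)
    if frac >= dicer_threshold:
        modal = max(
            DICER_LENGTHS, key=lambda n: (profile.counts_by_length.get(n, 0.0), n)
        )
        return SRNAClass(f"siRNA{modal}", frac, modal)
    return SRNAClass("ndsRNA", frac, None)


@dataclass(frozen=True)
class ContextAnnotation:
    """Genomic context of a locus relative to the protein-coding annotation."""

    overlaps_cds: bool
    overlaps_te: bool
    distance_class: str  # O (overlapping), N (≤ near_bp), F (farther)
    nearest_gene_id: str | None
    nearest_gene_distance: int | None


def annotate_context(
    locus_interval: GenomicInterval,
    features: FeatureSet,
    near_bp: int = NEAR_BP,
) -> ContextAnnotation:
    """CDS/TE overlap flags and the O/N/F distance class to the nearest gene.

    Distance is the edge-to-edge gap (0 when sharing any base); strand is
    ignored.  With no genes on the chromosome the locus is classed F with
    missing gene id/distance.
    """
    overlaps_cds = bool(features.overlapping(locus_interval, kinds=("CDS",)))
    overlaps_te = bool(features.overlapping(locus_interval, kinds=("TE",)))
    gene, dist = features.nearest(locus_interval, kind="gene")
    if gene is None:
        return ContextAnnotation(overlaps_cds, overlaps_te, "F", None, None)
    if dist == 0:
        klass = "O"
    elif dist <= near_bp:
        klass = "N"
    else:
        klass = "F"
    return ContextAnnotation(overlaps_cds, overlaps_te, klass, gene.id, dist)


@dataclass(frozen=True)
class TRFAnnotation:
    """tRNA-fragment call for a locus overlapping a tRNA gene."""

    trna_id: str
    anticodon: str
    amino_acid: str
    side: str  # five_prime / three_prime / anticodon_spanning
    fraction_of_locus_reads_on_trna: float


def _read_side(read: ReadAlignment, ac: GenomicInterval, strand: str) -> str:
    """Side of the anticodon a read falls on, oriented by the tRNA's strand."""
    if read.interval.end <= ac.start:
        genomic = "left"
    elif read.interval.start >= ac.end:
        genomic = "right"
    else:
        return "anticodon_spanning"
    if strand == "-":
        return "five_prime" if genomic == "right" else "three_prime"
    return "five_prime" if genomic == "left" else "three_prime"


def annotate_trf(
    locus: SRNALocus,
    locus_reads: Sequence[ReadAlignment],
    features: FeatureSet,
) -> TRFAnnotation | None:
    """Classify a locus as a 5′/3′/anticodon-spanning tRNA fragment source.

    Reads lying on an overlapping tRNA vote (by weight) for the side of the
    anticodon they fall on; the locus call is the majority side, with ties
    going to ``anticodon_spanning``.  A locus with no overlapping tRNA
    returns None — absence of a tRF call is not an error.
    """
    trnas = features.overlapping(locus.interval, kinds=("tRNA",))
    if not trnas:
        return None

    best: tuple[float, GenomicFeature, dict[str, float]] | None = None
    for trna in trnas:
        votes = {"five_prime": 0.0, "three_prime": 0.0, "anticodon_spanning": 0.0}
        on_trna = 0.0
        ac: GenomicInterval = trna.attrs["anticodon_interval"]
        for r in locus_reads:
            if not r.interval.overlaps(trna.interval):
                continue
            on_trna += r.weight
            votes[_read_side(r, ac, trna.interval.strand)] += r.weight
        if best is None or on_trna > best[0]:
            best = (on_trna, trna, votes)

    assert best is not None
    on_trna, trna, votes = best
    if on_trna == 0.0:
        return None
    top = max(votes.values())
    winners = [side for side, w in votes.items() if w == top]
    side = winners[0] if len(winners) == 1 else "anticodon_spanning"
    total = sum(locus.counts.values()) or locus.profile.total
    return TRFAnnotation(
        trna_id=trna.id,
        anticodon=str(trna.attrs.get("anticodon", "")),
        amino_acid=str(trna.attrs.get("amino_acid", "")),
        side=side,
        fraction_of_locus_reads_on_trna=min(on_trna / total, 1.0) if total else 0.0,
    )


def classify_all(
    loci: Iterable[SRNALocus],
    mirna_flags: dict[str, bool] | None = None,
    features: FeatureSet | None = None,
    near_bp: int = NEAR_BP,
) -> dict[str, tuple[SRNAClass, ContextAnnotation | None]]:
    """Classify every locus and, when an annotation is given, its context."""
    mirna_flags = mirna_flags or {}
    out: dict[str, tuple[SRNAClass, ContextAnnotation | None]] = {}
    for locus in loci:
        cls = classify_locus(locus.profile, mirna_flags.get(locus.id, False))
        ctx = (
            annotate_context(locus.interval, features, near_bp)
            if features is not None
            else None
        )
        out[locus.id] = (cls, ctx)
    return out
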