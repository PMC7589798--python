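"""Synthetic genomes, annotations, reads, counts and DMR/DEG tables.

The generator reproduces the statistical structure the analysis assumes so
that every pipeline stage runs and is testable without any download:

* a 34-library design — three replicate pairs (wounded/control) for each
  parental cell (1 h and 72 h in the wounded second leaf pair, 72 h in the
  unwounded third leaf pair) and 16 offspring libraries (two siblings from
  each of four maternal lines per parental treatment);
* seven locus classes with class-specific length and abundance
  distributions, 24-nt siRNA loci placed preferentially inside transposable
  elements and nd-sRNA loci preferentially over coding sequence;
* a subset of nd-sRNA loci that are tRNA-fragment sources, with reads
  placed strictly 5′ or 3′ of the anticodon of a 12-isoacceptor tRNA
  catalogue;
* negative-binomial counts with planted wound log fold changes
  concentrated in nd-sRNA loci at the 72 h wounded-leaf contrast, a
  correlated 1 h subset, maternal-line random effects and a configured
  (negative) parent–offspring LFC correlation;
* DMR direction probabilities and DEG rates conditioned on realized sRNA
  overlap, matching the association structure the downstream models test.

Every draw flows from one ``numpy`` Generator seeded by
``SimulationParams.seed``; identical parameters give identical output.
Truth tables record all planted quantities for recovery tests.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    DEGRecord,
    DMRRecord,
    FeatureSet,
    GenomicFeature,
    GenomicInterval,
    ReadAlignment,
    SampleMeta,
    write_degs,
    write_dmrs,
    write_gff3,
    write_reads_bed,
    write_sample_meta,
    write_count_table,
)
from .diffabund import CountMatrix
from .locus_caller import ReadLengthProfile, SRNALocus

DEFAULT_SEED = 20201013

#: per-class locus counts of the real survey, used as mixture proportions
CLASS_COUNTS = {
    "miRNA": 44,
    "siRNA20": 10,
    "siRNA21": 226,
    "siRNA22": 411,
    "siRNA23": 50,
    "siRNA24": 25412,
    "ndsRNA": 3775,
}

#: 12 tRNA isoacceptors; the first three are the wound-responsive ones
TRNA_CATALOGUE = [
    ("Leu", "CAA"),
    ("Gly", "CCC"),
    ("Ala", "GGC"),
    ("Gln", "TTG"),
    ("Asp", "GTC"),
    ("Glu", "TTC"),
    ("Ser", "GCT"),
    ("Arg", "ACG"),
    ("Val", "CAC"),
    ("Thr", "TGT"),
    ("Pro", "TGG"),
    ("Ile", "AAT"),
]


def _norm(d: Mapping[str, float]) -> dict[str, float]:
    tot = sum(d.values())
    return {k: v / tot for k, v in d.items()}


@dataclass
class SimulationParams:
    """All knobs of the generator, with study-shaped defaults."""

    seed: int = DEFAULT_SEED
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 60
    n_tes: int = 50
    n_trnas: int = 12
    n_loci: int = 160
    class_mix: dict[str, float] = field(
        default_factory=lambda: _norm(CLASS_COUNTS)
    )
    # class-median locus lengths (bp) and log-normal spread
    length_median: dict[str, float] = field(
        default_factory=lambda: {"miRNA": 227.0, "siRNA": 409.0, "ndsRNA": 774.0}
    )
    length_log_sd: float = 0.5
    # class-mean log10 abundance (reads per million) and spread
    expr_log10rpm_mean: dict[str, float] = field(
        default_factory=lambda: {"miRNA": 1.4, "siRNA": 0.37, "ndsRNA": 0.66}
    )
    expr_log10rpm_sd: float = 0.4
    nb_dispersion: float = 0.1
    library_size: int = 2_000_000  # mean mapped reads per library (counts model)
    library_log_sd: float = 0.15
    reads_per_sample: int = 4000  # read-level simulation depth (BED output)
    n_parent_reps: int = 3
    n_maternal_lines: int = 4  # per parental treatment
    n_sibs: int = 2
    # annotation/locus placement
    te_overlap_siRNA24: float = 0.90
    cds_overlap_nd: float = 0.627
    min_locus_gap: int = 200  # keeps loci separable at the default pad
    n_trf_loci: int = 12  # nd-sRNA loci that are tRF sources
    trf_five_prime_frac: float = 23.0 / 34.0
    # planted wound response (concentrated in nd-sRNA at 72 h, wounded leaf)
    frac_nd_responsive: float = 0.10
    lfc_up_prob: float = 328.0 / 377.0
    lfc_mag_mean: float = 2.0
    lfc_mag_sd: float = 0.5
    frac_1h_given_72h: float = 53.0 / 377.0
    lfc_1h_scale: float = 0.5
    parent_offspring_r: float = -0.2
    offspring_lfc_sd: float = 0.3
    maternal_sd: float = 0.2
    # DMR / DEG association structure
    n_dmrs: int = 120
    dmr_place_in_siRNA24: float = 0.35
    dmr_place_in_nd: float = 0.15
    dmr_length_mean: float = 300.0
    dmr_up_probs: dict[str, float] = field(
        default_factory=lambda: {"siRNA": 0.659, "ndsRNA": 0.418, "none": 0.488}
    )
    deg_rate_overlap: float = 0.132
    deg_rate_background: float = 0.084
    deg_expr_slope: float = -1.0
    deg_class_logodds: dict[str, float] = field(
        default_factory=lambda: {"none": 0.0, "siRNA": -0.8, "ndsRNA": 0.8}
    )

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-6:
            raise ValueError("class_mix proportions must sum to 1")
        probs = [
            *self.dmr_up_probs.values(),
            self.deg_rate_overlap,
            self.deg_rate_background,
            self.te_overlap_siRNA24,
            self.cds_overlap_nd,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        for name in ("n_chroms", "n_genes", "n_loci", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _length_class(label: str) -> str:
    if label == "miRNA":
        return "miRNA"
    return "siRNA" if label.startswith("siRNA") else "ndsRNA"


def _read_length_probs(label: str) -> tuple[np.ndarray, np.ndarray]:
    """Read-length distribution per class; dicer mass well off the 0.8 rule."""
    lengths = np.arange(15, 36)
    p = np.zeros_like(lengths, dtype=float)
    if label == "miRNA":
        p[lengths == 21] = 0.90
        p[lengths == 20] = 0.05
        p[lengths == 22] = 0.05
    elif label.startswith("siRNA"):
        modal = int(label[-2:])
        p[:] = 0.0
        p[(lengths >= 20) & (lengths <= 24)] = 0.015
        p[lengths == modal] = 0.88
        p[(lengths < 20) | (lengths > 24)] = 0.06 / 16
    else:  # nd-sRNA: broad 15–35 mixture, dicer mass ≈ 0.24
        p[:] = 1.0
    return lengths, p / p.sum()


# ---------------------------------------------------------------------------
# Annotation + locus placement
# ---------------------------------------------------------------------------


class _Occupied:
    """Per-chromosome occupied-interval bookkeeping for collision-free placement.

    Stored intervals are pairwise disjoint (placement only adds after a
    clean collision check), so a sorted list with bisection suffices.
    """

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def collides(self, chrom: str, start: int, end: int) -> bool:
        from bisect import bisect_left

        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return False
        i = bisect_left(ivs, (start, start))
        if i < len(ivs) and ivs[i][0] < end:
            return True
        return i > 0 and ivs[i - 1][1] > start

    def add(self, chrom: str, start: int, end: int) -> None:
        from bisect import insort

        insort(self._by_chrom.setdefault(chrom, []), (start, end))


def _place(
    rng: np.random.Generator,
    occupied: _Occupied,
    chroms: list[str],
    chrom_length: int,
    length: int,
    margin: int = 0,
    max_tries: int = 200,
) -> GenomicInterval | None:
    for _ in range(max_tries):
        chrom = chroms[int(rng.integers(len(chroms)))]
        if chrom_length - length - 1 <= 1:
            return None
        start = int(rng.integers(1, chrom_length - length - 1))
        if not occupied.collides(chrom, start - margin, start + length + margin):
            occupied.add(chrom, start - margin, start + length + margin)
            return GenomicInterval(chrom, start, start + length)
    return None


def simulate_annotation(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[FeatureSet, pd.DataFrame]:
    """Generate the annotation and the planted sRNA locus truth table.

    Genes (each with one CDS child), TEs and tRNA genes are placed without
    mutual overlap.  Locus placement then realises the configured context
    rates: 24-nt siRNA loci fall inside TEs with probability
    ``te_overlap_siRNA24``, nd-sRNA loci overlap CDS with probability
    ``cds_overlap_nd``, and ``n_trf_loci`` nd-sRNA loci sit exactly on tRNA
    genes with a planted 5′/3′ side.  Loci keep a mutual gap of at least
    ``min_locus_gap`` so island calling can separate them.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    chroms = [f"chr{i + 1}" for i in range(params.n_chroms)]

    features: list[GenomicFeature] = []
    occ = _Occupied()

    genes: list[GenomicFeature] = []
    for i in range(params.n_genes):
        length = int(np.clip(rng.lognormal(math.log(2000), 0.5), 400, 20000))
        iv = _place(rng, occ, chroms, params.chrom_length, length, margin=50)
        if iv is None:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(iv.chrom, iv.start, iv.end, strand)
        gid = f"gene{i + 1:05d}"
        gene = GenomicFeature(iv, "gene", gid)
        genes.append(gene)
        features.append(gene)
        utr = max(10, length // 10)
        cds_iv = GenomicInterval(iv.chrom, iv.start + utr, iv.end - utr, strand)
        features.append(
            GenomicFeature(cds_iv, "CDS", f"{gid}.cds", {"Parent": gid})
        )

    tes: list[GenomicFeature] = []
    for i in range(params.n_tes):
        length = int(np.clip(rng.lognormal(math.log(1500), 0.5), 300, 15000))
        iv = _place(rng, occ, chroms, params.chrom_length, length, margin=50)
        if iv is None:
            continue
        te = GenomicFeature(iv, "TE", f"te{i + 1:05d}")
        tes.append(te)
        features.append(te)

    trnas: list[GenomicFeature] = []
    for i in range(params.n_trnas):
        aa, anticodon = TRNA_CATALOGUE[i % len(TRNA_CATALOGUE)]
        iv = _place(rng, occ, chroms, params.chrom_length, 75, margin=300)
        if iv is None:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(iv.chrom, iv.start, iv.end, strand)
        ac = GenomicInterval(iv.chrom, iv.start + 33, iv.start + 36, strand)
        trnas.append(
            GenomicFeature(
                iv,
                "tRNA",
                f"trna{i + 1:03d}",
                {"anticodon": anticodon, "amino_acid": aa, "anticodon_interval": ac},
            )
        )
    features.extend(trnas)

    # --- locus placement ------------------------------------------------
    labels = list(params.class_mix)
    draws = rng.choice(len(labels), size=params.n_loci, p=[params.class_mix[l] for l in labels])
    locus_occ = _Occupied()
    rows: list[dict] = []
    trf_budget = min(params.n_trf_loci, len(trnas))
    trf_assigned = 0
    lidx = 0
    for d in draws:
        label = labels[int(d)]
        lclass = _length_class(label)
        length = int(
            np.clip(
                rng.lognormal(math.log(params.length_median[lclass]), params.length_log_sd),
                40,
                12000,
            )
        )
        is_trf = False
        trf_side = ""
        trna_id = ""
        iv: GenomicInterval | None = None
        if label == "ndsRNA" and trf_assigned < trf_budget:
            # dedicate the first nd-sRNA draws to the tRF catalogue
            trna = trnas[trf_assigned]
            iv = GenomicInterval(trna.interval.chrom, trna.interval.start, trna.interval.end)
            if not locus_occ.collides(
                iv.chrom, iv.start - params.min_locus_gap, iv.end + params.min_locus_gap
            ):
                locus_occ.add(
                    iv.chrom,
                    iv.start - params.min_locus_gap,
                    iv.end + params.min_locus_gap,
                )
                is_trf = True
                trna_id = trna.id
                trf_side = (
                    "five_prime"
                    if rng.random() < params.trf_five_prime_frac
                    else "three_prime"
                )
                trf_assigned += 1
            else:
                iv = None
        if iv is None or not is_trf:
            target: GenomicInterval | None = None
            hosts: list[GenomicFeature] | None = None
            if label == "siRNA24" and tes and rng.random() < params.te_overlap_siRNA24:
                hosts = tes
            elif label == "ndsRNA" and genes and rng.random() < params.cds_overlap_nd:
                hosts = genes
            iv = None
            if hosts is not None:
                # resample the host each attempt so full hosts do not force
                # a fallback to background placement
                for _ in range(50):
                    target = hosts[int(rng.integers(len(hosts)))].interval
                    if target.length > length:
                        start = target.start + int(rng.integers(0, target.length - length))
                    else:
                        start = max(1, target.start - (length - target.length) // 2)
                    end = start + length
                    if not locus_occ.collides(
                        target.chrom,
                        start - params.min_locus_gap,
                        end + params.min_locus_gap,
                    ):
                        locus_occ.add(
                            target.chrom,
                            start - params.min_locus_gap,
                            end + params.min_locus_gap,
                        )
                        iv = GenomicInterval(target.chrom, start, end)
                        break
            if iv is None:
                iv = _place(
                    rng,
                    locus_occ,
                    chroms,
                    params.chrom_length,
                    length,
                    margin=params.min_locus_gap,
                )
            if iv is None:
                continue  # genome too crowded; drop the draw
        lidx += 1
        lclass_expr = _length_class(label)
        log10rpm = rng.normal(
            params.expr_log10rpm_mean[lclass_expr], params.expr_log10rpm_sd
        )
        rows.append(
            {
                "locus_id": f"locus{lidx:06d}",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "length": iv.length,
                "label": label,
                "mirna_flag": label == "miRNA",
                "is_trf": is_trf,
                "trf_side": trf_side,
                "trna_id": trna_id,
                "log10_rpm": float(log10rpm),
            }
        )
    loci = pd.DataFrame(rows)
    return FeatureSet(features), loci


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------


def study_design(params: SimulationParams, rng: np.random.Generator) -> list[SampleMeta]:
    """The 34-library layout: 18 parental + 16 offspring samples."""
    samples: list[SampleMeta] = []

    def lib() -> int:
        return int(rng.lognormal(math.log(params.library_size), params.library_log_sd))

    for timepoint, leaf in (("1h", "second"), ("72h", "second"), ("72h", "third")):
        for treatment in ("control", "wounded"):
            for rep in range(1, params.n_parent_reps + 1):
                tp = timepoint.replace("h", "h")
                samples.append(
                    SampleMeta(
                        sample_id=f"P_{timepoint}_{'L2' if leaf == 'second' else 'L3'}_{treatment[0]}{rep}",
                        generation="parent",
                        treatment=treatment,
                        timepoint=timepoint,
                        leaf_pair=leaf,
                        library_size=lib(),
                    )
                )
    for treatment in ("control", "wounded"):
        for line in range(1, params.n_maternal_lines + 1):
            for sib in range(1, params.n_sibs + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"O_{treatment[0]}{line}_s{sib}",
                        generation="offspring",
                        treatment=treatment,
                        leaf_pair="second",
                        maternal_line=f"{treatment[0].upper()}{line}",
                        library_size=lib(),
                    )
                )
    return samples


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def _trf_read(
    rng: np.random.Generator,
    trna_iv: GenomicInterval,
    side: str,
) -> tuple[int, int]:
    """A read start/end strictly on the planted side of the anticodon."""
    ac_start = trna_iv.start + 33
    ac_end = trna_iv.start + 36
    left = (side == "five_prime") == (trna_iv.strand != "-")
    if left:
        region_lo, region_hi = trna_iv.start, ac_start
    else:
        region_lo, region_hi = ac_end, trna_iv.end
    max_len = min(28, region_hi - region_lo)
    length = int(rng.integers(15, max_len + 1))
    start = int(rng.integers(region_lo, region_hi - length + 1))
    return start, start + length


def simulate_reads(
    params: SimulationParams,
    loci: pd.DataFrame,
    features: FeatureSet | None = None,
    samples: Sequence[SampleMeta] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[ReadAlignment]]:
    """Per-sample read alignments over the planted loci.

    Each sample receives exactly ``reads_per_sample`` reads, multinomially
    allocated across loci in proportion to locus abundance.  Read lengths
    follow the class distribution; tRF-locus reads are confined to the
    planted side of the tRNA anticodon, oriented by the tRNA's strand when
    the annotation is supplied.
    """
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    if samples is None:
        samples = study_design(params, np.random.default_rng(params.seed + 2))
    strands = (
        {t.id: t.interval.strand for t in features.trnas} if features is not None else {}
    )
    weights = np.power(10.0, loci["log10_rpm"].to_numpy())
    probs = weights / weights.sum()
    length_dists = {label: _read_length_probs(label) for label in loci["label"].unique()}

    out: dict[str, list[ReadAlignment]] = {}
    for sample in samples:
        alloc = rng.multinomial(params.reads_per_sample, probs)
        reads: list[ReadAlignment] = []
        for row, k in zip(loci.itertuples(index=False), alloc):
            if k == 0:
                continue
            if row.is_trf:
                trna_iv = GenomicInterval(
                    row.chrom, row.start, row.end, strands.get(row.trna_id, "+")
                )
                for _ in range(int(k)):
                    s, e = _trf_read(rng, trna_iv, row.trf_side)
                    reads.append(
                        ReadAlignment(GenomicInterval(row.chrom, s, e), sample.sample_id)
                    )
                continue
            lengths, p = length_dists[row.label]
            ls = rng.choice(lengths, size=int(k), p=p)
            for L in ls:
                L = int(L)
                if row.end - row.start > L:
                    s = int(rng.integers(row.start, row.end - L))
                else:
                    s = row.start
                reads.append(
                    ReadAlignment(GenomicInterval(row.chrom, s, s + L), sample.sample_id)
                )
        out[sample.sample_id] = reads
    return out


def loci_from_truth(
    loci: pd.DataFrame, reads_by_sample: Mapping[str, list[ReadAlignment]]
) -> list[SRNALocus]:
    """Materialize :class:`SRNALocus` objects at the planted intervals."""
    pooled: dict[str, list[ReadAlignment]] = {lid: [] for lid in loci["locus_id"]}
    arrays: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom, sub in loci.groupby("chrom"):
        arrays[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            list(sub["locus_id"]),
        )
    for reads in reads_by_sample.values():
        for r in reads:
            if r.interval.chrom not in arrays:
                continue
            starts, ends, ids = arrays[r.interval.chrom]
            hit = np.flatnonzero(
                (starts < r.interval.end) & (r.interval.start < ends)
            )
            if hit.size:
                pooled[ids[int(hit[0])]].append(r)
    out = []
    for row in loci.itertuples(index=False):
        members = pooled[row.locus_id]
        counts: dict[str, float] = {}
        for r in members:
            counts[r.sample_id] = counts.get(r.sample_id, 0.0) + r.weight
        out.append(
            SRNALocus(
                id=row.locus_id,
                interval=GenomicInterval(row.chrom, row.start, row.end),
                profile=ReadLengthProfile.from_reads(members),
                counts=counts,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def planted_lfcs(
    params: SimulationParams, loci: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Planted per-locus log2 fold changes for each of the four contrasts.

    Wound effects concentrate in nd-sRNA loci at the 72 h second-leaf
    contrast (mostly increases); the 1 h response is a scaled subset; the
    unwounded third leaf is quiet; offspring LFCs are drawn with the
    configured correlation against the parental 72 h response.
    """
    n = len(loci)
    lfc72 = np.zeros(n)
    lfc1 = np.zeros(n)
    lfc3 = np.zeros(n)

    nd = (loci["label"] == "ndsRNA").to_numpy()
    responsive = nd & (rng.random(n) < params.frac_nd_responsive)
    mags = np.clip(
        rng.normal(params.lfc_mag_mean, params.lfc_mag_sd, size=n), 0.5, None
    )
    signs = np.where(rng.random(n) < params.lfc_up_prob, 1.0, -1.0)
    lfc72[responsive] = (mags * signs)[responsive]
    early = responsive & (rng.random(n) < params.frac_1h_given_72h)
    lfc1[early] = params.lfc_1h_scale * lfc72[early]

    # offspring: population correlation r against the parental 72 h LFC
    r = params.parent_offspring_r
    sd_y = params.offspring_lfc_sd
    x = lfc72
    sd_x = float(x.std()) or 1.0
    noise = rng.normal(0.0, sd_y * math.sqrt(max(1.0 - r * r, 0.0)), size=n)
    lfc_off = r * sd_y / sd_x * (x - x.mean()) + noise

    return pd.DataFrame(
        {
            "locus_id": loci["locus_id"],
            "lfc_parent_1h_leaf2": lfc1,
            "lfc_parent_72h_leaf2": lfc72,
            "lfc_parent_72h_leaf3": lfc3,
            "lfc_offspring_leaf2": lfc_off,
        }
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw of NB(mu, alpha); alpha = 0 degenerates to Poisson."""
    mu = np.clip(mu, 1e-12, None)
    if alpha < 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def simulate_counts(
    params: SimulationParams,
    loci: pd.DataFrame,
    samples: Sequence[SampleMeta] | None = None,
    lfcs: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts for the 34-library design with the planted effect structure.

    Returns the count matrix and the planted-LFC truth table.  Maternal-line
    random effects (log-scale sd ``maternal_sd``) apply to offspring
    libraries only.
    """
    rng = np.random.default_rng(params.seed + 3) if rng is None else rng
    if samples is None:
        samples = study_design(params, rng)
    if lfcs is None:
        lfcs = planted_lfcs(params, loci, rng)

    q = np.power(10.0, loci["log10_rpm"].to_numpy()) / 1e6  # per-read rate
    n_loci = len(loci)
    lfc_cols = {
        ("parent", "1h", "second"): lfcs["lfc_parent_1h_leaf2"].to_numpy(),
        ("parent", "72h", "second"): lfcs["lfc_parent_72h_leaf2"].to_numpy(),
        ("parent", "72h", "third"): lfcs["lfc_parent_72h_leaf3"].to_numpy(),
        ("offspring", None, "second"): lfcs["lfc_offspring_leaf2"].to_numpy(),
    }
    line_effects: dict[str, np.ndarray] = {}
    cols = {}
    for s in samples:
        key = (s.generation, s.timepoint, s.leaf_pair)
        lfc = lfc_cols[key]
        log_mu = np.log(q * float(s.library_size))
        if s.treatment == "wounded":
            log_mu = log_mu + lfc * math.log(2.0)
        if s.generation == "offspring":
            if s.maternal_line not in line_effects:
                line_effects[s.maternal_line] = rng.normal(
                    0.0, params.maternal_sd, size=n_loci
                )
            log_mu = log_mu + line_effects[s.maternal_line]
        cols[s.sample_id] = _nb_draw(rng, np.exp(log_mu), params.nb_dispersion)
    counts = pd.DataFrame(cols, index=loci["locus_id"])
    return CountMatrix(counts=counts, samples=list(samples)), lfcs


# ---------------------------------------------------------------------------
# DMRs and DEGs
# ---------------------------------------------------------------------------


def simulate_dmr_deg(
    params: SimulationParams,
    loci: pd.DataFrame,
    features: FeatureSet,
    rng: np.random.Generator | None = None,
) -> tuple[list[DMRRecord], list[DEGRecord], pd.DataFrame]:
    """DMR and DEG tables with the planted sRNA-association structure.

    DMRs are preferentially dropped inside 24-nt siRNA loci (then nd-sRNA
    loci); the methylation direction is drawn from the configured
    up-probability of the *realized* overlap group, so realized proportions
    match the configuration in expectation.  Genes become DEGs at the
    overlap-conditional rates, with an expression-dependent direction bias
    and class-specific direction log-odds.

    Returns (dmrs, degs, gene truth table).
    """
    rng = np.random.default_rng(params.seed + 4) if rng is None else rng
    chroms = sorted({iv for iv in loci["chrom"].unique()})

    si24 = loci[loci["label"] == "siRNA24"]
    nd = loci[loci["label"] == "ndsRNA"]

    locus_arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in loci.groupby("chrom"):
        dicer = sub["label"].str.startswith("siRNA").to_numpy()
        locus_arrays[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            np.where(sub["mirna_flag"], "miRNA", np.where(dicer, "siRNA", "ndsRNA")),
        )

    def realized_group(chrom: str, start: int, end: int) -> str:
        if chrom not in locus_arrays:
            return "none"
        starts, ends, labels = locus_arrays[chrom]
        hit = (starts < end) & (start < ends)
        if not hit.any():
            return "none"
        sub = labels[hit]
        if (sub == "siRNA").any():
            return "siRNA"
        if (sub == "ndsRNA").any():
            return "ndsRNA"
        return "none"

    dmrs: list[DMRRecord] = []
    for _ in range(params.n_dmrs):
        length = int(np.clip(rng.normal(params.dmr_length_mean, 100.0), 50, 2000))
        u = rng.random()
        if u < params.dmr_place_in_siRNA24 and len(si24):
            host = si24.iloc[int(rng.integers(len(si24)))]
        elif u < params.dmr_place_in_siRNA24 + params.dmr_place_in_nd and len(nd):
            host = nd.iloc[int(rng.integers(len(nd)))]
        else:
            host = None
        if host is not None:
            lo = int(host["start"])
            hi = max(lo + 1, int(host["end"]) - length)
            start = int(rng.integers(lo, hi)) if hi > lo else lo
            chrom = str(host["chrom"])
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1, params.chrom_length - length - 1))
        end = start + length
        group = realized_group(chrom, start, end)
        group_key = group if group in params.dmr_up_probs else "none"
        direction = "up" if rng.random() < params.dmr_up_probs[group_key] else "down"
        context = ("CHH", "CG", "CHG")[int(rng.integers(3))]
        dmrs.append(DMRRecord(GenomicInterval(chrom, start, end), direction, context))

    genes = features.genes
    from .assoc import build_locus_arrays, overlap_group  # local: avoids cycle at import

    pairs = [
        (
            GenomicInterval(r.chrom, r.start, r.end),
            "siRNA" if str(r.label).startswith("siRNA") else
            ("ndsRNA" if r.label == "ndsRNA" else "miRNA"),
        )
        for r in loci.itertuples(index=False)
    ]
    arrays = build_locus_arrays(pairs)

    degs: list[DEGRecord] = []
    gene_rows = []
    log_exprs = rng.normal(1.2, 0.5, size=len(genes))
    mean_logexpr = float(log_exprs.mean()) if len(genes) else 0.0
    for gene, log_expr in zip(genes, log_exprs):
        grp = overlap_group(gene.interval, pairs, arrays=arrays)
        grp = grp if grp in ("siRNA", "ndsRNA") else "none"
        rate = params.deg_rate_overlap if grp != "none" else params.deg_rate_background
        is_de = rng.random() < rate
        if is_de:
            z = (
                params.deg_expr_slope * (log_expr - mean_logexpr)
                + params.deg_class_logodds.get(grp, 0.0)
            )
            p_up = 1.0 / (1.0 + math.exp(-z))
            direction = "up" if rng.random() < p_up else "down"
        else:
            direction = "none"
        mean_expression = float(10.0 ** log_expr)
        degs.append(DEGRecord(gene.id, direction, mean_expression))
        gene_rows.append(
            {
                "gene_id": gene.id,
                "overlap_group": grp,
                "is_de": is_de,
                "direction": direction,
                "log10_expression": float(log_expr),
            }
        )
    return dmrs, degs, pd.DataFrame(gene_rows)


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

PROFILES: dict[str, dict] = {
    # CI-scale: every stage in seconds, all classes represented
    "tiny": dict(
        n_loci=160,
        n_genes=60,
        n_tes=50,
        n_trnas=12,
        n_chroms=2,
        chrom_length=500_000,
        n_dmrs=120,
        library_size=2_000_000,
        reads_per_sample=4000,
        class_mix=_norm(
            {
                "miRNA": 0.05,
                "siRNA20": 0.02,
                "siRNA21": 0.05,
                "siRNA22": 0.05,
                "siRNA23": 0.03,
                "siRNA24": 0.50,
                "ndsRNA": 0.30,
            }
        ),
    ),
    # survey-shaped: Table-1-like class mix and DMR/DEG volumes at desk scale
    "paper-shaped": dict(
        n_loci=15000,
        n_genes=3000,
        n_tes=4000,
        n_trnas=12,
        n_chroms=4,
        chrom_length=12_000_000,
        n_dmrs=3731,
        library_size=5_200_000,
        reads_per_sample=0,
    ),
}


@dataclass
class FixtureBundle:
    """Everything one simulation run produced, plus its truth tables."""

    params: SimulationParams
    features: FeatureSet
    loci: pd.DataFrame  # planted locus truth
    samples: list[SampleMeta]
    counts: CountMatrix
    lfcs: pd.DataFrame  # planted LFC truth
    dmrs: list[DMRRecord]
    degs: list[DEGRecord]
    gene_truth: pd.DataFrame
    reads: dict[str, list[ReadAlignment]] | None = None

    @property
    def truth_tables(self) -> dict[str, pd.DataFrame]:
        return {"loci": self.loci, "lfcs": self.lfcs, "genes": self.gene_truth}


def make_fixture(
    profile_name: str = "tiny",
    seed: int = DEFAULT_SEED,
    outdir: str | Path | None = None,
    overrides: Mapping | None = None,
) -> FixtureBundle:
    """Generate a complete input bundle for one named simulation profile.

    With ``outdir`` set, writes annotation.gff3, per-sample BED reads (when
    the profile simulates reads), counts.tsv, meta.tsv, dmrs.tsv, degs.tsv
    and the truth tables; reruns with the same seed are identical.
    """
    if profile_name not in PROFILES:
        raise ValueError(f"unknown profile {profile_name!r}; choose from {sorted(PROFILES)}")
    kwargs = dict(PROFILES[profile_name])
    if overrides:
        kwargs.update(overrides)
    params = SimulationParams(seed=seed, **kwargs)

    rng = np.random.default_rng(params.seed)
    features, loci = simulate_annotation(params, rng)
    samples = study_design(params, rng)
    counts, lfcs = simulate_counts(params, loci, samples=samples, rng=rng)
    dmrs, degs, gene_truth = simulate_dmr_deg(params, loci, features, rng=rng)
    reads = None
    if params.reads_per_sample > 0:
        reads = simulate_reads(params, loci, features=features, samples=samples, rng=rng)

    bundle = FixtureBundle(
        params=params,
        features=features,
        loci=loci,
        samples=samples,
        counts=counts,
        lfcs=lfcs,
        dmrs=dmrs,
        degs=degs,
        gene_truth=gene_truth,
        reads=reads,
    )
    if outdir is not None:
        write_fixture(bundle, outdir)
    return bundle


def locus_table_from_bundle(bundle: FixtureBundle) -> list[SRNALocus]:
    """Pipeline-facing locus objects: read-derived profiles when reads were
    simulated, otherwise profiles synthesized from the class length mix."""
    if bundle.reads is not None:
        return loci_from_truth(bundle.loci, bundle.reads)
    rng = np.random.default_rng(bundle.params.seed + 5)
    out = []
    for row in bundle.loci.itertuples(index=False):
        lengths, p = _read_length_probs(row.label)
        draws = rng.multinomial(500, p)
        profile = ReadLengthProfile(
            {int(n): float(k) for n, k in zip(lengths, draws) if k > 0}
        )
        out.append(
            SRNALocus(
                id=row.locus_id,
                interval=GenomicInterval(row.chrom, row.start, row.end),
                profile=profile,
            )
        )
    return out


def write_fixture(bundle: FixtureBundle, outdir: str | Path) -> None:
    from .pipeline import write_locus_table  # deferred: pipeline is downstream

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gff3(outdir / "annotation.gff3", bundle.features)
    mirna_flags = dict(zip(bundle.loci["locus_id"], bundle.loci["mirna_flag"]))
    write_locus_table(outdir / "loci.tsv", locus_table_from_bundle(bundle), mirna_flags)
    write_count_table(outdir / "counts.tsv", bundle.counts.counts)
    write_sample_meta(outdir / "meta.tsv", bundle.samples)
    write_dmrs(outdir / "dmrs.tsv", bundle.dmrs)
    write_degs(outdir / "degs.tsv", bundle.degs)
    bundle.loci.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    bundle.lfcs.to_csv(outdir / "truth_lfcs.tsv", sep="\t", index=False)
    bundle.gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    if bundle.reads is not None:
        reads_dir = outdir / "reads"
        reads_dir.mkdir(exist_ok=True)
        for sample_id, reads in bundle.reads.items():
            write_reads_bed(reads_dir / f"{sample_id}.bed", reads)
    manifest = {
        "profile_params": {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in dataclasses.asdict(bundle.params).items()
        },
        "n_loci": int(len(bundle.loci)),
        "n_samples": len(bundle.samples),
        "n_dmrs": len(bundle.dmrs),
        "n_genes": len(bundle.features.genes),
    }
    import yaml

    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
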