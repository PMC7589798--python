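"""End-to-end orchestration: classify → filter → test → associate → report.

The pipeline consumes a directory of standard-format inputs (GFF3
annotation, a locus table with read-length profiles, a counts TSV, sample
metadata, optional DMR/DEG tables), runs every stage in a fixed order with
one structured log line per stage, and writes per-contrast result tables,
the classification table, a Table-1-style class summary and the
association report.  Reruns with identical config and inputs are
byte-identical.  Missing DMR or DEG tables degrade gracefully: the
corresponding association rows are marked skipped, never failed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import classify as classify_mod
from . import diffabund
from .diffabund import CountMatrix
from .io_formats import (
    FeatureSet,
    GenomicInterval,
    read_count_table,
    read_degs,
    read_dmrs,
    read_gff3,
    read_sample_meta,
    write_results,
)
from .locus_caller import ReadLengthProfile, SRNALocus

PROFILE_COLS = [f"len{n}" for n in range(15, 36)]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    indir: str = "."
    outdir: str = "out"
    gff: str = "annotation.gff3"
    loci: str = "loci.tsv"
    counts: str = "counts.tsv"
    meta: str = "meta.tsv"
    dmrs: str | None = "dmrs.tsv"
    degs: str | None = "degs.tsv"
    pad: int = 75
    min_reads: float = 5.0
    min_rpm: float = 2.0
    near_bp: int = 5000
    dmr_window: int = 20_000
    tail_q: float = 0.05
    fdr: float = 0.05
    seed: int = 20201013
    contrasts: tuple[str, ...] = tuple(diffabund.CONTRASTS)
    top_trf_n: int = 315  # size of the "most wound-responsive" nd-sRNA set

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must lie in (0, 1)")
        for name in ("pad", "min_reads", "min_rpm", "near_bp", "dmr_window", "tail_q"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contrasts" in raw:
            raw["contrasts"] = tuple(raw["contrasts"])
        return cls(**raw)


def read_locus_table(
    path: str | Path,
) -> tuple[list[SRNALocus], dict[str, bool]]:
    """Read a locus table TSV (id, coordinates, mirna_flag, len15..len35).

    Returns the loci and the per-locus miRNA flag map.
    """
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        profile = ReadLengthProfile(
            {
                n: float(getattr(row, f"len{n}"))
                for n in range(15, 36)
                if float(getattr(row, f"len{n}")) > 0
            }
        )
        out.append(
            SRNALocus(
                id=str(row.locus_id),
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                profile=profile,
            )
        )
    mirna_flags = {
        str(r.locus_id): bool(r.mirna_flag) for r in df.itertuples(index=False)
    }
    return out, mirna_flags


def write_locus_table(
    path: str | Path, loci: Sequence[SRNALocus], mirna_flags: Mapping[str, bool] | None = None
) -> None:
    mirna_flags = mirna_flags or {}
    rows = []
    for locus in loci:
        row = {
            "locus_id": locus.id,
            "chrom": locus.interval.chrom,
            "start": locus.interval.start,
            "end": locus.interval.end,
            "length": locus.length,
            "mirna_flag": bool(mirna_flags.get(locus.id, False)),
        }
        for n in range(15, 36):
            row[f"len{n}"] = locus.profile.counts_by_length.get(n, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def summarize_table1(
    classified: pd.DataFrame, counts: CountMatrix
) -> pd.DataFrame:
    """Per-class summary: locus count, mean log10 rpm, mean length, % CDS/TE.

    ``classified`` columns: locus_id, label, length, overlaps_cds,
    overlaps_te.  Loci with zero mean RPM are excluded from the log10 rpm
    mean (log of zero is undefined), not from the other columns.
    """
    mean_rpm = counts.mean_rpm()
    df = classified.copy()
    df["mean_rpm"] = df["locus_id"].map(mean_rpm)
    rows = []
    for label in classify_mod.CLASS_LABELS:
        sub = df[df["label"] == label]
        if sub.empty:
            continue
        pos = sub[sub["mean_rpm"] > 0]
        rows.append(
            {
                "class": label,
                "n_loci": len(sub),
                "mean_log10_rpm": float(np.log10(pos["mean_rpm"]).mean()) if len(pos) else np.nan,
                "mean_length": float(sub["length"].mean()),
                "pct_cds_overlap": 100.0 * float(sub["overlaps_cds"].mean()),
                "pct_te_overlap": 100.0 * float(sub["overlaps_te"].mean()),
            }
        )
    return pd.DataFrame(rows)


def _skipped(test_name: str, reason: str) -> assoc_mod.AssociationResult:
    return assoc_mod.AssociationResult(
        test_name, float("nan"), 0, float("nan"), note=f"skipped: {reason}"
    )


def _dicer_group(label: str) -> str:
    if label == "miRNA":
        return "miRNA"
    return "siRNA" if label.startswith("siRNA") else "ndsRNA"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the report bundle and writes it to outdir."""
    indir = Path(config.indir)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t_start = time.time()

    def log(stage: str, n_in, n_out) -> None:
        log_lines.append(
            f"{stage}\tn_in={n_in}\tn_out={n_out}\telapsed={time.time() - t_start:.2f}s"
        )

    # ---- load ----------------------------------------------------------
    features = read_gff3(indir / config.gff)
    samples = read_sample_meta(indir / config.meta)
    matrix = read_count_table(indir / config.counts, samples=samples)
    loci, mirna_flags = read_locus_table(indir / config.loci)
    dmrs = None
    if config.dmrs and (indir / config.dmrs).exists():
        dmrs = read_dmrs(indir / config.dmrs)
    degs = None
    if config.degs and (indir / config.degs).exists():
        degs = read_degs(indir / config.degs)
    log("load", len(matrix.counts), len(loci))

    # ---- classify ------------------------------------------------------
    class_rows = []
    for locus in loci:
        cls = classify_mod.classify_locus(locus.profile, mirna_flags.get(locus.id, False))
        ctx = classify_mod.annotate_context(locus.interval, features, config.near_bp)
        class_rows.append(
            {
                "locus_id": locus.id,
                "label": cls.label,
                "stratum": cls.stratum,
                "dicer_fraction": cls.dicer_fraction,
                "length": locus.length,
                "chrom": locus.interval.chrom,
                "start": locus.interval.start,
                "end": locus.interval.end,
                "overlaps_cds": ctx.overlaps_cds,
                "overlaps_te": ctx.overlaps_te,
                "distance_class": ctx.distance_class,
                "nearest_gene_id": ctx.nearest_gene_id,
                "nearest_gene_distance": ctx.nearest_gene_distance,
            }
        )
    classified = pd.DataFrame(class_rows)
    classified.to_csv(outdir / "classified.tsv", sep="\t", index=False)
    log("classify", len(loci), len(classified))

    # ---- table 1 summary ----------------------------------------------
    table1 = summarize_table1(classified, matrix)
    table1.to_csv(outdir / "table1.tsv", sep="\t", index=False)

    # ---- differential abundance ---------------------------------------
    filtered = diffabund.filter_rpm(matrix, config.min_rpm)
    strata = dict(zip(classified["locus_id"], classified["stratum"]))
    tested = filtered.counts.index.intersection(classified["locus_id"])
    filtered = CountMatrix(
        counts=filtered.counts.loc[tested], samples=filtered.samples
    )
    results = diffabund.run_contrasts(filtered, strata, list(config.contrasts))
    for name, df in results.items():
        write_results(outdir / f"results_{name}.tsv", df)
    log("diffabund", len(matrix.counts), len(filtered.counts))

    # ---- associations --------------------------------------------------
    report: list[assoc_mod.AssociationResult] = []
    by_class = classified.set_index("locus_id")

    def lfc_of(contrast: str) -> pd.Series:
        df = results[contrast]
        return df.set_index("locus_id")["lfc"]

    nd_ids = by_class.index[by_class["label"] == "ndsRNA"]

    # LFC correlations among nd-sRNA loci, across tissues and generations
    pairs = [
        ("parent_1h_leaf2", "parent_72h_leaf2"),
        ("parent_72h_leaf2", "parent_72h_leaf3"),
        ("parent_72h_leaf2", "offspring_leaf2"),
    ]
    for a, b in pairs:
        if a in results and b in results:
            la, lb = lfc_of(a), lfc_of(b)
            shared = la.index.intersection(lb.index).intersection(nd_ids)
            if len(shared) >= 3:
                report.append(
                    assoc_mod.lfc_correlation(
                        la[shared], lb[shared], name=f"lfc_correlation[nd:{a}~{b}]"
                    )
                )

    # the most wound-responsive nd-sRNA set: offspring response summary + joint model
    if {"parent_72h_leaf2", "parent_72h_leaf3", "offspring_leaf2"} <= set(results):
        l2 = lfc_of("parent_72h_leaf2")
        l3 = lfc_of("parent_72h_leaf3")
        lo = lfc_of("offspring_leaf2")
        shared = l2.index.intersection(l3.index).intersection(lo.index).intersection(nd_ids)
        top = l2[shared].sort_values(ascending=False).head(config.top_trf_n).index
        if len(top) >= 10:
            report.append(
                assoc_mod.one_sample_t_values(
                    lo[top], name="offspring_lfc_t[top_nd_72h]"
                )
            )
            report.append(
                assoc_mod.offspring_lfc_model(l2[top], l3[top], lo[top])
            )

    # DMR association battery
    if dmrs:
        intervals = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in by_class.reset_index().itertuples(index=False)
        ]
        near = assoc_mod.nearest_dmr(intervals, dmrs)
        near.index = by_class.index
        non_mirna = by_class["label"] != "miRNA"
        ldf = pd.DataFrame(
            {
                "overlaps_dmr": (near["distance"] == 0).astype(int),
                "length": by_class["length"],
                "distance_class": by_class["distance_class"],
                "srna_class": np.where(
                    by_class["label"].str.startswith("siRNA"), "dicer", "ndsRNA"
                ),
            }
        )[non_mirna]
        for name, res in assoc_mod.dmr_overlap_logistic(ldf).items():
            report.append(res)

        # DMR direction by realized overlap group
        locus_pairs = [
            (
                GenomicInterval(r.chrom, r.start, r.end),
                _dicer_group(r.label),
            )
            for r in by_class.reset_index().itertuples(index=False)
        ]
        arrays = assoc_mod.build_locus_arrays(locus_pairs)
        groups, directions = [], []
        for d in dmrs:
            g = assoc_mod.overlap_group(d.interval, locus_pairs, window=0, arrays=arrays)
            groups.append(g if g in ("siRNA", "ndsRNA") else "none")
            directions.append(d.direction)
        report.append(assoc_mod.direction_chisq(groups, directions))

        # LFC vs nearest-DMR direction within the window, per class & contrast
        within = near["distance"] <= config.dmr_window
        for contrast in ("parent_1h_leaf2", "parent_72h_leaf2", "parent_72h_leaf3"):
            if contrast not in results:
                continue
            lfc = lfc_of(contrast)
            for group in ("siRNA", "ndsRNA"):
                sel = (
                    within
                    & (by_class["label"].map(_dicer_group) == group)
                    & by_class.index.isin(lfc.index)
                )
                ids = by_class.index[sel]
                if len(ids) >= 10:
                    report.append(
                        assoc_mod.lfc_vs_direction_glm(
                            lfc[ids],
                            near.loc[ids, "direction"],
                            name=f"lfc_vs_dmr_direction[{group}:{contrast}]",
                        )
                    )
    else:
        report.append(_skipped("dmr_association", "no DMR table supplied"))

    # DEG association battery
    if degs:
        gene_iv = {g.id: g.interval for g in features.genes}
        locus_pairs = [
            (GenomicInterval(r.chrom, r.start, r.end), _dicer_group(r.label))
            for r in by_class.reset_index().itertuples(index=False)
        ]
        arrays = assoc_mod.build_locus_arrays(locus_pairs)
        rows = []
        for d in degs:
            iv = gene_iv.get(d.gene_id)
            if iv is None:
                continue
            grp = assoc_mod.overlap_group(iv, locus_pairs, window=config.near_bp, arrays=arrays)
            rows.append(
                {
                    "gene_id": d.gene_id,
                    "direction": d.direction,
                    "log_expr": np.log10(max(d.mean_expression, 1e-6)),
                    "overlap_class": grp if grp in ("siRNA", "ndsRNA") else "none",
                }
            )
        gdf = pd.DataFrame(rows)
        report.append(
            assoc_mod.deg_overlap_rate(
                gdf["direction"] != "none", gdf["overlap_class"] != "none"
            )
        )
        de_only = gdf[gdf["direction"] != "none"]
        if de_only["direction"].nunique() == 2 and len(de_only) >= 20:
            for name, res in assoc_mod.direction_by_class_expression_model(
                de_only["direction"], de_only["log_expr"], de_only["overlap_class"]
            ).items():
                report.append(res)
    else:
        report.append(_skipped("deg_association", "no DEG table supplied"))

    # class ANOVAs on abundance and length
    mean_rpm = matrix.mean_rpm()
    adf = classified[classified["locus_id"].map(mean_rpm) > 0]
    if adf["label"].nunique() >= 2:
        report.append(
            assoc_mod.class_anova(
                np.log10(adf["locus_id"].map(mean_rpm)),
                adf["label"],
                name="class_anova[log10_rpm]",
            )
        )
        report.append(
            assoc_mod.class_anova(adf["length"], adf["label"], name="class_anova[length]")
        )
    log("assoc", len(report), len(report))

    # ---- write report --------------------------------------------------
    rows = []
    for res in report:
        row = res.to_row()
        row["estimates"] = json.dumps(row["estimates"], sort_keys=True)
        rows.append(row)
    report_df = pd.DataFrame(rows)
    report_df.to_csv(outdir / "assoc_report.tsv", sep="\t", index=False)

    with open(outdir / "config_echo.yaml", "w") as fh:
        cfg = dataclasses.asdict(config)
        cfg["contrasts"] = list(cfg["contrasts"])
        yaml.safe_dump(cfg, fh, sort_keys=True)
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    return {
        "classified": classified,
        "table1": table1,
        "results": results,
        "report": report_df,
        "log": log_lines,
    }
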