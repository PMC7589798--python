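"""Association models linking sRNA loci to transgenerational plasticity.

The models here relate per-locus wound-response log fold changes (LFCs)
and locus classes to (a) each other across tissues and generations, and
(b) externally supplied tables of differentially methylated regions (DMRs)
and differentially expressed genes (DEGs) from progeny of wounded plants:

* Pearson correlations and one-sample t summaries of LFC vectors;
* OLS of offspring LFC on the wounded (2nd-leaf) and systemic (3rd-leaf)
  parental LFCs;
* logistic regression of DMR overlap on locus size, gene-distance class
  and dicer status, with per-term likelihood-ratio chi-squares;
* contingency chi-square of DMR methylation direction by overlap group;
* linear models of LFC against the direction of the nearest DMR within a
  20 kb window;
* 2x2 DEG rate contrast, a binomial GLM of DEG direction on expression and
  overlap class, and factorial OLS models of sRNA LFC against mRNA change
  by locus type (Type-II sums of squares by default);
* hypergeometric LFC-tail outlier enrichment and one-way class ANOVAs.

Standard fits go through statsmodels/scipy; per-term likelihood-ratio
statistics are formed by explicit drop-one refits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_formats import DMRRecord, GenomicInterval

DMR_WINDOW = 20_000
GENE_WINDOW = 5_000
DEFAULT_TAIL_Q = 0.05


@dataclass
class AssociationResult:
    """One named statistical test: statistic, df, p and effect estimates."""

    test_name: str
    statistic: float
    df: tuple[int, ...] | int
    p: float
    estimates: dict[str, tuple[float, float]] = field(default_factory=dict)
    n: int = 0
    note: str = ""

    def to_row(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "df": str(self.df),
            "p": self.p,
            "n": self.n,
            "estimates": {k: list(v) for k, v in self.estimates.items()},
            "note": self.note,
        }


# ---------------------------------------------------------------------------
# LFC correlations and t summaries
# ---------------------------------------------------------------------------


def lfc_correlation(
    lfc_a: Sequence[float], lfc_b: Sequence[float], name: str = "lfc_correlation"
) -> AssociationResult:
    """Pearson correlation of two LFC vectors with t = r·sqrt(n−2)/sqrt(1−r²)."""
    a = np.asarray(lfc_a, dtype=float)
    b = np.asarray(lfc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("LFC vectors must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    a_c = a - a.mean()
    b_c = b - b.mean()
    denom = math.sqrt(float(a_c @ a_c) * float(b_c @ b_c))
    if denom == 0:
        raise ValueError("zero variance in an LFC vector")
    r = float(a_c @ b_c) / denom
    if abs(r) >= 1.0:
        t = math.copysign(math.inf, r)
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return AssociationResult(
        name, t, n - 2, p, estimates={"r": (r, float("nan"))}, n=n
    )


def one_sample_t(mean: float, sd: float, n: int, name: str = "one_sample_t") -> AssociationResult:
    """One-sample t statistic from summary values: t = mean/(sd/sqrt(n))."""
    if n < 2 or sd <= 0:
        raise ValueError("need n ≥ 2 and sd > 0")
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return AssociationResult(name, t, n - 1, p, estimates={"mean": (mean, sd / math.sqrt(n))}, n=n)


def one_sample_t_values(values: Sequence[float], name: str = "one_sample_t") -> AssociationResult:
    """Raw-vector variant of :func:`one_sample_t`."""
    x = np.asarray(values, dtype=float)
    return one_sample_t(float(x.mean()), float(x.std(ddof=1)), x.size, name=name)


def offspring_lfc_model(
    lfc_2nd: Sequence[float],
    lfc_3rd: Sequence[float],
    lfc_offspring: Sequence[float],
) -> AssociationResult:
    """OLS of offspring LFC on the wounded 2nd-leaf and systemic 3rd-leaf LFCs."""
    X = np.column_stack(
        [np.ones(len(lfc_2nd)), np.asarray(lfc_2nd, float), np.asarray(lfc_3rd, float)]
    )
    y = np.asarray(lfc_offspring, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: the parental LFC predictors are collinear")
    fit = sm.OLS(y, X).fit()
    est = {
        "intercept": (float(fit.params[0]), float(fit.bse[0])),
        "lfc_2nd": (float(fit.params[1]), float(fit.bse[1])),
        "lfc_3rd": (float(fit.params[2]), float(fit.bse[2])),
        "p_lfc_2nd": (float(fit.pvalues[1]), float("nan")),
        "p_lfc_3rd": (float(fit.pvalues[2]), float("nan")),
    }
    return AssociationResult(
        "offspring_lfc_model",
        float(fit.fvalue),
        (int(fit.df_model), int(fit.df_resid)),
        float(fit.f_pvalue),
        estimates=est,
        n=len(y),
    )


# ---------------------------------------------------------------------------
# Interval helpers shared by the DMR/DEG models
# ---------------------------------------------------------------------------


def _gap_to_set(
    interval: GenomicInterval, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    return np.maximum(np.maximum(starts - interval.end, interval.start - ends), 0)


def nearest_dmr(
    intervals: Sequence[GenomicInterval], dmrs: Sequence[DMRRecord]
) -> pd.DataFrame:
    """Distance to, and direction of, the nearest DMR for each interval.

    Rows with no DMR on the interval's chromosome get distance NaN.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[DMRRecord]]] = {}
    for d in dmrs:
        by_chrom.setdefault(d.interval.chrom, ([], [], []))  # type: ignore[arg-type]
    grouped: dict[str, list[DMRRecord]] = {}
    for d in dmrs:
        grouped.setdefault(d.interval.chrom, []).append(d)
    arrays = {
        chrom: (
            np.array([d.interval.start for d in ds]),
            np.array([d.interval.end for d in ds]),
            ds,
        )
        for chrom, ds in grouped.items()
    }
    rows = []
    for iv in intervals:
        if iv.chrom not in arrays:
            rows.append({"distance": np.nan, "direction": None})
            continue
        starts, ends, ds = arrays[iv.chrom]
        gaps = _gap_to_set(iv, starts, ends)
        i = int(np.argmin(gaps))
        rows.append({"distance": int(gaps[i]), "direction": ds[i].direction})
    return pd.DataFrame(rows)


def overlap_group(
    gene_interval: GenomicInterval,
    loci: Sequence[tuple[GenomicInterval, str]],
    window: int = GENE_WINDOW,
    arrays: dict | None = None,
) -> str:
    """Class of the nearest sRNA locus within `window` bp: siRNA/ndsRNA/none.

    `loci` pairs each locus interval with its dicer grouping ("siRNA" for
    any dicer size class, "ndsRNA" otherwise).  When both classes qualify,
    the nearer locus wins.
    """
    if arrays is None:
        arrays = build_locus_arrays(loci)
    if gene_interval.chrom not in arrays:
        return "none"
    starts, ends, labels = arrays[gene_interval.chrom]
    gaps = _gap_to_set(gene_interval, starts, ends)
    within = gaps <= window
    if not within.any():
        return "none"
    i = int(np.argmin(np.where(within, gaps, np.inf)))
    return labels[i]


def build_locus_arrays(loci: Sequence[tuple[GenomicInterval, str]]) -> dict:
    arrays: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    grouped: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for iv, label in loci:
        grouped.setdefault(iv.chrom, []).append((iv, label))
    for chrom, pairs in grouped.items():
        arrays[chrom] = (
            np.array([p[0].start for p in pairs]),
            np.array([p[0].end for p in pairs]),
            [p[1] for p in pairs],
        )
    return arrays


# ---------------------------------------------------------------------------
# DMR models
# ---------------------------------------------------------------------------


def _binomial_lr_terms(
    y: np.ndarray,
    blocks: dict[str, np.ndarray],
    test_prefix: str,
    n: int,
) -> dict[str, AssociationResult]:
    """Fit a binomial GLM and LR-test each term by a drop-one refit."""
    X_full = np.column_stack([np.ones(len(y)), *blocks.values()])
    if len(np.unique(y)) < 2:
        res = AssociationResult(
            f"{test_prefix}[degenerate]", math.nan, 0, math.nan, n=n,
            note="degenerate: response is constant (complete overlap or none)",
        )
        return {"full": res}
    full = sm.GLM(y, X_full, family=sm.families.Binomial()).fit(maxiter=200)
    out: dict[str, AssociationResult] = {}
    note = ""
    if np.any(np.abs(full.params) > 25):
        note = "possible complete separation; estimates unstable"
    col_starts: dict[str, tuple[int, int]] = {}
    pos = 1
    for name, block in blocks.items():
        width = block.shape[1] if block.ndim == 2 else 1
        col_starts[name] = (pos, pos + width)
        pos += width
    for name in blocks:
        keep = [
            b for other, b in blocks.items() if other != name
        ]
        X_red = np.column_stack([np.ones(len(y)), *keep]) if keep else np.ones((len(y), 1))
        red = sm.GLM(y, X_red, family=sm.families.Binomial()).fit(maxiter=200)
        df_term = X_full.shape[1] - X_red.shape[1]
        stat = max(0.0, 2.0 * (full.llf - red.llf))
        lo, hi = col_starts[name]
        est = {
            f"{name}_{j}": (float(full.params[i]), float(full.bse[i]))
            for j, i in enumerate(range(lo, hi))
        }
        out[name] = AssociationResult(
            f"{test_prefix}[{name}]",
            stat,
            df_term,
            float(stats.chi2.sf(stat, df_term)),
            estimates=est,
            n=n,
            note=note,
        )
    out["full"] = AssociationResult(
        f"{test_prefix}[full]", float(full.llf), X_full.shape[1], math.nan, n=n, note=note
    )
    return out


def dmr_overlap_logistic(loci: pd.DataFrame) -> dict[str, AssociationResult]:
    """Logistic regression of DMR overlap on locus size, position and class.

    `loci` columns: ``overlaps_dmr`` (0/1), ``length`` (bp),
    ``distance_class`` (O/N/F), ``srna_class`` ("dicer"/"ndsRNA").
    Each term is tested by a likelihood-ratio chi-square from a drop-one
    refit; a constant response is returned flagged, not raised.
    """
    y = loci["overlaps_dmr"].to_numpy(dtype=float)
    n = len(loci)
    log_len = np.log(loci["length"].to_numpy(dtype=float))
    dc = pd.get_dummies(
        pd.Categorical(loci["distance_class"], categories=["O", "N", "F"]),
        drop_first=True,
    ).to_numpy(dtype=float)
    dicer = (loci["srna_class"].astype(str) != "ndsRNA").to_numpy(dtype=float)
    blocks = {
        "log_length": log_len[:, None],
        "distance_class": dc,
        "srna_class": dicer[:, None],
    }
    return _binomial_lr_terms(y, blocks, "dmr_overlap_logistic", n)


def direction_chisq(
    overlap_groups: Sequence[str], directions: Sequence[str]
) -> AssociationResult:
    """Chi-square of DMR methylation direction by sRNA-overlap group.

    Builds the (group × up/down) contingency table over the groups present
    (none/siRNA/ndsRNA order), without continuity correction, and reports
    the per-group up-methylated proportions.
    """
    g = pd.Categorical(overlap_groups, categories=["none", "siRNA", "ndsRNA"])
    d = pd.Categorical(directions, categories=["up", "down"])
    table = pd.crosstab(g, d, dropna=False)
    table = table.loc[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        raise ValueError("need at least two overlap groups with observations")
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    est = {}
    for grp in table.index:
        row = table.loc[grp]
        est[f"up_prop_{grp}"] = (float(row["up"] / row.sum()), float("nan"))
    return AssociationResult(
        "direction_chisq", float(chi2), int(df), float(p), estimates=est, n=int(table.to_numpy().sum())
    )


def lfc_vs_direction_glm(
    lfc: Sequence[float], direction: Sequence[str], name: str = "lfc_vs_direction"
) -> AssociationResult:
    """Linear model of sRNA LFC on the nearest-DMR methylation direction.

    Callers filter to loci within the 20 kb DMR window (and per locus
    class) before invoking; the F-test here is the single-factor ANOVA of
    LFC by up/down direction.
    """
    y = np.asarray(lfc, dtype=float)
    up = np.asarray([1.0 if d == "up" else 0.0 for d in direction])
    if len(np.unique(up)) < 2:
        return AssociationResult(
            name, math.nan, (0, len(y)), math.nan, n=len(y),
            note="degenerate: only one methylation direction present",
        )
    X = np.column_stack([np.ones_like(up), up])
    fit = sm.OLS(y, X).fit()
    f = float(fit.fvalue)
    return AssociationResult(
        name,
        f,
        (int(fit.df_model), int(fit.df_resid)),
        float(fit.f_pvalue),
        estimates={"direction_up": (float(fit.params[1]), float(fit.bse[1]))},
        n=len(y),
    )


# ---------------------------------------------------------------------------
# DEG models
# ---------------------------------------------------------------------------


def deg_overlap_rate(
    is_de: Sequence[bool], overlaps_srna: Sequence[bool]
) -> AssociationResult:
    """2×2 chi-square of gene DE status by sRNA-locus overlap (within 5 kb).

    Reports the DE rate with and without overlap and the odds ratio ad/bc.
    """
    de = np.asarray(is_de, dtype=bool)
    ov = np.asarray(overlaps_srna, dtype=bool)
    a = int(np.sum(de & ov))
    b = int(np.sum(~de & ov))
    c = int(np.sum(de & ~ov))
    d = int(np.sum(~de & ~ov))
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        raise ValueError("degenerate 2x2 table (an empty row or column)")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    est = {
        "rate_overlap": (a / (a + b), float("nan")),
        "rate_background": (c / (c + d), float("nan")),
        "odds_ratio": (float(odds), float("nan")),
    }
    return AssociationResult(
        "deg_overlap_rate", float(chi2), int(df), float(p), estimates=est, n=int(table.sum())
    )


def direction_by_class_expression_model(
    direction: Sequence[str],
    log_mean_expression: Sequence[float],
    overlap_class: Sequence[str],
) -> dict[str, AssociationResult]:
    """Binomial GLM of DEG direction on log expression and sRNA overlap class.

    Only up/down genes enter (non-DE genes carry no direction).  The class
    factor {none, siRNA, ndsRNA} contributes 2 df; when a single class is
    present the term is dropped with a warning rather than an error.
    """
    d = np.asarray(direction)
    keep = np.isin(d, ["up", "down"])
    d = d[keep]
    y = (d == "up").astype(float)
    x = np.asarray(log_mean_expression, dtype=float)[keep]
    cls = pd.Categorical(
        np.asarray(overlap_class)[keep], categories=["none", "siRNA", "ndsRNA"]
    )
    blocks: dict[str, np.ndarray] = {"log_expression": x[:, None]}
    present = [c for c in cls.categories if (cls == c).sum() > 0]
    if len(present) >= 2:
        dummies = pd.get_dummies(cls.remove_unused_categories(), drop_first=True)
        blocks["overlap_class"] = dummies.to_numpy(dtype=float)
    else:
        warnings.warn("single overlap class present; class term dropped", stacklevel=2)
    return _binomial_lr_terms(y, blocks, "deg_direction_model", int(y.size))


def table2_model(
    data: pd.DataFrame, ss_type: int = 2
) -> dict[str, AssociationResult]:
    """Factorial OLS of sRNA LFC on mRNA transgenerational change × locus type.

    `data` columns: ``lfc``, ``mrna_change`` (up/none/down), ``srna_type``
    (siRNA/ndsRNA).  Terms: mRNA change (2 df), sRNA type (1 df), their
    interaction (2 df), with partial (Type-II) sums of squares by default;
    ``ss_type=1`` gives sequential SS.  Fit separately per proximity subset
    by the caller.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    df = data.copy()
    df["mrna_change"] = pd.Categorical(df["mrna_change"], categories=["down", "none", "up"])
    df["srna_type"] = pd.Categorical(df["srna_type"], categories=["siRNA", "ndsRNA"])
    fit = ols("lfc ~ C(mrna_change) * C(srna_type)", data=df).fit()
    table = anova_lm(fit, typ=ss_type)
    rename = {
        "C(mrna_change)": "mrna_tgen_change",
        "C(srna_type)": "srna_type",
        "C(mrna_change):C(srna_type)": "interaction",
    }
    out: dict[str, AssociationResult] = {}
    resid_df = int(table.loc["Residual", "df"])
    for raw, name in rename.items():
        row = table.loc[raw]
        out[name] = AssociationResult(
            f"table2[{name}]",
            float(row["F"]),
            (int(row["df"]), resid_df),
            float(row["PR(>F)"]),
            estimates={"SS": (float(row["sum_sq"]), float("nan"))},
            n=len(df),
        )
    out["full"] = AssociationResult(
        "table2[full]",
        float(fit.fvalue),
        (int(fit.df_model), int(fit.df_resid)),
        float(fit.f_pvalue),
        n=len(df),
    )
    return out


# ---------------------------------------------------------------------------
# Outlier enrichment and class ANOVA
# ---------------------------------------------------------------------------


def outlier_enrichment(
    lfc: Sequence[float],
    membership: Sequence[bool],
    tail_q: float = DEFAULT_TAIL_Q,
    side: str = "upper",
) -> AssociationResult:
    """Hypergeometric enrichment of an annotation among LFC-tail loci.

    The tail is the upper (or lower) ``tail_q`` quantile of the LFC vector;
    the p-value is the hypergeometric upper tail of the member count among
    tail loci against all tested loci.  This is a hypergeometric surrogate
    for rank-based outlier enrichment recipes, and is labelled as such.
    """
    if side not in ("upper", "lower"):
        raise ValueError("side must be 'upper' or 'lower'")
    x = np.asarray(lfc, dtype=float)
    member = np.asarray(membership, dtype=bool)
    N = x.size
    if N == 0 or member.size != N:
        raise ValueError("lfc and membership must be equal-length and non-empty")
    k_tail = max(1, int(math.ceil(tail_q * N)))
    order = np.argsort(x, kind="mergesort")
    tail_idx = order[-k_tail:] if side == "upper" else order[:k_tail]
    K = int(member.sum())
    k = int(member[tail_idx].sum())
    p = float(stats.hypergeom.sf(k - 1, N, K, k_tail))
    expected = k_tail * K / N
    return AssociationResult(
        "lfc_outlier_enrichment_hypergeom",
        float(k),
        (k_tail, K),
        p,
        estimates={
            "members_in_tail": (float(k), float("nan")),
            "expected_in_tail": (float(expected), float("nan")),
        },
        n=N,
    )


def class_anova(
    values: Sequence[float], labels: Sequence[str], name: str = "class_anova"
) -> AssociationResult:
    """One-way ANOVA of a per-locus quantity (length, log rpm, ...) by class."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = [v[lab == g] for g in pd.unique(lab)]
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA needs at least two groups (between-group df would be 0)")
    f, p = stats.f_oneway(*groups)
    n = v.size
    est = {f"mean_{g}": (float(v[lab == g].mean()), float("nan")) for g in pd.unique(lab)}
    return AssociationResult(name, float(f), (k - 1, n - k), float(p), estimates=est, n=n)
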