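"""Cross-layer correlation screens linking microbiota, genes and weight.

The central idea: across diets, the microbiota-attributable shift in a
gene's expression (ΔGEL = mean FMT − mean GF, per diet) should track
the microbiota-attributable shift in body weight (ΔBW) if the gene
mediates microbiome-driven weight regulation. Genes are screened by
Pearson correlation against both ΔBW measures over the diet panel and
selected when either |r| reaches the threshold (inclusive at the
two-decimal precision the screen reports, so a printed 0.70 selects).

Two further screens place taxa in the chain: per-diet mean relative
abundance (FMT mice only) against each selected gene's ΔGEL (counting
genes with |r| above a stricter threshold, default 0.8), and simple
regression of individual FMT mouse body weight on taxon abundance,
summarised by R². Both operate at any taxonomic rank via count
aggregation over the lineage map.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from gutlink.errors import InputError, UndefinedCorrelationError
from gutlink.growth import END_WEEK, DietContrast
from gutlink.stats import ols_line, pearson
from gutlink.synthetic import RANKS

__all__ = [
    "compute_delta_gel",
    "gene_weight_screen",
    "select_by_threshold",
    "taxon_gene_screen",
    "taxon_bw_regression",
    "aggregate_rank",
    "relative_abundance",
]

log = logging.getLogger(__name__)

GENE_R_SELECT = 0.70
TAXON_R_SELECT = 0.8


# ---------------------------------------------------------------------------
# ΔGEL


def compute_delta_gel(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    diets: list[str] | None = None,
) -> pd.DataFrame:
    """Per-diet microbiota-attributable expression shift, genes × diets.

    ΔGEL(g, d) = mean over FMT samples − mean over GF samples of gene g
    in diet d, on the input expression scale (no log). Diets missing
    either colonization group yield an all-NaN column; genes with any
    NaN are dropped later by the screen.
    """
    if diets is None:
        diets = list(pd.unique(metadata["diet"]))
    out = pd.DataFrame(index=expr.index, columns=diets, dtype=float)
    for diet in diets:
        cell = metadata[metadata["diet"] == diet]
        means = {}
        for colonization in ("GF", "FMT"):
            mice = cell.loc[cell["colonization"] == colonization, "mouse_id"]
            cols = [m for m in mice if m in expr.columns]
            if not cols:
                log.warning("diet %s lacks %s samples; ΔGEL undefined", diet, colonization)
                means = None
                break
            means[colonization] = expr[cols].mean(axis=1)
        if means is None:
            out[diet] = np.nan
        else:
            out[diet] = means["FMT"] - means["GF"]
    return out


# ---------------------------------------------------------------------------
# gene–weight screen


def select_by_threshold(
    r_abs: float, r_slope: float, r_select: float = GENE_R_SELECT
) -> bool:
    """Selection rule: max(|r_abs|, |r_slope|) ≥ r_select, inclusive at
    the two-decimal precision the screen's tables print."""
    return max(round(abs(r_abs), 2), round(abs(r_slope), 2)) >= round(r_select, 2)


def gene_weight_screen(
    delta_gel: pd.DataFrame,
    contrasts: list[DietContrast] | pd.DataFrame,
    r_select: float = GENE_R_SELECT,
) -> pd.DataFrame:
    """Correlate each gene's ΔGEL with both ΔBW measures across diets.

    Returns a frame (gene, r_abs, p_abs, r_slope, p_slope, selected)
    with n = number of diets pairs per correlation. Genes with an
    undefined diet (NaN) or zero ΔGEL variance are excluded with a
    logged reason.
    """
    if isinstance(contrasts, pd.DataFrame):
        cframe = contrasts
    else:
        cframe = pd.DataFrame(
            {
                "diet": [c.diet for c in contrasts],
                "delta_bw_abs": [c.delta_bw_abs for c in contrasts],
                "delta_bw_slope": [c.delta_bw_slope for c in contrasts],
            }
        )
    diets = [d for d in delta_gel.columns if d in set(cframe["diet"])]
    if len(diets) < 3:
        raise InputError(f"need >= 3 usable diets, have {len(diets)}")
    cvec = cframe.set_index("diet").loc[diets]
    bw_abs = cvec["delta_bw_abs"].to_numpy(dtype=float)
    bw_slope = cvec["delta_bw_slope"].to_numpy(dtype=float)

    rows = []
    for gene, row in delta_gel[diets].iterrows():
        vals = row.to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            log.info("gene %s: ΔGEL undefined in some diet; excluded", gene)
            continue
        try:
            ca = pearson(vals, bw_abs)
            cs = pearson(vals, bw_slope)
        except UndefinedCorrelationError as exc:
            log.info("gene %s excluded: %s", gene, exc)
            continue
        rows.append(
            {
                "gene": gene,
                "n_diets": len(diets),
                "r_abs": ca.r,
                "p_abs": ca.p_two_sided,
                "r_slope": cs.r,
                "p_slope": cs.p_two_sided,
                "selected": select_by_threshold(ca.r, cs.r, r_select),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "n_diets", "r_abs", "p_abs", "r_slope", "p_slope", "selected"]
    )


# ---------------------------------------------------------------------------
# taxon aggregation and abundance summaries


def aggregate_rank(
    abundance: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum counts over taxa sharing the label at ``rank``.

    Taxa without a lineage entry at the rank are pooled into
    ``unclassified``. Column (per-sample) sums are conserved exactly.
    """
    if rank not in RANKS:
        raise InputError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = taxonomy.set_index("taxon_id")[rank].reindex(abundance.index)
    labels = labels.fillna("unclassified").replace("", "unclassified")
    out = abundance.groupby(labels.to_numpy()).sum()
    out.index.name = rank
    return out


def relative_abundance(abundance: pd.DataFrame) -> pd.DataFrame:
    """Column-wise closure to proportions; all-zero samples stay zero."""
    totals = abundance.sum(axis=0)
    safe = totals.replace(0, np.nan)
    return abundance.div(safe, axis=1).fillna(0.0)


def _fmt_columns(abundance: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    fmt_mice = metadata.loc[metadata["colonization"] == "FMT", "mouse_id"]
    cols = [m for m in fmt_mice if m in abundance.columns]
    if not cols:
        raise InputError("no FMT samples found in abundance table")
    return abundance[cols]


def _diet_means(
    rel: pd.DataFrame, metadata: pd.DataFrame, diets: list[str]
) -> pd.DataFrame:
    meta = metadata.set_index("mouse_id")
    out = pd.DataFrame(index=rel.index, columns=diets, dtype=float)
    for diet in diets:
        cols = [c for c in rel.columns if meta.loc[c, "diet"] == diet]
        if not cols:
            raise InputError(f"no FMT abundance samples in diet {diet!r}")
        out[diet] = rel[cols].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# taxon–gene screen


def taxon_gene_screen(
    abundance: pd.DataFrame,
    taxonomy: pd.DataFrame,
    metadata: pd.DataFrame,
    selected_delta_gel: pd.DataFrame,
    rank: str = "species",
    r_select: float = TAXON_R_SELECT,
) -> pd.DataFrame:
    """Count, per taxon, the selected genes whose ΔGEL it tracks.

    Abundance is aggregated to ``rank``, closed to relative abundance
    per sample, averaged per diet over FMT mice, and correlated with
    each selected gene's ΔGEL across diets; genes with |r| > r_select
    (strict) are counted. Result is sorted by gene_count descending.
    """
    if selected_delta_gel.empty:
        raise InputError("selected gene set is empty")
    diets = list(selected_delta_gel.columns)
    fmt = _fmt_columns(abundance, metadata)
    at_rank = aggregate_rank(fmt, taxonomy, rank)
    at_rank = at_rank.loc[at_rank.sum(axis=1) > 0]
    rel = relative_abundance(at_rank)
    means = _diet_means(rel, metadata, diets)

    rows = []
    for taxon, avec in means.iterrows():
        a = avec.to_numpy(dtype=float)
        correlated: dict[str, float] = {}
        try:
            for gene, gvec in selected_delta_gel.iterrows():
                res = pearson(a, gvec.to_numpy(dtype=float))
                if abs(res.r) > r_select:
                    correlated[str(gene)] = res.r
        except UndefinedCorrelationError as exc:
            log.info("taxon %s excluded: %s", taxon, exc)
            continue
        rows.append(
            {
                "taxon": taxon,
                "rank": rank,
                "gene_count": len(correlated),
                "correlated_genes": ",".join(sorted(correlated)),
                "mean_abundance": float(a.mean()),
            }
        )
    out = pd.DataFrame(
        rows, columns=["taxon", "rank", "gene_count", "correlated_genes", "mean_abundance"]
    )
    return out.sort_values(
        ["gene_count", "taxon"], ascending=[False, True], ignore_index=True
    )


# ---------------------------------------------------------------------------
# taxon–body-weight regression


def taxon_bw_regression(
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    growth: pd.DataFrame,
    taxonomy: pd.DataFrame,
    rank: str = "species",
    week: int = END_WEEK,
) -> pd.DataFrame:
    """Regress individual FMT body weight on taxon relative abundance.

    One point per FMT mouse: (relative abundance of the taxon in that
    mouse's sample, its week-``week`` body weight). Returns slope,
    intercept and R² (= squared Pearson r) per taxon at ``rank``;
    constant-abundance taxa are excluded.
    """
    fmt = _fmt_columns(abundance, metadata)
    bw = (
        growth[growth["week"] == week]
        .set_index("mouse_id")["bw_g"]
        .reindex(fmt.columns)
    )
    if bw.isna().any():
        missing = list(bw.index[bw.isna()])
        raise InputError(f"missing week-{week} body weight for mice {missing}")
    if len(bw) < 3:
        raise InputError("need at least 3 FMT mice")
    at_rank = aggregate_rank(fmt, taxonomy, rank)
    at_rank = at_rank.loc[at_rank.sum(axis=1) > 0]
    rel = relative_abundance(at_rank)
    y = bw.to_numpy(dtype=float)

    rows = []
    for taxon, avec in rel.iterrows():
        x = avec.to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            log.info("taxon %s has constant abundance; R² undefined, excluded", taxon)
            continue
        slope, intercept, _, _ = ols_line(x, y)
        try:
            r = pearson(x, y).r
        except UndefinedCorrelationError:
            continue
        rows.append(
            {
                "taxon": taxon,
                "rank": rank,
                "slope": slope,
                "intercept": intercept,
                "r_squared": r * r,
            }
        )
    return pd.DataFrame(
        rows, columns=["taxon", "rank", "slope", "intercept", "r_squared"]
    ).sort_values("r_squared", ascending=False, ignore_index=True)
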