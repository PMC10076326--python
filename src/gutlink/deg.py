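"""Differential-expression screen between GF and FMT mice.

Per tissue×diet cell, genes are tested with a Welch t test on
log2(value + 1) and filtered with the screen's criteria p < 0.05 and
fold change > 1 — i.e. |log2FC| > 0, any directional difference.
Benjamini–Hochberg q-values are reported per cell but do not gate the
filter (the screen thresholds raw p). The cross-diet and cross-tissue
intersections then identify genes whose response to colonization is
shared across all diets (per tissue) or across all tissues (per diet).

The negative-binomial count model some pipelines use for this step is
deliberately replaced by the Welch test on the log scale: the screen's
contribution is the threshold-and-intersect logic, not the two-group
test behind it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gutlink.errors import InputError
from gutlink.stats import bh_adjust, welch_test

__all__ = ["call_degs", "call_all_degs", "intersect_degs", "IntersectionReport"]

log = logging.getLogger(__name__)

PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class IntersectionReport:
    """Genes shared across all diets (per tissue) and all tissues (per diet).

    Intersections over incomplete families (a missing tissue×diet cell)
    are undefined and stored as ``None``, never silently empty.
    """

    per_tissue: dict[str, set[str] | None]
    per_diet: dict[str, set[str] | None]
    per_tissue_counts: dict[str, int | None] = field(default_factory=dict)
    per_diet_counts: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "per_tissue_counts",
            {k: (None if v is None else len(v)) for k, v in self.per_tissue.items()},
        )
        object.__setattr__(
            self,
            "per_diet_counts",
            {k: (None if v is None else len(v)) for k, v in self.per_diet.items()},
        )


def call_degs(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    tissue: str,
    diet: str,
    p_threshold: float = 0.05,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Screen one tissue×diet cell for GF-vs-FMT differential expression.

    ``expr`` is the genes × samples matrix for ``tissue`` with mouse ids
    as columns. Returns a frame (gene, tissue, diet, log2fc, p, q,
    passes); ``passes`` = (p < p_threshold) & (log2fc != 0). All-zero
    genes get log2fc 0 and never pass. Returns None is never used:
    cells with < 2 samples in either group are the caller's problem and
    raise.
    """
    cell = metadata[metadata["diet"] == diet]
    groups = {}
    for colonization in ("GF", "FMT"):
        mice = cell.loc[cell["colonization"] == colonization, "mouse_id"]
        cols = [m for m in mice if m in expr.columns]
        if len(cols) < 2:
            raise InputError(
                f"{colonization} group in {tissue}/{diet} has {len(cols)} samples (< 2)"
            )
        groups[colonization] = expr[cols].to_numpy(dtype=float)
    if np.any(groups["GF"] < 0) or np.any(groups["FMT"] < 0):
        raise InputError("expression values must be nonnegative")

    gf, fmt = groups["GF"], groups["FMT"]
    log2fc = np.log2(
        (fmt.mean(axis=1) + pseudocount) / (gf.mean(axis=1) + pseudocount)
    )
    pvals = np.empty(expr.shape[0])
    for i in range(expr.shape[0]):
        _, _, pvals[i] = welch_test(
            np.log2(fmt[i] + pseudocount), np.log2(gf[i] + pseudocount)
        )
    qvals = bh_adjust(pvals)
    passes = (pvals < p_threshold) & (log2fc != 0.0)
    return pd.DataFrame(
        {
            "gene": expr.index,
            "tissue": tissue,
            "diet": diet,
            "log2fc": log2fc,
            "p": pvals,
            "q": qvals,
            "passes": passes,
        }
    ).reset_index(drop=True)


def call_all_degs(
    expression: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
    diets: list[str] | None = None,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Run the screen over every tissue×diet cell and concatenate.

    Cells where a group has < 2 samples are skipped with a warning and
    simply absent from the output (downstream intersections then report
    the affected families as undefined).
    """
    if diets is None:
        diets = list(pd.unique(metadata["diet"]))
    frames = []
    for tissue, expr in expression.items():
        for diet in diets:
            try:
                frames.append(
                    call_degs(expr, metadata, tissue, diet, p_threshold=p_threshold)
                )
            except InputError as exc:
                log.warning("skipping cell %s/%s: %s", tissue, diet, exc)
    if not frames:
        raise InputError("no tissue×diet cell could be screened")
    return pd.concat(frames, ignore_index=True)


def intersect_degs(
    records: pd.DataFrame,
    tissues: list[str] | None = None,
    diets: list[str] | None = None,
) -> IntersectionReport:
    """Cross-diet and cross-tissue intersections of passing genes.

    ``tissues``/``diets`` declare the full layout; cells absent from
    ``records`` make every intersection that needs them undefined
    (``None``) rather than empty.
    """
    if tissues is None:
        tissues = sorted(records["tissue"].unique())
    if diets is None:
        diets = sorted(records["diet"].unique())
    passing: dict[tuple[str, str], set[str]] = {}
    for (tissue, diet), grp in records.groupby(["tissue", "diet"]):
        passing[(tissue, diet)] = set(grp.loc[grp["passes"], "gene"])

    def _intersect(cells: list[tuple[str, str]]) -> set[str] | None:
        if any(c not in passing for c in cells):
            return None
        sets = [passing[c] for c in cells]
        return set.intersection(*sets) if sets else None

    per_tissue = {
        t: _intersect([(t, d) for d in diets]) for t in tissues
    }
    per_diet = {
        d: _intersect([(t, d) for t in tissues]) for d in diets
    }
    return IntersectionReport(per_tissue=per_tissue, per_diet=per_diet)
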