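"""Per-diet body-weight contrasts between GF and FMT mice.

Two microbiota-attributable ΔBW measures feed the downstream gene
screen: ΔBW(g), the difference in mean week-0→week-8 weight gain, and
ΔBW(s), the difference of pooled regression slopes (all mice's raw
(week, BW) points per colonization group). The ANCOVA compares the two
groups' regression lines; gain-per-day converts the per-mouse gain over
the observation span to g/day (7 days/week).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from gutlink.errors import DegenerateFitError, InputError
from gutlink.stats import AncovaResult, ancova_compare, ols_line

__all__ = [
    "DietContrast",
    "compute_diet_contrast",
    "compute_all_contrasts",
    "gain_per_day",
    "contrasts_frame",
]

log = logging.getLogger(__name__)

END_WEEK = 8  # fixed endpoint for the absolute-gain contrast


@dataclass(frozen=True)
class DietContrast:
    """GF-vs-FMT body-weight contrast within one diet.

    ``ancova`` is None when the growth data are exactly linear (no
    residual variance), where the nested F tests are undefined.
    """

    diet: str
    delta_bw_abs: float  # grams: mean FMT (wk8−wk0) gain − mean GF gain
    delta_bw_slope: float  # g/week: pooled FMT slope − pooled GF slope
    ancova: AncovaResult | None
    gain_per_day: dict[str, float]  # colonization -> g/day


def _group_points(
    growth: pd.DataFrame, metadata: pd.DataFrame, diet: str, colonization: str
) -> pd.DataFrame:
    mice = metadata.loc[
        (metadata["diet"] == diet) & (metadata["colonization"] == colonization),
        "mouse_id",
    ]
    pts = growth[growth["mouse_id"].isin(mice)]
    if pts.empty:
        raise InputError(f"no growth data for {colonization} mice in diet {diet!r}")
    return pts


def _mean_gain(pts: pd.DataFrame, diet: str, colonization: str) -> float:
    gains = []
    for mouse, grp in pts.groupby("mouse_id"):
        by_week = grp.set_index("week")["bw_g"]
        if 0 not in by_week.index or END_WEEK not in by_week.index:
            log.warning(
                "mouse %s (%s/%s) lacks week 0 or week %d; excluded from "
                "absolute-gain contrast",
                mouse,
                diet,
                colonization,
                END_WEEK,
            )
            continue
        gains.append(float(by_week.loc[END_WEEK] - by_week.loc[0]))
    if not gains:
        raise InputError(
            f"no mouse with both week 0 and week {END_WEEK} in {colonization}/{diet}"
        )
    return sum(gains) / len(gains)


def compute_diet_contrast(
    growth: pd.DataFrame, metadata: pd.DataFrame, diet: str
) -> DietContrast:
    """Body-weight contrast for one diet.

    ``growth`` is the long table (mouse_id, week, bw_g); ``metadata``
    maps mice to colonization and diet. Mice missing the week-0 or
    week-8 observation are excluded (with a warning) from the
    absolute-gain measure only.
    """
    if diet not in set(metadata["diet"]):
        raise InputError(f"diet {diet!r} not present in metadata")
    pts = {
        c: _group_points(growth, metadata, diet, c) for c in ("GF", "FMT")
    }
    slopes = {}
    for c, p in pts.items():
        slope, _, _, _ = ols_line(p["week"], p["bw_g"])
        slopes[c] = slope
    try:
        anc = ancova_compare(
            (pts["FMT"]["week"], pts["FMT"]["bw_g"]),
            (pts["GF"]["week"], pts["GF"]["bw_g"]),
        )
    except DegenerateFitError:
        log.info("diet %s: exactly linear growth, ANCOVA undefined", diet)
        anc = None
    delta_abs = _mean_gain(pts["FMT"], diet, "FMT") - _mean_gain(pts["GF"], diet, "GF")
    gpd = {
        c: _gain_per_day_group(p, diet, c) for c, p in pts.items()
    }
    return DietContrast(
        diet=diet,
        delta_bw_abs=delta_abs,
        delta_bw_slope=slopes["FMT"] - slopes["GF"],
        ancova=anc,
        gain_per_day=gpd,
    )


def _gain_per_day_group(pts: pd.DataFrame, diet: str, colonization: str) -> float:
    rates = []
    for mouse, grp in pts.groupby("mouse_id"):
        by_week = grp.sort_values("week")
        if len(by_week) < 2:
            log.warning(
                "mouse %s (%s/%s) has a single timepoint; excluded from gain/day",
                mouse,
                diet,
                colonization,
            )
            continue
        first, last = by_week.iloc[0], by_week.iloc[-1]
        days = 7.0 * (last["week"] - first["week"])
        rates.append(float((last["bw_g"] - first["bw_g"]) / days))
    if not rates:
        raise InputError(f"no multi-timepoint mouse in {colonization}/{diet}")
    return sum(rates) / len(rates)


def gain_per_day(growth: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Mean weight gain per day (g/day) per colonization×diet group."""
    rows = []
    for diet in pd.unique(metadata["diet"]):
        present = set(metadata.loc[metadata["diet"] == diet, "colonization"])
        for colonization in ("GF", "FMT"):
            if colonization not in present:
                continue
            pts = _group_points(growth, metadata, diet, colonization)
            rows.append(
                {
                    "diet": diet,
                    "colonization": colonization,
                    "gain_per_day": _gain_per_day_group(pts, diet, colonization),
                }
            )
    return pd.DataFrame(rows)


def compute_all_contrasts(
    growth: pd.DataFrame, metadata: pd.DataFrame, diets: list[str] | None = None
) -> list[DietContrast]:
    if diets is None:
        diets = list(pd.unique(metadata["diet"]))
    return [compute_diet_contrast(growth, metadata, d) for d in diets]


def contrasts_frame(contrasts: list[DietContrast]) -> pd.DataFrame:
    """Flatten contrasts into the per-diet TSV layout."""
    return pd.DataFrame(
        {
            "diet": [c.diet for c in contrasts],
            "delta_bw_abs": [c.delta_bw_abs for c in contrasts],
            "delta_bw_slope": [c.delta_bw_slope for c in contrasts],
            "F_slope": [c.ancova.F_slope if c.ancova else float("nan") for c in contrasts],
            "p_slope": [c.ancova.p_slope if c.ancova else float("nan") for c in contrasts],
            "F_elev": [c.ancova.F_elev if c.ancova else float("nan") for c in contrasts],
            "p_elev": [c.ancova.p_elev if c.ancova else float("nan") for c in contrasts],
            "gain_per_day_FMT": [c.gain_per_day["FMT"] for c in contrasts],
            "gain_per_day_GF": [c.gain_per_day["GF"] for c in contrasts],
        }
    )
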