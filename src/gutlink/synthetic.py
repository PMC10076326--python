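"""Synthetic gnotobiotic-cohort generator with planted linkages.

The generator emulates a germ-free (GF) vs fecal-microbiota-transplant
(FMT) study across several diets: per-mouse linear body-weight growth
whose FMT−GF slope gap varies by diet, log-normal tissue expression with
a planted subset of genes whose FMT−GF shift tracks the same per-diet
effect, and compositional taxon counts with planted taxa (sharing one
family) whose abundance tracks the planted shifts and individual body
weight. Every planted signal is recorded in a :class:`GroundTruth` so
downstream screens can be validated by parameter recovery.

A single integer seed drives everything; each table draws from its own
fixed substream, so regenerating one table never perturbs the others.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gutlink.errors import InvalidConfigError

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "make_ground_truth",
    "generate_growth",
    "generate_expression",
    "generate_abundance",
    "simulate_cohort",
    "write_cohort",
]

DEFAULT_DIETS = ("ND", "StaHC", "SucHC", "FruHC", "SaHF", "USaHF")
DEFAULT_TISSUES = ("liver", "eWAT")

# substream offsets (fixed so adding a table never shifts another)
_S_DESIGN, _S_GROWTH, _S_EXPR, _S_ABUND, _S_TREE = 0, 1, 2, 3, 4

_PHYLA = (
    "Bacillota",
    "Bacteroidota",
    "Pseudomonadota",
    "Actinomycetota",
    "Verrucomicrobiota",
    "Desulfobacterota",
)
_PHYLUM_WEIGHTS = (0.45, 0.35, 0.08, 0.06, 0.04, 0.02)
PLANTED_FAMILY = "Ruminococcaceae"
RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for one synthetic cohort.

    ``n_mice_per_cell=None`` draws each diet's group size from {4, 7}
    (the same n for GF and FMT within a diet), mirroring the unbalanced
    designs such studies use; an integer forces a balanced design.
    """

    diets: tuple[str, ...] = DEFAULT_DIETS
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_mice_per_cell: int | None = None
    weeks: tuple[int, ...] = tuple(range(9))
    n_genes: int = 200
    n_planted_genes: int = 10
    n_taxa: int = 150
    n_planted_taxa: int = 5
    planted_family_size: int = 3
    effect_scale_bw: float = 1.0  # g/week per unit diet effect
    effect_scale_gel: float = 1.0  # fractional FMT expression shift per unit
    noise_sd_bw: float = 0.5  # g, per observation
    noise_cv_expr: float = 0.2  # CV of log-normal expression noise
    library_size: int = 20000  # reads per microbiome sample
    dirichlet_concentration: float = 300.0
    seed: int = 0

    @property
    def n_diets(self) -> int:
        return len(self.diets)

    def __post_init__(self) -> None:
        if self.n_diets < 1 or not self.tissues:
            raise InvalidConfigError("need at least one diet and one tissue")
        if len(set(self.diets)) != self.n_diets:
            raise InvalidConfigError("duplicate diet labels")
        for name in ("n_genes", "n_taxa", "n_planted_genes", "n_planted_taxa"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if self.n_planted_genes > self.n_genes:
            raise InvalidConfigError("n_planted_genes > n_genes")
        if self.n_planted_taxa > self.n_taxa:
            raise InvalidConfigError("n_planted_taxa > n_taxa")
        if self.planted_family_size < 1 and self.n_planted_taxa > 0:
            raise InvalidConfigError(
                "planted_family_size must be >= 1 when taxa are planted"
            )
        if self.planted_family_size > self.n_planted_taxa:
            raise InvalidConfigError("planted_family_size > n_planted_taxa")
        if len(self.weeks) < 2:
            raise InvalidConfigError("need at least 2 observation weeks")
        if any(w < 0 for w in self.weeks):
            raise InvalidConfigError("weeks must be nonnegative")
        if any(b <= a for a, b in zip(self.weeks, self.weeks[1:])):
            raise InvalidConfigError("weeks must be strictly increasing")
        if self.n_mice_per_cell is not None and self.n_mice_per_cell < 1:
            raise InvalidConfigError("n_mice_per_cell must be >= 1")
        if self.noise_sd_bw < 0 or self.noise_cv_expr < 0:
            raise InvalidConfigError("noise parameters must be >= 0")
        if self.library_size < 1:
            raise InvalidConfigError("library_size must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Planted signals of one cohort: what recovery tests must find."""

    diet_effect: dict[str, float]  # u_d, dimensionless, per diet
    planted_genes: dict[str, float]  # gene id -> signed gain g_k
    planted_taxa: dict[str, float]  # taxon id -> gain h_j
    planted_family: str
    bw_slopes: dict[str, dict[str, float]]  # diet -> {GF: s, FMT: s}
    group_sizes: dict[str, int] = field(default_factory=dict)

    def slope_difference(self, diet: str) -> float:
        """True FMT − GF growth-slope gap (g/week) for one diet."""
        return self.bw_slopes[diet]["FMT"] - self.bw_slopes[diet]["GF"]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    truth: GroundTruth
    metadata: pd.DataFrame  # mouse_id, colonization, diet
    growth: pd.DataFrame  # mouse_id, week, bw_g
    expression: dict[str, pd.DataFrame]  # tissue -> genes × mice
    abundance: pd.DataFrame  # taxa × mice (GF columns all zero)
    taxonomy: pd.DataFrame  # taxon_id + rank columns + lineage
    tree_newick: str


def _rng(config: CohortConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, offset])


# ---------------------------------------------------------------------------
# ground truth and design


def make_ground_truth(config: CohortConfig) -> GroundTruth:
    """Draw the planted effects that define one cohort's biology.

    Per-diet effects u_d ~ U(0.2, 1.0) make the FMT−GF slope gap vary
    across diets (the variation the cross-diet correlation screen
    needs); germ-free base slopes ~ U(0.35, 0.65) g/week; planted gene
    gains are ±1 with random sign. Planted taxon gains are all positive
    so the family aggregate reinforces its members: taxa sharing the
    planted family get coherent strong gains ~ U(1.4, 1.8) while the
    singleton planted taxa get weaker ones ~ U(0.6, 1.0) — the
    family-level signal dominates any single species, the structure the
    family-aggregation screens look for.
    """
    rng = _rng(config, _S_DESIGN)
    u = rng.uniform(0.2, 1.0, size=config.n_diets)
    gf_slope = rng.uniform(0.35, 0.65, size=config.n_diets)
    bw_slopes = {
        d: {"GF": float(g), "FMT": float(g + config.effect_scale_bw * ui)}
        for d, g, ui in zip(config.diets, gf_slope, u)
    }
    gene_ids = [f"Gene_{i:04d}" for i in range(config.n_genes)]
    taxon_ids = [f"OTU_{i:04d}" for i in range(config.n_taxa)]
    pg_idx = rng.choice(config.n_genes, size=config.n_planted_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_planted_genes)
    planted_genes = {gene_ids[i]: float(s) for i, s in zip(sorted(pg_idx), signs)}
    pt_idx = sorted(rng.choice(config.n_taxa, size=config.n_planted_taxa, replace=False))
    n_fam = config.planted_family_size
    gains = np.concatenate(
        [
            rng.uniform(1.4, 1.8, size=n_fam),
            rng.uniform(0.6, 1.0, size=config.n_planted_taxa - n_fam),
        ]
    )
    planted_taxa = {taxon_ids[i]: float(h) for i, h in zip(pt_idx, gains)}
    if config.n_mice_per_cell is None:
        sizes = rng.choice([4, 7], size=config.n_diets)
    else:
        sizes = np.full(config.n_diets, config.n_mice_per_cell)
    group_sizes = {d: int(n) for d, n in zip(config.diets, sizes)}
    return GroundTruth(
        diet_effect={d: float(ui) for d, ui in zip(config.diets, u)},
        planted_genes=planted_genes,
        planted_taxa=planted_taxa,
        planted_family=PLANTED_FAMILY,
        bw_slopes=bw_slopes,
        group_sizes=group_sizes,
    )


def _metadata(config: CohortConfig, truth: GroundTruth) -> pd.DataFrame:
    rows = []
    i = 0
    for diet in config.diets:
        for colonization in ("GF", "FMT"):
            for _ in range(truth.group_sizes[diet]):
                rows.append(
                    {
                        "mouse_id": f"M{i:03d}",
                        "colonization": colonization,
                        "diet": diet,
                    }
                )
                i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# growth


def generate_growth(
    config: CohortConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse body-weight trajectories plus the cohort metadata.

    BW_i(t) = b0_i + s_{diet,colonization}·t + ε with ε ~ N(0, σ²) and
    baseline b0_i ~ N(20 g, 1 g²) truncated positive.
    """
    meta = _metadata(config, truth)
    rng = _rng(config, _S_GROWTH)
    weeks = np.asarray(config.weeks, dtype=float)
    rows = []
    for _, m in meta.iterrows():
        slope = truth.bw_slopes[m["diet"]][m["colonization"]]
        b0 = float(rng.normal(20.0, 1.0))
        while b0 <= 0:  # pragma: no cover - ~20 sigma event
            b0 = float(rng.normal(20.0, 1.0))
        noise = (
            rng.normal(0.0, config.noise_sd_bw, size=weeks.size)
            if config.noise_sd_bw > 0
            else np.zeros(weeks.size)
        )
        bw = b0 + slope * weeks + noise
        bw = np.maximum(bw, 0.1)  # physical floor; untouched in practice
        for w, v in zip(config.weeks, bw):
            rows.append({"mouse_id": m["mouse_id"], "week": int(w), "bw_g": float(v)})
    return pd.DataFrame(rows), meta


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    config: CohortConfig, truth: GroundTruth, metadata: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """One genes × mice expression matrix per tissue.

    Non-planted genes share their gene-specific log-normal baseline in
    both colonization groups. A planted gene k has its FMT mean scaled
    by (1 + effect_scale_gel·g_k·u_d) in diet d — linear in the diet
    effect, so the noiseless ΔGEL row is exactly proportional to u_d —
    clipped at zero. Multiplicative log-normal noise has CV
    ``noise_cv_expr``; values are nonnegative by construction.
    """
    rng = _rng(config, _S_EXPR)
    gene_ids = [f"Gene_{i:04d}" for i in range(config.n_genes)]
    cv = config.noise_cv_expr
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    out: dict[str, pd.DataFrame] = {}
    for tissue in config.tissues:
        base = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=config.n_genes)
        mat = np.empty((config.n_genes, len(metadata)))
        for j, (_, m) in enumerate(metadata.iterrows()):
            u = truth.diet_effect[m["diet"]]
            mean = base.copy()
            if m["colonization"] == "FMT":
                for gene, gain in truth.planted_genes.items():
                    gi = gene_ids.index(gene)
                    mean[gi] = base[gi] * max(
                        0.0, 1.0 + config.effect_scale_gel * gain * u
                    )
            if sigma > 0:
                noise = np.exp(rng.normal(0.0, sigma, size=config.n_genes))
                noise /= np.exp(sigma * sigma / 2.0)  # unit-mean noise
                mat[:, j] = mean * noise
            else:
                mat[:, j] = mean
        out[tissue] = pd.DataFrame(
            mat, index=pd.Index(gene_ids, name="gene"), columns=metadata["mouse_id"]
        )
    return out


# ---------------------------------------------------------------------------
# abundance, taxonomy, tree


def _taxonomy(config: CohortConfig, truth: GroundTruth, rng: np.random.Generator) -> pd.DataFrame:
    taxon_ids = [f"OTU_{i:04d}" for i in range(config.n_taxa)]
    planted = list(truth.planted_taxa)
    family_members = set(planted[: config.planted_family_size])
    rows = []
    for t in taxon_ids:
        if t in family_members:
            phylum, cls, order = "Bacillota", "Clostridia", "Eubacteriales"
            family = truth.planted_family
        else:
            phylum = _PHYLA[rng.choice(len(_PHYLA), p=_PHYLUM_WEIGHTS)]
            cls = f"{phylum}_c{rng.integers(1, 3)}"
            order = f"{cls}_o{rng.integers(1, 3)}"
            family = f"{order}_f{rng.integers(1, 4)}"
        genus = f"{family}_g{rng.integers(1, 3)}"
        species = t
        lineage = ";".join([phylum, cls, order, family, genus, species])
        rows.append(
            {
                "taxon_id": t,
                "phylum": phylum,
                "class": cls,
                "order": order,
                "family": family,
                "genus": genus,
                "species": species,
                "lineage": lineage,
            }
        )
    return pd.DataFrame(rows)


def _random_bifurcating_newick(labels: Sequence[str], rng: np.random.Generator) -> str:
    """Random bifurcating topology with Exp(1) branch lengths."""

    def build(items: list[str]) -> str:
        if len(items) == 1:
            return f"{items[0]}:{rng.exponential(1.0):.6f}"
        split = int(rng.integers(1, len(items)))
        left = build(items[:split])
        right = build(items[split:])
        return f"({left},{right}):{rng.exponential(1.0):.6f}"

    shuffled = list(labels)
    rng.shuffle(shuffled)
    if len(shuffled) == 1:
        return f"({shuffled[0]}:{rng.exponential(1.0):.6f});"
    split = int(rng.integers(1, len(shuffled)))
    return f"({build(shuffled[:split])},{build(shuffled[split:])});"


def generate_abundance(
    config: CohortConfig, truth: GroundTruth, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Taxon count table, taxonomy map and a random phylogeny.

    FMT sample counts ~ Multinomial(library_size, p) with
    p ~ Dirichlet(c·base_d); the diet-d base composition scales each
    planted taxon j by exp(h_j·u_d) before renormalising. GF mice carry
    no microbiota and get all-zero columns. The first
    ``planted_family_size`` planted taxa share the planted family; the
    tree is a random bifurcation with Exp(1) branch lengths (only
    presence/absence branch logic is exercised downstream).
    """
    if config.library_size < config.n_taxa:
        warnings.warn(
            "library_size < n_taxa: many taxa will be unobserved",
            stacklevel=2,
        )
    rng = _rng(config, _S_ABUND)
    taxon_ids = [f"OTU_{i:04d}" for i in range(config.n_taxa)]
    base_w = rng.gamma(0.8, 1.0, size=config.n_taxa)
    floor = float(np.quantile(base_w, 0.8))
    idx = {t: i for i, t in enumerate(taxon_ids)}
    for taxon in truth.planted_taxa:
        base_w[idx[taxon]] = 1.5 * floor

    diet_base = {}
    for diet in config.diets:
        w = base_w.copy()
        u = truth.diet_effect[diet]
        for taxon, h in truth.planted_taxa.items():
            w[idx[taxon]] *= np.exp(h * u)
        diet_base[diet] = w / w.sum()

    mat = np.zeros((config.n_taxa, len(metadata)), dtype=int)
    for j, (_, m) in enumerate(metadata.iterrows()):
        if m["colonization"] != "FMT":
            continue
        alpha = config.dirichlet_concentration * diet_base[m["diet"]]
        p = rng.dirichlet(alpha)
        mat[:, j] = rng.multinomial(config.library_size, p)
    abundance = pd.DataFrame(
        mat, index=pd.Index(taxon_ids, name="taxon_id"), columns=metadata["mouse_id"]
    )
    taxonomy = _taxonomy(config, truth, rng)
    tree = _random_bifurcating_newick(taxon_ids, _rng(config, _S_TREE))
    return abundance, taxonomy, tree


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(config: CohortConfig | None = None, **kwargs) -> SyntheticCohort:
    """Generate a complete cohort (growth, expression, microbiome, truth).

    Keyword arguments override :class:`CohortConfig` defaults, e.g.
    ``simulate_cohort(seed=3, noise_sd_bw=0.0)``.
    """
    if config is None:
        config = CohortConfig(**kwargs)
    elif kwargs:
        raise InvalidConfigError("pass either a config or keyword overrides, not both")
    truth = make_ground_truth(config)
    growth, metadata = generate_growth(config, truth)
    expression = generate_expression(config, truth, metadata)
    abundance, taxonomy, tree = generate_abundance(config, truth, metadata)
    return SyntheticCohort(
        config=config,
        truth=truth,
        metadata=metadata,
        growth=growth,
        expression=expression,
        abundance=abundance,
        taxonomy=taxonomy,
        tree_newick=tree,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every cohort table as TSV (+ newick tree, ground-truth JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _tsv(name: str, df: pd.DataFrame, index: bool) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=index)
        paths[name] = p

    _tsv("metadata.tsv", cohort.metadata, index=False)
    _tsv("growth.tsv", cohort.growth, index=False)
    for tissue, mat in cohort.expression.items():
        _tsv(f"expression_{tissue}.tsv", mat, index=True)
    _tsv("abundance.tsv", cohort.abundance, index=True)
    _tsv("taxonomy.tsv", cohort.taxonomy, index=False)
    tree_path = out / "tree.nwk"
    tree_path.write_text(cohort.tree_newick + "\n")
    paths["tree.nwk"] = tree_path
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(asdict(cohort.truth), indent=2, sort_keys=True))
    paths["ground_truth.json"] = truth_path
    manifest = out / "manifest.json"
    manifest.write_text(
        json.dumps(
            {"config": {**asdict(cohort.config)}, "files": sorted(paths)},
            indent=2,
            sort_keys=True,
            default=list,
        )
    )
    paths["manifest.json"] = manifest
    return paths
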