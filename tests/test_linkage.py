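"""Cross-layer correlation screens: ΔGEL, gene–weight, taxon screens."""

import numpy as np
import pandas as pd
import pytest

from gutlink.errors import InputError
from gutlink.growth import compute_all_contrasts, contrasts_frame
from gutlink.linkage import (
    aggregate_rank,
    compute_delta_gel,
    gene_weight_screen,
    relative_abundance,
    select_by_threshold,
    taxon_bw_regression,
    taxon_gene_screen,
)
from gutlink.synthetic import simulate_cohort

DIETS = ["d1", "d2", "d3", "d4", "d5", "d6"]


def _expr_meta(gene_rows: dict, n_per_group=2):
    """Matrix with per-diet GF/FMT sample pairs from (gf, fmt) means."""
    cols, meta = [], []
    data = {g: [] for g in gene_rows}
    for d in DIETS:
        for col in ("GF", "FMT"):
            for i in range(n_per_group):
                cid = f"{d}_{col}{i}"
                cols.append(cid)
                meta.append({"mouse_id": cid, "colonization": col, "diet": d})
                for g, (gf_vals, fmt_vals) in gene_rows.items():
                    v = fmt_vals[DIETS.index(d)] if col == "FMT" else gf_vals[DIETS.index(d)]
                    data[g].append(v)
    expr = pd.DataFrame(data, index=cols).T
    return expr, pd.DataFrame(meta)


class TestDeltaGel:
    def test_identical_groups_zero(self):
        base = [10.0] * 6
        expr, meta = _expr_meta({"a": (base, base)})
        dgel = compute_delta_gel(expr, meta, diets=DIETS)
        assert np.allclose(dgel.loc["a"], 0.0)

    def test_constant_offset(self):
        base = [10.0, 12.0, 9.0, 11.0, 10.5, 13.0]
        shifted = [v + 3.0 for v in base]
        expr, meta = _expr_meta({"a": (base, shifted)})
        dgel = compute_delta_gel(expr, meta, diets=DIETS)
        assert np.allclose(dgel.loc["a"], 3.0)

    def test_noiseless_planted_row_proportional_to_diet_effect(self, noiseless_cohort):
        c = noiseless_cohort
        dgel = compute_delta_gel(
            c.expression[c.config.tissues[0]], c.metadata, diets=list(c.config.diets)
        )
        u = np.array([c.truth.diet_effect[d] for d in c.config.diets])
        for gene, gain in c.truth.planted_genes.items():
            row = dgel.loc[gene].to_numpy()
            ratio = row / u
            assert np.allclose(ratio, ratio[0], atol=1e-9)


class TestGeneWeightScreen:
    def _contrasts(self, abs_vec, slope_vec):
        return pd.DataFrame(
            {"diet": DIETS, "delta_bw_abs": abs_vec, "delta_bw_slope": slope_vec}
        )

    def test_exact_match_selected(self):
        vec = [1.0, 2.0, 0.5, 1.5, 2.5, 0.8]
        dgel = pd.DataFrame([vec], index=["a"], columns=DIETS)
        out = gene_weight_screen(dgel, self._contrasts(vec, [0.1] * 6))
        assert out.loc[0, "r_abs"] == pytest.approx(1.0)
        assert bool(out.loc[0, "selected"])

    def test_selection_uses_either_measure(self):
        vec = [1.0, 2.0, 0.5, 1.5, 2.5, 0.8]
        noise = [0.3, 0.1, 0.25, 0.2, 0.15, 0.28]
        dgel = pd.DataFrame([vec], index=["a"], columns=DIETS)
        out = gene_weight_screen(dgel, self._contrasts(noise, vec))
        assert bool(out.loc[0, "selected"])

    def test_inclusive_at_printed_precision(self):
        # |r| rounding to 0.70 selects; 0.69 does not
        assert select_by_threshold(0.6951, 0.0)
        assert select_by_threshold(-0.704, 0.1)
        assert not select_by_threshold(0.694, 0.62)

    def test_scale_invariance(self, default_cohort):
        c = default_cohort
        contrasts = contrasts_frame(compute_all_contrasts(c.growth, c.metadata))
        dgel = compute_delta_gel(
            c.expression["liver"], c.metadata, diets=list(c.config.diets)
        )
        out1 = gene_weight_screen(dgel, contrasts)
        scaled = contrasts.assign(
            delta_bw_abs=contrasts["delta_bw_abs"] * 7.3,
            delta_bw_slope=contrasts["delta_bw_slope"] * 0.11,
        )
        out2 = gene_weight_screen(dgel * 3.7, scaled)
        pd.testing.assert_series_equal(out1["selected"], out2["selected"])
        assert out1["r_abs"].to_numpy() == pytest.approx(
            out2["r_abs"].to_numpy(), abs=1e-10
        )

    def test_zero_variance_gene_excluded(self):
        vec = [1.0, 2.0, 0.5, 1.5, 2.5, 0.8]
        dgel = pd.DataFrame(
            [vec, [2.0] * 6], index=["a", "flat"], columns=DIETS
        )
        out = gene_weight_screen(dgel, self._contrasts(vec, vec))
        assert list(out["gene"]) == ["a"]

    def test_too_few_diets_rejected(self):
        dgel = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["d1", "d2"])
        contrasts = pd.DataFrame(
            {"diet": ["d1", "d2"], "delta_bw_abs": [1, 2], "delta_bw_slope": [1, 2]}
        )
        with pytest.raises(InputError):
            gene_weight_screen(dgel, contrasts)

    def test_planted_gene_recovery_on_synthetic(self):
        hits = []
        for seed in range(1, 6):
            c = simulate_cohort(seed=seed)
            contrasts = contrasts_frame(compute_all_contrasts(c.growth, c.metadata))
            planted = set(c.truth.planted_genes)
            for expr in c.expression.values():
                dgel = compute_delta_gel(expr, c.metadata, diets=list(c.config.diets))
                out = gene_weight_screen(dgel, contrasts)
                sel = set(out.loc[out["selected"], "gene"])
                hits.append(len(sel & planted) / len(planted))
        assert np.mean(hits) >= 0.8


class TestRankAggregation:
    def _tables(self):
        abundance = pd.DataFrame(
            {"s1": [3, 5, 2], "s2": [1, 0, 4]},
            index=pd.Index(["t1", "t2", "t3"], name="taxon_id"),
        )
        taxonomy = pd.DataFrame(
            {
                "taxon_id": ["t1", "t2", "t3"],
                "family": ["F1", "F1", "F2"],
                "species": ["t1", "t2", "t3"],
            }
        )
        return abundance, taxonomy

    def test_family_sum(self):
        abundance, taxonomy = self._tables()
        fam = aggregate_rank(abundance, taxonomy, "family")
        assert fam.loc["F1", "s1"] == 8
        assert fam.loc["F2", "s2"] == 4

    def test_species_identity(self):
        abundance, taxonomy = self._tables()
        sp = aggregate_rank(abundance, taxonomy, "species")
        assert sp.sort_index().to_numpy().tolist() == abundance.sort_index().to_numpy().tolist()

    def test_column_sums_conserved(self, default_cohort):
        c = default_cohort
        for rank in ("phylum", "class", "order", "family", "genus", "species"):
            agg = aggregate_rank(c.abundance, c.taxonomy, rank)
            assert (agg.sum(axis=0) == c.abundance.sum(axis=0)).all()

    def test_unknown_rank_rejected(self):
        abundance, taxonomy = self._tables()
        with pytest.raises(InputError):
            aggregate_rank(abundance, taxonomy, "kingdom")

    def test_missing_lineage_pooled_unclassified(self):
        abundance, taxonomy = self._tables()
        fam = aggregate_rank(abundance, taxonomy.iloc[:2], "family")
        assert "unclassified" in fam.index
        assert fam.loc["unclassified", "s2"] == 4


class TestTaxonGeneScreen:
    def test_exact_tracking_counted(self, default_cohort):
        c = default_cohort
        # plant a fake ΔGEL equal to a real taxon's diet-mean abundance
        from gutlink.linkage import _diet_means, _fmt_columns

        fmt = _fmt_columns(c.abundance, c.metadata)
        rel = relative_abundance(aggregate_rank(fmt, c.taxonomy, "species"))
        means = _diet_means(rel, c.metadata, list(c.config.diets))
        target = means.iloc[5]
        sel = pd.DataFrame([target.to_numpy()], index=["fake"], columns=c.config.diets)
        out = taxon_gene_screen(
            c.abundance, c.taxonomy, c.metadata, sel, rank="species"
        ).set_index("taxon")
        assert out.loc[target.name, "gene_count"] == 1

    def test_impossible_threshold_zeroes_counts(self, default_cohort):
        c = default_cohort
        sel = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["g"], columns=c.config.diets
        )
        out = taxon_gene_screen(
            c.abundance, c.taxonomy, c.metadata, sel, rank="family", r_select=1.01
        )
        assert (out["gene_count"] == 0).all()

    def test_empty_gene_set_rejected(self, default_cohort):
        c = default_cohort
        with pytest.raises(InputError):
            taxon_gene_screen(
                c.abundance, c.taxonomy, c.metadata, pd.DataFrame(), rank="family"
            )

    def test_planted_family_top_ranked_most_seeds(self):
        wins = []
        for seed in range(1, 9):
            c = simulate_cohort(seed=seed)
            contrasts = contrasts_frame(compute_all_contrasts(c.growth, c.metadata))
            sel_gel = []
            for t, expr in c.expression.items():
                dgel = compute_delta_gel(expr, c.metadata, diets=list(c.config.diets))
                scr = gene_weight_screen(dgel, contrasts)
                sub = dgel.loc[sorted(scr.loc[scr["selected"], "gene"])].copy()
                sub.index = [f"{t}:{g}" for g in sub.index]
                sel_gel.append(sub)
            taxa = taxon_gene_screen(
                c.abundance, c.taxonomy, c.metadata, pd.concat(sel_gel), rank="family"
            ).set_index("taxon")
            wins.append(
                taxa.loc[c.truth.planted_family, "gene_count"] == taxa["gene_count"].max()
            )
        assert np.mean(wins) >= 0.75


class TestTaxonBWRegression:
    def test_exact_linear_r2_one(self, default_cohort):
        c = default_cohort
        # construct BW exactly linear in one taxon's relative abundance
        from gutlink.linkage import _fmt_columns

        fmt = _fmt_columns(c.abundance, c.metadata)
        rel = relative_abundance(aggregate_rank(fmt, c.taxonomy, "species"))
        taxon = rel.var(axis=1).idxmax()
        growth = pd.DataFrame(
            {
                "mouse_id": rel.columns,
                "week": 8,
                "bw_g": 20.0 + 100.0 * rel.loc[taxon].to_numpy(),
            }
        )
        out = taxon_bw_regression(
            c.abundance, c.metadata, growth, c.taxonomy, rank="species"
        ).set_index("taxon")
        assert out.loc[taxon, "r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_permutation_null_mean_r2(self, rng):
        # E[R²] under the null is 1/(n−1)
        n = 12
        x = rng.uniform(size=n)
        y = rng.normal(size=n)
        r2 = []
        for _ in range(1000):
            perm = rng.permutation(n)
            r = np.corrcoef(x, y[perm])[0, 1]
            r2.append(r * r)
        expected = 1.0 / (n - 1)
        se = np.std(r2) / np.sqrt(len(r2))
        assert abs(np.mean(r2) - expected) < 4 * se

    def test_family_beats_members_most_seeds(self):
        wins = []
        for seed in range(1, 9):
            c = simulate_cohort(seed=seed)
            fam = taxon_bw_regression(
                c.abundance, c.metadata, c.growth, c.taxonomy, rank="family"
            ).set_index("taxon")
            sp = taxon_bw_regression(
                c.abundance, c.metadata, c.growth, c.taxonomy, rank="species"
            ).set_index("taxon")
            members = list(c.truth.planted_taxa)[: c.config.planted_family_size]
            wins.append(
                fam.loc[c.truth.planted_family, "r_squared"]
                >= sp.loc[members, "r_squared"].max()
            )
        assert np.mean(wins) >= 0.6

    def test_too_few_mice_rejected(self, default_cohort):
        c = default_cohort
        two = c.metadata[c.metadata["colonization"] == "FMT"].head(2)
        meta = pd.concat([two, c.metadata[c.metadata["colonization"] == "GF"].head(2)])
        with pytest.raises(InputError):
            taxon_bw_regression(
                c.abundance[list(meta["mouse_id"])],
                meta,
                c.growth,
                c.taxonomy,
                rank="species",
            )
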