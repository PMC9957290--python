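"""RPKM arithmetic, abundance vs prevalence accounting, breakdowns."""

import numpy as np
import pytest

from ibparch import abundance as ab
from ibparch.model import Architecture, TaxonomyRecord


def _arch(gene_id, arch_string, has_sp=False, n_tmd=0):
    domains = arch_string.split("_")
    loc = ("both" if has_sp and n_tmd else "sp_only" if has_sp
           else "tmd_only" if n_tmd else "none")
    return Architecture(
        gene_id=gene_id, domain_order=domains, arch_string=arch_string,
        n_target=domains.count("pfam11999"), n_nterm=0,
        n_cterm=len(domains) - domains.count("pfam11999"),
        has_sp=has_sp, n_tmd=n_tmd, localization_class=loc,
    )


class TestRpkm:
    def test_definitional_values(self):
        assert ab.rpkm(10, 1000, 1_000_000) == pytest.approx(10.0)
        assert ab.rpkm(0, 123, 456) == 0.0
        assert ab.rpkm(25, 500, 2_000_000) == pytest.approx(25.0)  # 25/0.5/2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ab.rpkm(1, 0, 1000)
        with pytest.raises(ValueError):
            ab.rpkm(1, 100, 0)

    def test_linearity_and_inverse_length_grid(self):
        """rpkm(2r) = 2 rpkm(r); rpkm(.,2L) = rpkm(.,L)/2 — to 1e-12."""
        for r in (0.0, 1.0, 17.0, 1234.0):
            for L in (100.0, 999.0, 2500.0):
                for T in (1e5, 1e6, 3.7e7):
                    base = ab.rpkm(r, L, T)
                    assert ab.rpkm(2 * r, L, T) == pytest.approx(2 * base, abs=1e-12, rel=1e-12)
                    assert ab.rpkm(r, 2 * L, T) == pytest.approx(base / 2, abs=1e-12, rel=1e-12)
                    assert ab.rpkm(r, L, 2 * T) == pytest.approx(base / 2, abs=1e-12, rel=1e-12)


class TestAggregate:
    def test_two_architecture_shares(self):
        archs = [_arch("g1", "pfam11999"), _arch("g2", "pfam11999_pfam11999")]
        recs = ab.aggregate_architectures(archs, {"g1": 75.0, "g2": 25.0})
        assert recs[0].arch_string == "pfam11999"
        assert recs[0].pct_abundance == pytest.approx(75.0)
        assert recs[1].pct_abundance == pytest.approx(25.0)

    def test_prevalence_count_shares(self):
        archs = [_arch(f"g{i}", "pfam11999") for i in range(4)]
        archs.append(_arch("g9", "pfam11999_pfam16130"))
        rpkms = {a.gene_id: 1.0 for a in archs}
        recs = ab.aggregate_architectures(archs, rpkms)
        by = {r.arch_string: r for r in recs}
        assert by["pfam11999"].pct_prevalence == pytest.approx(80.0)
        assert by["pfam11999_pfam16130"].pct_prevalence == pytest.approx(20.0)

    def test_missing_gene_errors_with_ids(self):
        with pytest.raises(KeyError, match="g1"):
            ab.aggregate_architectures([_arch("g1", "pfam11999")], {})

    def test_abundance_prevalence_independence(self):
        """One very abundant gene ranks its architecture first by RPKM while
        staying a small minority by count."""
        archs = [_arch("big", "pfam11999_pfam13205")]
        archs += [_arch(f"g{i}", "pfam11999") for i in range(19)]
        rpkms = {"big": 950.0, **{f"g{i}": 50.0 / 19 for i in range(19)}}
        recs = ab.aggregate_architectures(archs, rpkms)
        top = recs[0]
        assert top.arch_string == "pfam11999_pfam13205"
        assert top.pct_abundance == pytest.approx(95.0)
        assert top.pct_prevalence == pytest.approx(5.0)

    def test_percent_tables_invariant_under_uniform_scaling(self):
        archs = [_arch("g1", "pfam11999"), _arch("g2", "pfam11999_pfam16130")]
        rpkms = {"g1": 3.0, "g2": 9.0}
        a = ab.aggregate_architectures(archs, rpkms)
        b = ab.aggregate_architectures(archs, {k: v * 1e4 for k, v in rpkms.items()})
        for x, y in zip(a, b):
            assert x.pct_abundance == pytest.approx(y.pct_abundance)
            assert x.pct_prevalence == y.pct_prevalence

    def test_pct_abundance_sums_to_100(self, default_ctx):
        ctx, _ = default_ctx
        total = sum(r.pct_abundance for r in ctx["records"])
        assert total == pytest.approx(100.0, abs=0.01)
        assert sum(r.n_genes for r in ctx["records"]) == len(ctx["catalogue"])


class TestEnvironmentBreakdown:
    def test_published_style_counts(self):
        pcts = ab.environment_breakdown(
            {"interior_ice": 3581, "sea_ice_interface": 797,
             "epipelagic": 60, "meso_bathypelagic": 8}
        )
        assert round(pcts["interior_ice"], 2) == 80.54
        assert round(pcts["sea_ice_interface"], 2) == 17.93
        assert round(pcts["epipelagic"], 2) == 1.35
        assert round(pcts["meso_bathypelagic"], 2) == 0.18

    def test_degenerate_and_simple_cases(self):
        assert ab.environment_breakdown({"a": 1, "b": 0})["a"] == 100.0
        pcts = ab.environment_breakdown({"a": 2, "b": 1, "c": 1})
        assert (pcts["a"], pcts["b"], pcts["c"]) == (50.0, 25.0, 25.0)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            ab.environment_breakdown({"a": 0, "b": 0})


class TestLocalizationBreakdown:
    def test_three_protein_enumeration(self):
        archs = [
            _arch("g1", "pfam11999", has_sp=True, n_tmd=0),
            _arch("g2", "pfam11999", has_sp=False, n_tmd=1),
            _arch("g3", "pfam11999", has_sp=True, n_tmd=1),
        ]
        df = ab.localization_breakdown(archs).set_index("statistic")
        assert df.loc["class_sp_only", "percent"] == pytest.approx(100 / 3)
        assert df.loc["class_tmd_only", "percent"] == pytest.approx(100 / 3)
        assert df.loc["class_both", "percent"] == pytest.approx(100 / 3)
        assert df.loc["neither", "percent"] == 0.0
        assert df.loc["sp_and_tmd", "count"] == 1

    def test_all_plain_proteins(self):
        archs = [_arch(f"g{i}", "pfam11999") for i in range(5)]
        df = ab.localization_breakdown(archs).set_index("statistic")
        assert df.loc["neither", "percent"] == 100.0
        assert df.loc["tmd_0", "percent"] == 100.0

    def test_empty_subset_warns_and_is_empty(self):
        df = ab.localization_breakdown([], subset="pfam11999")
        assert df.empty

    def test_planted_bernoulli_sp_rate(self):
        """SP share over n=10,000 Bernoulli(0.4) draws lands within 3 s.e."""
        rng = np.random.default_rng(11)
        n, p = 10_000, 0.4
        archs = [
            _arch(f"g{i}", "pfam11999", has_sp=bool(rng.random() < p))
            for i in range(n)
        ]
        df = ab.localization_breakdown(archs).set_index("statistic")
        se = 100 * (p * (1 - p) / n) ** 0.5
        assert abs(df.loc["sp_any", "percent"] - 40.0) <= 3 * se


class TestTaxonBreakdown:
    def _tax(self, gene_order):
        return {
            g: TaxonomyRecord(g, {"domain": "Bacteria", "order": o})
            for g, o in gene_order.items() if o
        }

    def test_order_classified_total(self):
        # per-order counts 51/17/6/1 among 86 proteins -> classified total 75
        orders = (["Alteromonadales"] * 51 + ["Flavobacteriales"] * 17
                  + ["Cellvibrionales"] * 6 + ["Vibrionales"] * 1 + [None] * 11)
        archs = [_arch(f"g{i}", "pfam11999_pfam16130") for i in range(86)]
        tax = self._tax({f"g{i}": o for i, o in enumerate(orders)})
        df = ab.taxon_breakdown(archs, "order", tax).set_index("taxon")
        assert df.loc["__classified__", "count"] == 75
        assert df.loc["Alteromonadales", "count"] == 51
        assert df.loc["unclassified", "count"] == 11
        assert df.drop("__classified__")["count"].sum() == 86

    def test_no_taxonomy_all_unclassified(self):
        archs = [_arch("g1", "pfam11999")]
        df = ab.taxon_breakdown(archs, "order", {}).set_index("taxon")
        assert df.loc["unclassified", "percent"] == 100.0

    def test_unknown_rank_is_error(self):
        with pytest.raises(ValueError):
            ab.taxon_breakdown([], "species", {})

    def test_planted_synthetic_counts_recovered(self, default_ctx):
        ctx, truth = default_ctx
        df = ab.taxon_breakdown(
            ctx["catalogue"], "order", ctx["taxonomy_by_gene"]
        ).set_index("taxon")
        tt = truth.genes[truth.genes["is_target"] & ~truth.genes["is_eukaryote"]]
        planted = tt[tt["order"] != ""]["order"].value_counts()
        for order, count in planted.items():
            assert df.loc[order, "count"] == count
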