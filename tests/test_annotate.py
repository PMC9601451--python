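import numpy as np
import pandas as pd
import pytest

from rnamsnp import annotate as ann


def _catalogue(rows):
    return pd.DataFrame(
        rows,
        columns=["rsid", "mod_type", "confidence", "effect", "gene", "gene_type", "region"],
    )


@pytest.fixture()
def catalogue():
    return _catalogue(
        [
            ("rs1", "m6A", "high", "loss", "GENE1", "protein_coding", "exonic"),
            ("rs2", "m6A", "low", "gain", "GENE2", "protein_coding", "intronic"),
            ("rs2", "m5C", "medium", "loss", "GENE2", "protein_coding", "intronic"),
            ("rs5", "m1A", "medium", "loss", "GENE3", "noncoding", "other"),
            ("rs99", "m7G", "high", "loss", "GENE4", "protein_coding", "3'UTR"),
        ]
    )


class TestAnnotateGwas:
    def test_inner_join_drops_catalogue_only_snps(self, gwas_frame, catalogue):
        out = ann.annotate_gwas(gwas_frame, catalogue)
        assert "rs99" not in set(out["rsid"])
        # rs2 carries two modification types -> two rows
        assert (out["rsid"] == "rs2").sum() == 2

    def test_threshold_is_strict(self, gwas_frame, catalogue):
        gwas_frame.loc[gwas_frame["rsid"] == "rs1", "pvalue"] = 5e-8
        out = ann.annotate_gwas(gwas_frame, catalogue, p_threshold=5e-8)
        assert not out.loc[out["rsid"] == "rs1", "significant"].iloc[0]

    def test_empty_intersection_warns(self, gwas_frame):
        lonely = _catalogue([("rsX", "m6A", "high", "loss", "G", "protein_coding", "exonic")])
        with pytest.warns(UserWarning, match="no rsID overlap"):
            out = ann.annotate_gwas(gwas_frame, lonely)
        assert out.empty

    def test_bundle_intersection_matches_set_oracle(self, small_bundle):
        gwas = small_bundle["exposure"]
        cat = small_bundle["catalogue"]
        out = ann.annotate_gwas(gwas, cat)
        expected = len(
            set(map(tuple, cat[["rsid", "mod_type"]].values))
            & {(r, m) for r in gwas["rsid"] for m in cat.loc[cat["rsid"] == r, "mod_type"]}
        )
        assert len(out) == expected == len(cat[cat["rsid"].isin(set(gwas["rsid"]))])


class TestSummaries:
    def test_per_type_formatting(self, gwas_frame, catalogue):
        out = ann.annotate_gwas(gwas_frame, catalogue)
        summary = ann.summarize_by_type(out).set_index("mod_type")
        # rs1 (m6A, p=1e-23 significant), rs2 (m6A, p=6.6e-14 significant)
        assert summary.loc["m6A", "formatted"] == "2 (100.00%)"
        assert summary.loc["m1A", "n_significant"] == 0
        assert summary.loc["m1A", "formatted"] == "0 (0.00%)"

    def test_percentages_recompute_from_counts(self, small_bundle):
        out = ann.annotate_gwas(small_bundle["exposure"], small_bundle["catalogue"])
        summary = ann.summarize_by_type(out)
        from rnamsnp._utils import percent

        for _, row in summary.iterrows():
            assert row["pct_significant"] == percent(row["n_significant"], row["n_total"], 2)

    def test_overall_distinct_vs_row_counts(self, gwas_frame, catalogue):
        out = ann.annotate_gwas(gwas_frame, catalogue)
        counts = ann.overall_counts(out)
        assert counts["n_rows"] == 4
        assert counts["n_snps"] == 3  # rs2 counted once
        assert counts["n_rows_significant"] >= counts["n_snps_significant"]

    def test_tally_levels_and_denominators(self, gwas_frame, catalogue):
        out = ann.annotate_gwas(gwas_frame, catalogue)
        tally = ann.tally_classifications(out)
        t = tally.set_index(["category", "level"])
        # distinct SNPs: rs1, rs2 (highest-confidence row kept), rs5
        assert t.loc[("effect", "loss"), "denominator"] == 3
        region_rows = tally[tally["category"] == "region"]
        assert (region_rows["denominator"] == 2).all()  # rs1, rs2 protein-coding


class TestClusterLoci:
    def test_single_snp_single_locus(self):
        df = pd.DataFrame({"rsid": ["rs1"], "chrom": ["1"], "pos": [100], "pvalue": [1e-9]})
        loci = ann.cluster_loci(df)
        assert len(loci) == 1
        assert loci.loc[0, "lead_rsid"] == "rs1"

    def test_window_rule_splits_distant_snps(self):
        df = pd.DataFrame(
            {"rsid": ["rs1", "rs2"], "chrom": ["1", "1"], "pos": [1, 2_000_001], "pvalue": [1e-9, 1e-10]}
        )
        assert len(ann.cluster_loci(df, window_kb=1000)) == 2
        assert len(ann.cluster_loci(df, window_kb=2000)) == 1

    def test_partition_matches_transitive_closure_oracle(self, rng):
        n = 20
        df = pd.DataFrame(
            {
                "rsid": [f"rs{i}" for i in range(n)],
                "chrom": rng.choice(["1", "2"], size=n),
                "pos": rng.integers(1, 5_000_000, size=n),
                "pvalue": rng.random(n) * 1e-8,
            }
        )
        window = 400  # kb
        loci = ann.cluster_loci(df, window_kb=window)
        # brute force: union-find over all pairwise <=window relations
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if df.loc[i, "chrom"] == df.loc[j, "chrom"] and abs(
                    int(df.loc[i, "pos"]) - int(df.loc[j, "pos"])
                ) <= window * 1000:
                    parent[find(i)] = find(j)
        oracle_groups = {}
        for i in range(n):
            oracle_groups.setdefault(find(i), set()).add(df.loc[i, "rsid"])
        got_groups = {frozenset(m.split(",")) for m in loci["members"]}
        assert got_groups == {frozenset(g) for g in oracle_groups.values()}
        # partition property
        assert sum(loci["n_snps"]) == n

    def test_lead_is_smallest_p_then_position(self):
        df = pd.DataFrame(
            {
                "rsid": ["a", "b", "c"],
                "chrom": ["1"] * 3,
                "pos": [300, 100, 200],
                "pvalue": [1e-9, 1e-12, 1e-12],
            }
        )
        loci = ann.cluster_loci(df, window_kb=10)
        assert loci.loc[0, "lead_rsid"] == "b"  # tie at 1e-12, smaller position


class TestLinkQtl:
    @pytest.fixture()
    def annotated(self, gwas_frame, catalogue):
        return ann.annotate_gwas(gwas_frame, catalogue)

    def _qtl(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "rsid",
                "target_id",
                "target_chrom",
                "target_tss",
                "beta",
                "se",
                "pvalue",
                "tissue_or_study",
            ],
        )

    def test_cis_trans_window(self, annotated):
        qtl = self._qtl(
            [
                ("rs1", "G1", "1", 500_100, 0.2, 0.02, 1e-12, "blood"),  # 500 kb away -> cis
                ("rs1", "G2", "2", 100, 0.2, 0.02, 1e-12, "blood"),  # other chrom -> trans
                ("rs2", "G3", "1", 1_100_100, 0.2, 0.02, 1e-12, "blood"),  # 1050 kb -> trans
            ]
        )
        out = ann.link_qtl(annotated, qtl, cis_window_kb=1000, p_signal=5e-5)
        lab = out.set_index("target_id")["cis_trans"]
        assert lab["G1"] == "cis"
        assert lab["G2"] == "trans"
        assert lab["G3"] == "trans"

    def test_signal_filter_matches_manual_count(self, annotated, rng):
        pvals = [1e-6, 2e-5, 5e-5, 6e-5, 1e-4, 0.5, 1e-12, 4.9e-5, 5.1e-5, 0.9, 3e-7, 1.0]
        qtl = self._qtl(
            [(f"rs{1 + (i % 2)}", f"G{i}", "1", 100 + i, 0.1, 0.02, p, "blood") for i, p in enumerate(pvals)]
        )
        out = ann.link_qtl(annotated, qtl, p_signal=5e-5)
        manual = sum(p < 5e-5 for p in pvals)  # strict: 5e-5 itself excluded
        assert len(out) == manual == 5

    def test_missing_tss_labelled_unknown(self, annotated):
        qtl = self._qtl([("rs1", "G1", np.nan, np.nan, 0.2, 0.02, 1e-12, "blood")])
        with pytest.warns(UserWarning, match="unknown"):
            out = ann.link_qtl(annotated, qtl)
        assert out.loc[0, "cis_trans"] == "unknown"

    def test_link_rate(self, annotated):
        qtl = self._qtl(
            [
                ("rs1", "G1", "1", 200, 0.2, 0.02, 1e-12, "blood"),
                ("rs2", "G2", "9", 100, 0.2, 0.02, 1e-12, "blood"),
            ]
        )
        out = ann.link_qtl(annotated, qtl)
        rate = ann.qtl_link_rate(out)
        assert rate == {"n_with_cis": 1, "n_total": 2, "pct_cis": 50.0}
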