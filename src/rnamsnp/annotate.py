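"""Annotation of GWAS summary statistics with the RNA-modification catalogue.

Joins the two tables on rsID, applies the genome-wide significance gate
(strict ``p < 5e-8`` by default), produces the per-modification-type summary
(counts with percentages at 2 decimals, half-up), the gain/loss,
confidence-tier and gene-region tallies (1 decimal), chains significant
SNPs into loci, and links annotated SNPs to QTL signals with cis/trans
labels.

A SNP may carry several modification types: it contributes one row per type
to the per-type summary but is counted once in overall distinct-SNP counts;
both counts are reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._utils import percent

__all__ = [
    "annotate_gwas",
    "summarize_by_type",
    "overall_counts",
    "tally_classifications",
    "cluster_loci",
    "link_qtl",
    "qtl_link_rate",
]

GENOME_WIDE_P = 5e-8


def annotate_gwas(
    gwas: pd.DataFrame, catalogue: pd.DataFrame, p_threshold: float = GENOME_WIDE_P
) -> pd.DataFrame:
    """Inner-join GWAS records with catalogue entries on rsID.

    One output row per ``(rsid, mod_type)`` pair; the ``significant`` flag
    uses a strict comparison, so a p-value exactly equal to the threshold is
    not significant.
    """
    merged = gwas.merge(catalogue, on="rsid", how="inner", suffixes=("", "_cat"))
    if merged.empty:
        warnings.warn("no rsID overlap between GWAS and catalogue; annotated table is empty")
    merged["significant"] = merged["pvalue"] < p_threshold
    return merged.reset_index(drop=True)


def summarize_by_type(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-modification-type tallies of catalogue SNPs found in the GWAS.

    Returns one row per modification type with ``n_total`` (all annotated
    rows of that type), ``n_significant``, ``pct_significant`` (half-up, 2
    decimals) and the printed-style string ``formatted`` = ``"N (P%)"``.
    Percentages recompute exactly from the reported counts.
    """
    rows = []
    for mod_type, grp in annotated.groupby("mod_type", sort=True):
        total = len(grp)
        sig = int(grp["significant"].sum())
        pct = percent(sig, total, 2)
        rows.append(
            {
                "mod_type": mod_type,
                "n_total": total,
                "n_significant": sig,
                "pct_significant": pct,
                "formatted": f"{sig} ({pct:.2f}%)",
            }
        )
    out = pd.DataFrame(rows, columns=["mod_type", "n_total", "n_significant", "pct_significant", "formatted"])
    _check_percent_consistency(out["n_significant"], out["n_total"], out["pct_significant"], 2)
    return out


def overall_counts(annotated: pd.DataFrame) -> dict:
    """Row-wise and distinct-SNP counts, overall and among significant SNPs."""
    sig = annotated[annotated["significant"]]
    return {
        "n_rows": len(annotated),
        "n_rows_significant": len(sig),
        "n_snps": annotated["rsid"].nunique(),
        "n_snps_significant": sig["rsid"].nunique(),
    }


def _check_percent_consistency(counts, totals, pcts, ndigits) -> None:
    """Internal consistency: printed percentage recomputes from printed counts."""
    for c, t, p in zip(counts, totals, pcts):
        assert percent(int(c), int(t), ndigits) == p, (c, t, p)


def tally_classifications(annotated: pd.DataFrame, significant_only: bool = False) -> pd.DataFrame:
    """Gain/loss, confidence and (protein-coding) region tallies.

    Counts are over distinct SNPs (a SNP with several modification types is
    counted once, keeping its highest-confidence entry); percentages are
    half-up at 1 decimal and each row carries its denominator.  Region
    classes are tallied over SNPs in protein-coding genes only.  A combined
    ``high_or_medium`` confidence row is included.
    """
    df = annotated
    if significant_only:
        df = df[df["significant"]]
    conf_rank = {"high": 0, "medium": 1, "low": 2}
    dedup = (
        df.assign(_rank=df["confidence"].map(conf_rank))
        .sort_values(["rsid", "_rank"], kind="mergesort")
        .drop_duplicates("rsid", keep="first")
    )
    n = len(dedup)
    rows = []

    def add(category, level, count, denom):
        rows.append(
            {
                "category": category,
                "level": level,
                "count": int(count),
                "denominator": int(denom),
                "pct": percent(int(count), int(denom), 1),
            }
        )

    for level in ("gain", "loss"):
        add("effect", level, (dedup["effect"] == level).sum(), n)
    for level in ("high", "medium", "low"):
        add("confidence", level, (dedup["confidence"] == level).sum(), n)
    add("confidence", "high_or_medium", dedup["confidence"].isin(["high", "medium"]).sum(), n)
    coding = dedup[dedup["gene_type"] == "protein_coding"]
    for level in ("exonic", "3'UTR", "5'UTR", "intronic", "other"):
        add("region", level, (coding["region"] == level).sum(), len(coding))
    out = pd.DataFrame(rows, columns=["category", "level", "count", "denominator", "pct"])
    _check_percent_consistency(out["count"], out["denominator"].replace(0, 1), out["pct"], 1)
    return out


def cluster_loci(significant: pd.DataFrame, window_kb: int = 1000) -> pd.DataFrame:
    """Chain significant SNPs into loci by single linkage within a window.

    Per chromosome, SNPs sorted by position are chained: a SNP within
    ``window_kb`` of its predecessor joins the predecessor's locus.  The
    output is a partition of the input SNPs.  The lead SNP of a locus is its
    smallest-p member, ties broken by smallest position.
    """
    window = window_kb * 1000
    df = significant.drop_duplicates("rsid")
    loci = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values(["pos", "rsid"], kind="mergesort")
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > window)
        bounds = [0, *list(breaks + 1), len(grp)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            members = grp.iloc[a:b]
            lead = members.sort_values(["pvalue", "pos"], kind="mergesort").iloc[0]
            loci.append(
                {
                    "chrom": str(chrom),
                    "start": int(members["pos"].min()),
                    "end": int(members["pos"].max()),
                    "n_snps": len(members),
                    "lead_rsid": lead["rsid"],
                    "lead_pvalue": float(lead["pvalue"]),
                    "members": ",".join(members["rsid"]),
                }
            )
    out = pd.DataFrame(
        loci, columns=["chrom", "start", "end", "n_snps", "lead_rsid", "lead_pvalue", "members"]
    )
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def link_qtl(
    annotated: pd.DataFrame,
    qtl: pd.DataFrame,
    cis_window_kb: int = 1000,
    p_signal: float = 5e-5,
) -> pd.DataFrame:
    """Join annotated SNPs to QTL records and keep significant signals.

    Rows with QTL ``pvalue < p_signal`` (strict) survive.  A signal is
    ``cis`` when SNP and target share a chromosome and the SNP sits within
    ``cis_window_kb`` of the target TSS, ``trans`` otherwise; rows lacking a
    TSS are labelled ``unknown`` with a warning.
    """
    snp_cols = ["rsid", "chrom", "pos", "gene", "significant"]
    snp_cols = [c for c in snp_cols if c in annotated.columns]
    left = annotated[snp_cols].drop_duplicates("rsid")
    merged = left.merge(qtl, on="rsid", how="inner", suffixes=("", "_qtl"))
    merged = merged[merged["pvalue_qtl" if "pvalue_qtl" in merged else "pvalue"] < p_signal]
    pcol = "pvalue_qtl" if "pvalue_qtl" in merged else "pvalue"
    merged = merged.rename(columns={pcol: "qtl_pvalue"}) if pcol != "qtl_pvalue" else merged

    window = cis_window_kb * 1000
    labels = []
    n_unknown = 0
    for row in merged.itertuples(index=False):
        tss = getattr(row, "target_tss", np.nan)
        tchrom = getattr(row, "target_chrom", np.nan)
        if pd.isna(tss):
            labels.append("unknown")
            n_unknown += 1
            continue
        same_chrom = pd.notna(tchrom) and str(tchrom) == str(row.chrom)
        labels.append("cis" if same_chrom and abs(int(row.pos) - int(tss)) <= window else "trans")
    merged = merged.copy()
    merged["cis_trans"] = labels
    if n_unknown:
        warnings.warn(f"{n_unknown} QTL link(s) lack a target TSS; labelled 'unknown'")
    return merged.reset_index(drop=True)


def qtl_link_rate(linked: pd.DataFrame) -> dict:
    """Share of linked SNPs with at least one cis signal (1-decimal percent)."""
    n_total = linked["rsid"].nunique()
    n_cis = linked.loc[linked["cis_trans"] == "cis", "rsid"].nunique()
    return {"n_with_cis": n_cis, "n_total": n_total, "pct_cis": percent(n_cis, n_total, 1)}
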