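"""Instrument construction for two-sample MR.

Three steps: select candidate instruments from the exposure table by a
strict p-value threshold; harmonize exposure and outcome alleles so both
effects refer to the same allele (flipping outcome signs and frequencies
where the allele pair is swapped, dropping strand-ambiguous palindromic
SNPs whose frequency is uninformative and pairs whose allele sets cannot be
reconciled); greedily LD-clump to a quasi-independent set (r-squared below
threshold within a distance window, best-p SNP kept first).

No strand-complement inference is attempted for non-palindromic mismatches:
an A/G vs T/C pair is reported as ``dropped_mismatch`` rather than silently
strand-flipped.  Palindromic SNPs (A/T or C/G) whose allele frequency lies
outside the ambiguity band in both studies are aligned by frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import LdPanel

__all__ = ["ClumpConfig", "select_instruments", "harmonize", "ld_clump", "retained"]

ACTIONS = ("kept", "flipped", "dropped_palindromic", "dropped_mismatch")


@dataclass
class ClumpConfig:
    r2_threshold: float = 0.001
    window_kb: int = 10_000
    p_instrument: float = 5e-4

    def __post_init__(self):
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")


def select_instruments(exposure: pd.DataFrame, p_instrument: float = 5e-4) -> pd.DataFrame:
    """Rows of the exposure table with p-value strictly below the threshold."""
    out = exposure[exposure["pvalue"] < p_instrument].reset_index(drop=True)
    if out.empty:
        warnings.warn(f"no instrument candidate passes p < {p_instrument}")
    return out


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _ambiguous_eaf(eaf, band: float) -> bool:
    """True when the frequency cannot resolve strand: missing or near 0.5."""
    if pd.isna(eaf):
        return True
    return abs(float(eaf) - 0.5) <= band


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_band: float = 0.08,
    drop_all_palindromic: bool = False,
) -> pd.DataFrame:
    """Merge exposure and outcome on rsID and align effect alleles.

    Returns one row per shared rsID with columns
    ``beta_exposure/se_exposure/pvalue_exposure``,
    ``beta_outcome/se_outcome/pvalue_outcome`` (outcome effects re-expressed
    on the exposure's effect allele) and ``harmonization_action`` in
    ``{kept, flipped, dropped_palindromic, dropped_mismatch}``.  Dropped
    rows stay in the table (with their action label) so that
    kept + flipped + dropped = shared rsIDs; use :func:`retained` to get
    the MR-ready subset.
    """
    exp = exposure.drop_duplicates("rsid")
    out = outcome.drop_duplicates("rsid")
    merged = exp.merge(out, on="rsid", how="inner", suffixes=("_exp", "_out"))

    rows = []
    for r in merged.itertuples(index=False):
        ea_x, oa_x = r.effect_allele_exp, r.other_allele_exp
        ea_y, oa_y = r.effect_allele_out, r.other_allele_out
        beta_y, eaf_y = r.beta_out, r.eaf_out
        palindromic = _is_palindromic(ea_x, oa_x)
        if {ea_x, oa_x} != {ea_y, oa_y}:
            action = "dropped_mismatch"
        elif palindromic and (
            drop_all_palindromic
            or _ambiguous_eaf(r.eaf_exp, palindromic_eaf_band)
            or _ambiguous_eaf(r.eaf_out, palindromic_eaf_band)
        ):
            action = "dropped_palindromic"
        elif palindromic:
            # both frequencies informative: align by frequency, since the
            # allele labels of a palindromic SNP are strand-ambiguous
            same_side = (float(r.eaf_exp) - 0.5) * (float(r.eaf_out) - 0.5) > 0
            if same_side:
                action = "kept"
            else:
                action = "flipped"
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
        elif ea_y == ea_x and oa_y == oa_x:
            action = "kept"
        else:  # swapped labels
            action = "flipped"
            beta_y = -beta_y
            eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
        rows.append(
            {
                "rsid": r.rsid,
                "chrom": getattr(r, "chrom_exp", getattr(r, "chrom", None)),
                "pos": getattr(r, "pos_exp", getattr(r, "pos", None)),
                "effect_allele": ea_x,
                "other_allele": oa_x,
                "eaf_exposure": r.eaf_exp,
                "eaf_outcome": eaf_y,
                "beta_exposure": r.beta_exp,
                "se_exposure": r.se_exp,
                "pvalue_exposure": r.pvalue_exp,
                "beta_outcome": beta_y,
                "se_outcome": r.se_out,
                "pvalue_outcome": r.pvalue_out,
                "harmonization_action": action,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "rsid",
            "chrom",
            "pos",
            "effect_allele",
            "other_allele",
            "eaf_exposure",
            "eaf_outcome",
            "beta_exposure",
            "se_exposure",
            "pvalue_exposure",
            "beta_outcome",
            "se_outcome",
            "pvalue_outcome",
            "harmonization_action",
        ],
    )
    return table


def retained(instrument_table: pd.DataFrame) -> pd.DataFrame:
    """Rows surviving harmonization (action kept or flipped)."""
    keep = instrument_table["harmonization_action"].isin(["kept", "flipped"])
    return instrument_table[keep].reset_index(drop=True)


def ld_clump(
    candidates: pd.DataFrame,
    ld: LdPanel,
    config: ClumpConfig | None = None,
) -> pd.DataFrame:
    """Greedy LD clumping of candidate instruments.

    Sort by exposure p ascending (ties: position, then rsID); keep the
    head; remove every SNP within ``window_kb`` of a kept SNP with
    r-squared at or above ``r2_threshold`` against it; repeat.  Pairs
    missing from the LD panel count as r-squared 0 (the panel warns once).
    Needs ``chrom``/``pos`` columns; the exposure p-value column may be
    named ``pvalue_exposure`` or ``pvalue``.
    """
    config = config or ClumpConfig()
    pcol = "pvalue_exposure" if "pvalue_exposure" in candidates.columns else "pvalue"
    df = candidates.sort_values([pcol, "pos", "rsid"], kind="mergesort").reset_index(drop=True)
    window = config.window_kb * 1000
    alive = np.ones(len(df), dtype=bool)
    kept_idx = []
    rsids = df["rsid"].to_numpy()
    chroms = df["chrom"].astype(str).to_numpy()
    poss = df["pos"].to_numpy()
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept_idx.append(i)
        for j in range(len(df)):
            if not alive[j] or j == i:
                continue
            if chroms[j] != chroms[i]:
                continue
            if abs(int(poss[j]) - int(poss[i])) > window:
                continue
            if ld.r2(rsids[i], rsids[j]) >= config.r2_threshold:
                alive[j] = False
    return df.iloc[kept_idx].reset_index(drop=True)
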