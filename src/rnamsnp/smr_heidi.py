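"""Summary-data-based MR (SMR) and the HEIDI heterogeneity test.

SMR tests whether a trait and a gene's expression share a genetic signal at
the gene's top cis-eQTL.  With ``z1 = beta_GWAS/se_GWAS`` and
``z2 = beta_eQTL/se_eQTL``, the statistic

.. math:: T_{SMR} = \\frac{z_1^2 z_2^2}{z_1^2 + z_2^2}

is referred to a 1-df chi-square; the effect of expression on trait is
``b_xy = beta_GWAS / beta_eQTL`` with ``se = |b_xy| / sqrt(T_SMR)``.

A significant SMR test is compatible with two genetic architectures: one
shared causal variant (pleiotropy, the interesting case) or two distinct
variants in LD (linkage).  HEIDI discriminates them: under a single shared
variant, ``b_xy`` estimated at any SNP in LD with the top eQTL equals the
top SNP's value up to sampling noise.  For the eligible SNPs (strong eQTL
z-score, LD to the top SNP inside a band), the differences
``d_i = b_xy(i) - b_xy(top)`` are jointly normal with a covariance obtained
by first-order error propagation, using the LD correlation r as the
correlation between effect estimates within each study (studies
independent).  ``T_HEIDI = sum_i z_{d_i}^2`` follows a weighted sum of
1-df chi-squares with weights the eigenvalues of the correlation matrix of
``z_d``; the p-value uses Satterthwaite moment matching by default, with a
multivariate-normal Monte-Carlo mode as oracle and fallback.  A small
HEIDI p rejects the single-variant model; ``p > 0.05`` supports it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import as_rng
from .io_formats import LdPanel

__all__ = ["SmrResult", "smr_test", "heidi_test", "smr_scan"]


@dataclass
class SmrResult:
    target_id: str
    top_snp: str
    b_xy: float
    se_bxy: float
    T_smr: float
    p_smr: float
    T_heidi: float
    p_heidi: float
    n_heidi_snps: int
    heidi_method: str
    pass_smr: bool
    pass_heidi: bool
    tissue: str = "unknown"

    def as_row(self) -> dict:
        return {
            "target_id": self.target_id,
            "tissue": self.tissue,
            "top_snp": self.top_snp,
            "b_xy": self.b_xy,
            "se_bxy": self.se_bxy,
            "T_smr": self.T_smr,
            "p_smr": self.p_smr,
            "T_heidi": self.T_heidi,
            "p_heidi": self.p_heidi,
            "n_heidi_snps": self.n_heidi_snps,
            "heidi_method": self.heidi_method,
            "pass_smr": self.pass_smr,
            "pass_heidi": self.pass_heidi,
        }


def smr_test(beta_gwas: float, se_gwas: float, beta_eqtl: float, se_eqtl: float):
    """SMR statistic at one SNP: returns ``(b_xy, se_bxy, T_smr, p_smr)``."""
    if se_gwas <= 0 or se_eqtl <= 0:
        raise ValueError("standard errors must be positive")
    if beta_eqtl == 0:
        raise ValueError("beta_eqtl is zero; b_xy undefined")
    z1 = beta_gwas / se_gwas
    z2 = beta_eqtl / se_eqtl
    t = (z1**2 * z2**2) / (z1**2 + z2**2)
    p = float(stats.chi2.sf(t, df=1))
    b_xy = beta_gwas / beta_eqtl
    se_bxy = abs(b_xy) / np.sqrt(t) if t > 0 else float("inf")
    return float(b_xy), float(se_bxy), float(t), p


def _bxy_covariance(bg, seg, be, see, R):
    """Covariance matrix of the per-SNP b_xy vector by the delta method.

    ``cov(bhat_i, bhat_j) = r_ij se_i se_j`` within each study; the GWAS and
    eQTL studies are independent.
    """
    inv_be = 1.0 / be
    # d b/d bg = 1/be ; d b/d be = -bg/be^2
    g1 = inv_be
    g2 = -bg * inv_be**2
    cov_g = R * np.outer(seg, seg)
    cov_e = R * np.outer(see, see)
    return np.outer(g1, g1) * cov_g + np.outer(g2, g2) * cov_e


def heidi_test(
    region: pd.DataFrame,
    ld: LdPanel,
    top_snp: str,
    z_eqtl_min: float = 3.16,
    r2_band: tuple = (0.05, 0.9),
    max_snps: int = 20,
    method: str = "satterthwaite",
    n_mc: int = 100_000,
    seed=None,
):
    """HEIDI test around a top eQTL SNP.

    ``region`` needs columns ``rsid, beta_gwas, se_gwas, beta_eqtl,
    se_eqtl`` and must contain ``top_snp``.  SNPs other than the top with
    ``|z_eqtl| >= z_eqtl_min`` and squared LD correlation to the top SNP
    inside ``r2_band`` are eligible; at most ``max_snps`` are used, by eQTL
    significance.  Returns ``(T_heidi, p_heidi, n_used, method)``; with
    fewer than 3 eligible SNPs the result is ``(nan, nan, n,
    "insufficient_snps")``.
    """
    df = region.drop_duplicates("rsid").set_index("rsid", drop=False)
    if top_snp not in df.index:
        raise ValueError(f"top SNP {top_snp} absent from region")
    z_eqtl = df["beta_eqtl"] / df["se_eqtl"]
    r_to_top = np.array([ld.r(top_snp, s) for s in df.index])
    r2_to_top = r_to_top**2
    eligible = (
        (df.index != top_snp)
        & (np.abs(z_eqtl) >= z_eqtl_min)
        & (r2_to_top >= r2_band[0])
        & (r2_to_top <= r2_band[1])
    )
    chosen = df[eligible].copy()
    if len(chosen) < 3:
        return float("nan"), float("nan"), int(len(chosen)), "insufficient_snps"
    if len(chosen) > max_snps:
        chosen = chosen.loc[np.abs(chosen["beta_eqtl"] / chosen["se_eqtl"]).nlargest(max_snps).index]

    snps = [top_snp, *chosen["rsid"].tolist()]
    sub = df.loc[snps]
    bg = sub["beta_gwas"].to_numpy(dtype=float)
    seg = sub["se_gwas"].to_numpy(dtype=float)
    be = sub["beta_eqtl"].to_numpy(dtype=float)
    see = sub["se_eqtl"].to_numpy(dtype=float)
    if np.any(be == 0):
        raise ValueError("zero eQTL effect in HEIDI region")
    R = ld.corr_matrix(snps)

    b = bg / be
    cov_b = _bxy_covariance(bg, seg, be, see, R)
    m = len(snps) - 1
    # d_i = b_i - b_top  (top is index 0)
    A = np.zeros((m, len(snps)))
    A[:, 0] = -1.0
    A[np.arange(m), np.arange(1, m + 1)] = 1.0
    d = A @ b
    cov_d = A @ cov_b @ A.T
    sd = np.sqrt(np.diag(cov_d))
    zd = d / sd
    C = cov_d / np.outer(sd, sd)
    T = float(np.sum(zd**2))

    lam = np.linalg.eigvalsh(C)
    lam = lam[lam > 1e-12]
    if method == "satterthwaite":
        scale = float(np.sum(lam**2) / np.sum(lam))
        dof = float(np.sum(lam) ** 2 / np.sum(lam**2))
        p = float(stats.chi2.sf(T / scale, df=dof))
    elif method == "mc":
        rng = as_rng(seed)
        # simulate zd ~ MVN(0, C) through the eigendecomposition (C may be
        # numerically semidefinite)
        vals, vecs = np.linalg.eigh(C)
        vals = np.clip(vals, 0.0, None)
        L = vecs * np.sqrt(vals)
        draws = rng.standard_normal((n_mc, len(vals))) @ L.T
        p = float(np.mean(np.sum(draws**2, axis=1) >= T))
    else:
        raise ValueError("method must be 'satterthwaite' or 'mc'")
    return T, p, m, method


def smr_scan(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    ld: LdPanel,
    p_eqtl_top: float = 5e-8,
    p_smr_threshold: float = 5e-6,
    heidi_gate: float = 0.05,
    cis_window_kb: int = 1000,
    heidi_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Run SMR + HEIDI for every eQTL target.

    For each ``(target_id, tissue_or_study)`` group: pick the top eQTL SNP
    (smallest eQTL p; must pass ``p_eqtl_top`` and occur in the GWAS,
    otherwise the target is skipped), compute the SMR test there, and run
    HEIDI on the cis-region SNPs shared between the eQTL and GWAS tables.
    ``pass_smr`` is ``p_smr < p_smr_threshold`` (strict) and ``pass_heidi``
    is ``p_heidi > heidi_gate`` (strict).
    """
    heidi_kwargs = heidi_kwargs or {}
    gw = gwas.drop_duplicates("rsid").set_index("rsid")
    rows = []
    group_cols = ["target_id"]
    if "tissue_or_study" in eqtl.columns:
        group_cols.append("tissue_or_study")
    for keys, grp in eqtl.groupby(group_cols, sort=True):
        target = keys[0] if isinstance(keys, tuple) else keys
        tissue = keys[1] if isinstance(keys, tuple) and len(keys) > 1 else "unknown"
        grp = grp.drop_duplicates("rsid")
        shared = grp[grp["rsid"].isin(gw.index)]
        if shared.empty:
            continue
        tss = shared["target_tss"].dropna()
        if len(tss) and "pos" in gw.columns:
            window = cis_window_kb * 1000
            pos = gw.loc[shared["rsid"], "pos"].to_numpy()
            shared = shared[np.abs(pos - float(tss.iloc[0])) <= window]
        if shared.empty:
            continue
        top = shared.loc[shared["pvalue"].idxmin()]
        if top["pvalue"] >= p_eqtl_top:
            continue  # no SNP passes the top-eQTL gate; target skipped
        g = gw.loc[top["rsid"]]
        b_xy, se_bxy, t_smr, p_smr = smr_test(g["beta"], g["se"], top["beta"], top["se"])
        region = pd.DataFrame(
            {
                "rsid": shared["rsid"].to_numpy(),
                "beta_gwas": gw.loc[shared["rsid"], "beta"].to_numpy(),
                "se_gwas": gw.loc[shared["rsid"], "se"].to_numpy(),
                "beta_eqtl": shared["beta"].to_numpy(),
                "se_eqtl": shared["se"].to_numpy(),
            }
        )
        region = region[region["beta_eqtl"] != 0]
        t_heidi, p_heidi, n_used, method = heidi_test(region, ld, top["rsid"], **heidi_kwargs)
        rows.append(
            SmrResult(
                target_id=str(target),
                top_snp=str(top["rsid"]),
                b_xy=b_xy,
                se_bxy=se_bxy,
                T_smr=t_smr,
                p_smr=p_smr,
                T_heidi=t_heidi,
                p_heidi=p_heidi,
                n_heidi_snps=n_used,
                heidi_method=method,
                pass_smr=bool(p_smr < p_smr_threshold),
                pass_heidi=bool(p_heidi > heidi_gate) if np.isfinite(p_heidi) else False,
                tissue=str(tissue),
            ).as_row()
        )
    return pd.DataFrame(
        rows,
        columns=[
            "target_id",
            "tissue",
            "top_snp",
            "b_xy",
            "se_bxy",
            "T_smr",
            "p_smr",
            "T_heidi",
            "p_heidi",
            "n_heidi_snps",
            "heidi_method",
            "pass_smr",
            "pass_heidi",
        ],
    )
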