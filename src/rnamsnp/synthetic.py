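"""Synthetic GWAS / QTL / catalogue generator with a persisted truth record.

The generative model is a two-sample structural model on individual-level
data:

.. math::

    X = \\sum_j \\gamma_j G_j + \\varepsilon_x, \\qquad
    Y = \\beta X + \\sum_j \\alpha_j G_j + \\varepsilon_y

where :math:`G_j` are SNP dosages with blockwise AR(1) linkage
disequilibrium, :math:`\\gamma_j` are SNP-exposure effects concentrated on
``n_causal`` SNPs and rescaled so the genetic component of the exposure
explains exactly ``heritability_x`` of its variance, :math:`\\beta` is the
causal effect of the exposure on the outcome, and :math:`\\alpha_j` are
direct (horizontally pleiotropic) SNP-outcome effects carried by a
``pleiotropy_fraction`` share of the causal SNPs.  Summary statistics are
exact per-SNP ordinary-least-squares marginal regressions on the simulated
individuals, so z-score calibration holds by construction rather than by
approximation.  Exposure and outcome cohorts are independent draws from the
same SNP parameters (two-sample design) unless requested otherwise.

An RNA-modification flag is assigned to each SNP at ``rnam_base_rate``,
multiplied by ``rnam_enrichment`` at causal SNPs (capped at 1), which gives
the enrichment stage a known ground truth.

Dosages come from thresholding latent AR(1) Gaussians at MAF-determined
quantiles (two haplotypes summed): adjacent SNPs at lag k within a block
have latent correlation ``rho**k``; blocks are independent.  All generators
are byte-identical under a fixed ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import as_rng
from .io_formats import GWAS_COLUMNS, LdPanel, MOD_TYPES, write_ld_dosages, write_results

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "gen_ld_panel",
    "gen_summary_stats",
    "gen_rnam_catalogue",
    "gen_qtl_stats",
    "gen_instrument_stats",
    "gen_smr_scenario",
    "gen_gene_sets",
    "simulate_bundle",
    "marginal_ols",
]

#: Default categorical distributions for catalogue annotation fields,
#: loosely shaped like the composition of public RNA-modification catalogues
#: (m6A dominates; most flagged sites are "functional loss").
DEFAULT_MOD_TYPE_PROBS = {
    "m6A": 0.83,
    "m1A": 0.05,
    "m7G": 0.02,
    "A-to-I": 0.03,
    "m5C": 0.02,
    "m5U": 0.01,
    "m6Am": 0.02,
    "2'-O-Me": 0.01,
    "pseudouridine": 0.01,
}
DEFAULT_CONFIDENCE_PROBS = {"high": 0.42, "medium": 0.25, "low": 0.33}
DEFAULT_EFFECT_PROBS = {"gain": 0.14, "loss": 0.86}
DEFAULT_GENE_TYPE_PROBS = {"protein_coding": 0.85, "noncoding": 0.15}
DEFAULT_REGION_PROBS = {"exonic": 0.29, "3'UTR": 0.20, "5'UTR": 0.05, "intronic": 0.46}

_DEFAULT_SEED = 20221018


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Defaults describe the bundled study conditions: 10,000 SNPs in 200
    LD blocks of 50, moderate within-block LD (rho = 0.5), 40 causal SNPs
    jointly explaining 60% of exposure variance (strong per-SNP signals,
    each individually detectable at genome-wide significance at the default
    cohort size), a causal exposure-outcome effect of 0.1, no horizontal
    pleiotropy, and an RNA-modification flag base rate of 5% enriched
    5-fold at causal SNPs.
    """

    n_individuals: int = 4000
    n_blocks: int = 200
    snps_per_block: int = 50
    rho: float = 0.5
    maf_range: tuple = (0.05, 0.5)
    n_causal: int = 40
    heritability_x: float = 0.6
    beta_causal: float = 0.1
    pleiotropy_fraction: float = 0.0
    alpha_scale: float = 0.0
    rnam_base_rate: float = 0.05
    rnam_enrichment: float = 5.0
    seed: int = _DEFAULT_SEED

    def __post_init__(self):
        if not (0 <= self.rho < 1):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.snps_per_block < 1:
            raise ValueError("snps_per_block must be >= 1")
        if self.n_causal > self.n_blocks * self.snps_per_block:
            raise ValueError("n_causal exceeds total SNP count")
        if not (0 <= self.heritability_x < 1):
            raise ValueError("heritability_x must be in [0, 1)")
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise ValueError("pleiotropy_fraction must be in [0, 1]")
        if not (0 < self.rnam_base_rate < 1):
            raise ValueError("rnam_base_rate must be in (0, 1)")
        if self.rnam_enrichment < 1:
            raise ValueError("rnam_enrichment must be >= 1")

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block


@dataclass
class TruthRecord:
    """Ground truth persisted alongside a simulated bundle."""

    rsids: list
    gamma: np.ndarray
    alpha: np.ndarray
    causal: np.ndarray
    beta: float
    seed: int
    realized_h2: float = float("nan")
    rnam_flags: np.ndarray | None = None
    catalogue_probs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "rsids": list(self.rsids),
            "gamma": np.asarray(self.gamma).tolist(),
            "alpha": np.asarray(self.alpha).tolist(),
            "causal": np.asarray(self.causal).astype(bool).tolist(),
            "beta": self.beta,
            "seed": self.seed,
            "realized_h2": self.realized_h2,
            "rnam_flags": (
                None if self.rnam_flags is None else np.asarray(self.rnam_flags).astype(bool).tolist()
            ),
            "catalogue_probs": self.catalogue_probs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            rsids=d["rsids"],
            gamma=np.asarray(d["gamma"]),
            alpha=np.asarray(d["alpha"]),
            causal=np.asarray(d["causal"], dtype=bool),
            beta=d["beta"],
            seed=d["seed"],
            realized_h2=d.get("realized_h2", float("nan")),
            rnam_flags=None if d.get("rnam_flags") is None else np.asarray(d["rnam_flags"], dtype=bool),
            catalogue_probs=d.get("catalogue_probs", {}),
        )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _block_latents(n: int, n_blocks: int, length: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Latent AR(1) Gaussians for equal-length blocks: (n, n_blocks * length).

    The recursion over SNP lag runs once for all blocks simultaneously,
    which keeps the per-step work a single (n, n_blocks) vector operation.
    """
    z = np.empty((n, n_blocks, length), dtype=np.float32)
    z[:, :, 0] = rng.standard_normal((n, n_blocks), dtype=np.float32)
    c = np.float32(np.sqrt(1.0 - rho**2))
    rho = np.float32(rho)
    for k in range(1, length):
        z[:, :, k] = rho * z[:, :, k - 1] + c * rng.standard_normal((n, n_blocks), dtype=np.float32)
    return z.reshape(n, n_blocks * length)


def _draw_dosages(mafs: np.ndarray, block_sizes, rho: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Dosage matrix (n, m): two thresholded latent-Gaussian haplotypes summed."""
    thresholds = stats.norm.ppf(mafs)
    out = np.zeros((n, len(mafs)), dtype=np.int8)
    sizes = list(block_sizes)
    if len(set(sizes)) == 1:
        for _hap in range(2):
            z = _block_latents(n, len(sizes), sizes[0], rho, rng)
            out += z < thresholds
        return out
    start = 0
    for size in sizes:
        th = thresholds[start : start + size]
        for _hap in range(2):
            z = _block_latents(n, 1, size, rho, rng)
            out[:, start : start + size] += z < th
        start += size
    return out


def gen_ld_panel(config: SimulationConfig, rng=None) -> LdPanel:
    """Simulate the reference cohort's dosage matrix with blockwise AR(1) LD.

    Blocks are laid out on chromosomes 1-22 round-robin, 5 kb between
    adjacent SNPs and 10 Mb between adjacent blocks on the same chromosome,
    so distance-windowed operations (clumping, cis labelling, locus
    chaining) see realistic coordinates.
    """
    rng = as_rng(rng if rng is not None else np.random.default_rng([config.seed, 1]))
    m = config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    block_sizes = [config.snps_per_block] * config.n_blocks
    dosages = _draw_dosages(mafs, block_sizes, config.rho, config.n_individuals, rng)

    rsids = [f"rs{i + 1}" for i in range(m)]
    block_idx = np.repeat(np.arange(config.n_blocks), config.snps_per_block)
    chrom = (block_idx % 22) + 1
    block_on_chrom = block_idx // 22
    pos = block_on_chrom * 10_000_000 + (np.arange(m) % config.snps_per_block) * 5_000 + 1
    snp_info = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": chrom.astype(str),
            "pos": pos.astype(int),
            "maf": mafs,
            "block": block_idx,
        }
    )
    panel = LdPanel.from_dosages(pd.DataFrame(dosages, columns=rsids), snp_info=snp_info)
    panel.generation = {"mafs": mafs, "block_sizes": block_sizes, "rho": config.rho}
    return panel


def _resample_genotypes(panel: LdPanel, n: int, rng: np.random.Generator) -> np.ndarray:
    """An independent cohort drawn from the panel's SNP parameters."""
    gen = getattr(panel, "generation", None)
    if gen is None:
        raise ValueError("panel was not produced by gen_ld_panel; cannot resample a second cohort")
    return _draw_dosages(gen["mafs"], gen["block_sizes"], gen["rho"], n, rng)


# ---------------------------------------------------------------------------
# Marginal summary statistics
# ---------------------------------------------------------------------------


def marginal_ols(G: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Exact per-SNP simple linear regression of ``y`` on each dosage column.

    Returns columns ``beta``, ``se``, ``pvalue`` (two-sided t, n-2 df,
    floored at 1e-300), ``eaf`` (observed allele frequency).  Monomorphic
    SNPs get beta 0, a huge SE and p = 1.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    yc = y - y.mean()
    syy = float(yc @ yc)
    gmean = G.mean(axis=0)
    sxx = np.einsum("ij,ij->j", G, G) - n * gmean**2
    sxy = G.T @ yc
    ok = sxx > 0
    beta = np.zeros(m)
    se = np.full(m, 1e6)
    pval = np.ones(m)
    beta[ok] = sxy[ok] / sxx[ok]
    sigma2 = np.maximum(syy - beta[ok] * sxy[ok], 0.0) / (n - 2)
    se[ok] = np.sqrt(np.maximum(sigma2, 1e-24) / sxx[ok])
    tstat = beta[ok] / se[ok]
    pval[ok] = np.maximum(2.0 * stats.t.sf(np.abs(tstat), df=n - 2), 1e-300)
    return pd.DataFrame({"beta": beta, "se": se, "pvalue": pval, "eaf": gmean / 2.0})


def _assoc_table(panel: LdPanel, ols: pd.DataFrame, n: int) -> pd.DataFrame:
    info = panel.snp_info
    out = pd.DataFrame(
        {
            "rsid": info["rsid"].to_numpy(),
            "chrom": info["chrom"].to_numpy(),
            "pos": info["pos"].to_numpy(),
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": ols["eaf"].to_numpy(),
            "beta": ols["beta"].to_numpy(),
            "se": ols["se"].to_numpy(),
            "pvalue": ols["pvalue"].to_numpy(),
            "n": n,
        }
    )
    return out[list(GWAS_COLUMNS)]


def gen_summary_stats(
    panel: LdPanel,
    config: SimulationConfig,
    rng=None,
    two_sample: bool = True,
    include_outcome: bool = True,
) -> dict:
    """Simulate exposure and outcome GWAS summary statistics plus the truth.

    The exposure is measured on the panel cohort; the outcome on an
    independent cohort of the same size drawn from the same SNP parameters
    (``two_sample=False`` reuses the panel cohort, giving a one-sample
    design).  Returns ``{"exposure": DataFrame, "outcome": DataFrame,
    "truth": TruthRecord}``.
    """
    rng = as_rng(rng if rng is not None else np.random.default_rng([config.seed, 2]))
    G = panel.dosages.to_numpy(dtype=float)
    n, m = G.shape
    if config.n_causal > m:
        raise ValueError("n_causal exceeds the panel's SNP count")

    causal_idx = np.sort(rng.choice(m, size=config.n_causal, replace=False))
    gamma = np.zeros(m)
    raw = rng.uniform(0.5, 1.5, size=config.n_causal) * rng.choice([-1.0, 1.0], size=config.n_causal)
    gamma[causal_idx] = raw

    h2 = config.heritability_x
    gpart = G @ gamma
    v = float(np.var(gpart))
    if h2 > 0 and v > 0:
        gamma *= np.sqrt(h2 / v)
        gpart = G @ gamma
    elif h2 == 0:
        gamma[:] = 0.0
        gpart = np.zeros(n)
    X = gpart + rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
    realized_h2 = 0.0
    if h2 > 0:
        realized_h2 = float(np.corrcoef(gpart, X)[0, 1] ** 2)

    exposure = _assoc_table(panel, marginal_ols(G, X), n)

    causal = np.zeros(m, dtype=bool)
    causal[causal_idx] = True
    if not include_outcome:
        truth = TruthRecord(
            rsids=list(panel.snp_info["rsid"]),
            gamma=gamma,
            alpha=np.zeros(m),
            causal=causal,
            beta=config.beta_causal,
            seed=config.seed,
            realized_h2=realized_h2,
        )
        return {"exposure": exposure, "outcome": None, "truth": truth}

    alpha = np.zeros(m)
    n_pleio = int(round(config.pleiotropy_fraction * config.n_causal))
    if n_pleio > 0 and config.alpha_scale > 0:
        pleio_idx = rng.choice(causal_idx, size=n_pleio, replace=False)
        alpha[pleio_idx] = rng.normal(0.0, config.alpha_scale, size=n_pleio)

    if two_sample:
        G2 = _resample_genotypes(panel, n, rng).astype(float)
        gpart2 = G2 @ gamma
        X2 = gpart2 + rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
    else:
        G2, X2 = G, X
    Y = config.beta_causal * X2 + G2 @ alpha + rng.standard_normal(n)
    outcome = _assoc_table(panel, marginal_ols(G2, Y), n)
    if two_sample:
        outcome["eaf"] = G2.mean(axis=0) / 2.0

    truth = TruthRecord(
        rsids=list(panel.snp_info["rsid"]),
        gamma=gamma,
        alpha=alpha,
        causal=causal,
        beta=config.beta_causal,
        seed=config.seed,
        realized_h2=realized_h2,
    )
    return {"exposure": exposure, "outcome": outcome, "truth": truth}


# ---------------------------------------------------------------------------
# Catalogue
# ---------------------------------------------------------------------------


def _draw_categorical(rng: np.random.Generator, probs: dict, size: int) -> np.ndarray:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return np.asarray(keys, dtype=object)[rng.choice(len(keys), size=size, p=p)]


def gen_rnam_catalogue(
    snp_list,
    truth: TruthRecord,
    config: SimulationConfig,
    rng=None,
    mod_type_probs: dict | None = None,
) -> pd.DataFrame:
    """Assign RNA-modification flags and draw catalogue annotations.

    Each SNP is flagged with probability ``rnam_base_rate``, multiplied by
    ``rnam_enrichment`` when the SNP is exposure-causal (capped at 1).
    Annotation fields are drawn from the module's default categorical
    distributions (overridable) and recorded in the truth.
    """
    rng = as_rng(rng if rng is not None else np.random.default_rng([config.seed, 3]))
    snp_list = list(snp_list)
    m = len(snp_list)
    causal = np.asarray(truth.causal, dtype=bool)
    if len(causal) != m:
        raise ValueError("truth is not aligned to snp_list")
    p_flag = np.full(m, config.rnam_base_rate)
    p_flag[causal] = min(1.0, config.rnam_base_rate * config.rnam_enrichment)
    flags = rng.random(m) < p_flag
    truth.rnam_flags = flags
    probs = {
        "mod_type": dict(mod_type_probs or DEFAULT_MOD_TYPE_PROBS),
        "confidence": dict(DEFAULT_CONFIDENCE_PROBS),
        "effect": dict(DEFAULT_EFFECT_PROBS),
        "gene_type": dict(DEFAULT_GENE_TYPE_PROBS),
        "region": dict(DEFAULT_REGION_PROBS),
    }
    truth.catalogue_probs = probs
    idx = np.flatnonzero(flags)
    k = len(idx)
    cat = pd.DataFrame(
        {
            "rsid": [snp_list[i] for i in idx],
            "mod_type": _draw_categorical(rng, probs["mod_type"], k),
            "confidence": _draw_categorical(rng, probs["confidence"], k),
            "effect": _draw_categorical(rng, probs["effect"], k),
            "gene": [f"GENE{i // config.snps_per_block + 1}" for i in idx],
            "gene_type": _draw_categorical(rng, probs["gene_type"], k),
            "region": _draw_categorical(rng, probs["region"], k),
        }
    )
    noncoding = cat["gene_type"] == "noncoding"
    cat.loc[noncoding, "region"] = "other"
    bad = [t for t in cat["mod_type"].unique() if t not in MOD_TYPES]
    assert not bad, f"generator produced unknown mod types {bad}"
    return cat


# ---------------------------------------------------------------------------
# QTL tables
# ---------------------------------------------------------------------------


def gen_qtl_stats(
    panel: LdPanel,
    config: SimulationConfig,
    rng=None,
    n_targets: int = 5,
    h2_expression: float = 0.1,
    tissue: str = "synthetic",
) -> pd.DataFrame:
    """Simulate cis-QTL summary statistics for a handful of gene targets.

    Each target gene sits on its own LD block; its expression is driven by
    one causal SNP in the block (explaining ``h2_expression`` of expression
    variance).  The QTL table reports marginal statistics for every SNP in
    the block, with the target TSS at the block start, so cis/trans
    labelling and SMR region selection work on it directly.
    """
    rng = as_rng(rng if rng is not None else np.random.default_rng([config.seed, 4]))
    G = panel.dosages.to_numpy(dtype=float)
    info = panel.snp_info
    n = G.shape[0]
    blocks = rng.choice(config.n_blocks, size=min(n_targets, config.n_blocks), replace=False)
    frames = []
    for b in sorted(blocks):
        cols = np.flatnonzero(info["block"].to_numpy() == b)
        causal_col = int(rng.choice(cols))
        g = G[:, causal_col]
        gs = np.std(g)
        eff = np.sqrt(h2_expression) / gs if gs > 0 else 0.0
        expr = eff * g + rng.normal(0.0, np.sqrt(1.0 - h2_expression), size=n)
        ols = marginal_ols(G[:, cols], expr)
        sub = info.iloc[cols]
        frames.append(
            pd.DataFrame(
                {
                    "rsid": sub["rsid"].to_numpy(),
                    "target_id": f"GENE{b + 1}",
                    "target_chrom": sub["chrom"].iloc[0],
                    "target_tss": int(sub["pos"].min()),
                    "beta": ols["beta"].to_numpy(),
                    "se": ols["se"].to_numpy(),
                    "pvalue": ols["pvalue"].to_numpy(),
                    "tissue_or_study": tissue,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Direct summary-level instrument sampler
# ---------------------------------------------------------------------------


def gen_instrument_stats(
    n_instruments: int,
    beta: float,
    seed,
    n_exposure: int = 50_000,
    n_outcome: int = 50_000,
    h2_x: float = 0.3,
    pleiotropy_fraction: float = 0.0,
    alpha_scale: float = 0.0,
    directional_pleiotropy: float = 0.0,
) -> pd.DataFrame:
    """Sample a harmonized instrument table directly at the summary level.

    For estimator-calibration studies that need thousands of replicates,
    individual-level simulation is unnecessary: under the same structural
    model the estimated SNP effects are (asymptotically) normal around their
    true values with known standard errors.  Each of ``n_instruments``
    independent SNPs gets a true exposure effect gamma_j (equal variance
    shares summing to ``h2_x``, random signs), an estimated exposure effect
    ``N(gamma_j, se_xj)`` and an estimated outcome effect
    ``N(beta * gamma_j + alpha_j + directional_pleiotropy, se_yj)``, with
    SEs from the usual ``1 / (n * 2 maf (1 - maf))`` variance of a marginal
    OLS coefficient on a unit-variance trait.
    """
    rng = as_rng(seed)
    maf = rng.uniform(0.1, 0.5, size=n_instruments)
    var_g = 2.0 * maf * (1.0 - maf)
    gamma = np.sqrt(h2_x / n_instruments / var_g) * rng.choice([-1.0, 1.0], size=n_instruments)
    se_x = np.sqrt((1.0 - h2_x / n_instruments) / (n_exposure * var_g))
    var_y = beta**2 + 1.0
    se_y = np.sqrt(var_y / (n_outcome * var_g))
    alpha = np.zeros(n_instruments)
    n_pleio = int(round(pleiotropy_fraction * n_instruments))
    if n_pleio > 0 and alpha_scale > 0:
        alpha[rng.choice(n_instruments, size=n_pleio, replace=False)] = rng.normal(
            0.0, alpha_scale, size=n_pleio
        )
    bx = rng.normal(gamma, se_x)
    by = rng.normal(beta * gamma + alpha + directional_pleiotropy, se_y)
    p_x = np.maximum(2.0 * stats.norm.sf(np.abs(bx / se_x)), 1e-300)
    return pd.DataFrame(
        {
            "rsid": [f"rs{i + 1}" for i in range(n_instruments)],
            "beta_exposure": bx,
            "se_exposure": se_x,
            "pvalue_exposure": p_x,
            "beta_outcome": by,
            "se_outcome": se_y,
            "true_gamma": gamma,
            "true_alpha": alpha,
        }
    )


def gen_smr_scenario(
    kind: str,
    seed,
    n: int = 20_000,
    m_snps: int = 25,
    rho: float = 0.7,
    h2_expr: float = 0.1,
    b_expr: float = 0.3,
    n_ref: int = 2000,
) -> dict:
    """One-locus scenario for SMR/HEIDI operating-characteristic studies.

    ``kind="pleiotropy"``: a single causal variant (the block's middle SNP)
    drives expression, and the outcome depends on the genotype only through
    expression (effect ``b_expr``) — SMR should fire and HEIDI should not
    reject.  ``kind="linkage"``: expression is driven by the middle SNP but
    the outcome is driven directly by its immediate neighbour (LD r-squared
    roughly 0.4-0.5 at the default rho), with an effect of comparable
    marginal size — SMR often fires spuriously and HEIDI should reject.

    eQTL and GWAS statistics come from two independent cohorts of ``n``
    individuals; the LD reference is a third cohort of ``n_ref``.  Returns
    ``{"gwas", "eqtl", "panel", "causal_snp"}``.
    """
    if kind not in ("pleiotropy", "linkage"):
        raise ValueError("kind must be 'pleiotropy' or 'linkage'")
    rng = as_rng(seed)
    mafs = rng.uniform(0.1, 0.5, m_snps)
    c = m_snps // 2
    g_eqtl = _draw_dosages(mafs, [m_snps], rho, n, rng).astype(float)
    g_gwas = _draw_dosages(mafs, [m_snps], rho, n, rng).astype(float)
    g_ref = _draw_dosages(mafs, [m_snps], rho, n_ref, rng).astype(float)
    eff = np.sqrt(h2_expr) / g_eqtl[:, c].std()
    expr = eff * g_eqtl[:, c] + rng.normal(0.0, np.sqrt(1.0 - h2_expr), n)
    eq = marginal_ols(g_eqtl, expr)
    if kind == "pleiotropy":
        expr_b = eff * g_gwas[:, c] + rng.normal(0.0, np.sqrt(1.0 - h2_expr), n)
        y = b_expr * expr_b + rng.standard_normal(n)
    else:
        y = b_expr * eff * g_gwas[:, c + 1] + rng.standard_normal(n)
    gw = marginal_ols(g_gwas, y)
    rsids = [f"rs{i + 1}" for i in range(m_snps)]
    pos = np.arange(m_snps) * 5000 + 1
    info = pd.DataFrame({"rsid": rsids, "chrom": "1", "pos": pos, "maf": mafs, "block": 0})
    gwas = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": "1",
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": gw["eaf"],
            "beta": gw["beta"],
            "se": gw["se"],
            "pvalue": gw["pvalue"],
            "n": n,
        }
    )[list(GWAS_COLUMNS)]
    eqtl = pd.DataFrame(
        {
            "rsid": rsids,
            "target_id": "GENE1",
            "target_chrom": "1",
            "target_tss": 1,
            "beta": eq["beta"],
            "se": eq["se"],
            "pvalue": eq["pvalue"],
            "tissue_or_study": "synthetic",
        }
    )
    panel = LdPanel.from_dosages(pd.DataFrame(g_ref, columns=rsids), snp_info=info)
    return {"gwas": gwas, "eqtl": eqtl, "panel": panel, "causal_snp": rsids[c]}


def gen_gene_sets(
    config: SimulationConfig,
    truth: TruthRecord,
    rng=None,
    n_random_sets: int = 8,
    set_size: int = 15,
) -> "GeneSetCollection":
    """Gene sets over the synthetic gene universe, with one truth-loaded set.

    ``CAUSAL_PATHWAY`` collects the genes of every block carrying a causal
    SNP; the remaining sets are random draws from the universe, so
    over-representation of causal genes is detectable against them.
    """
    from .io_formats import GeneSetCollection

    rng = as_rng(rng if rng is not None else np.random.default_rng([config.seed, 5]))
    universe = [f"GENE{b + 1}" for b in range(config.n_blocks)]
    causal_blocks = sorted({i // config.snps_per_block for i in np.flatnonzero(truth.causal)})
    sets = {"CAUSAL_PATHWAY": frozenset(f"GENE{b + 1}" for b in causal_blocks)}
    for s in range(n_random_sets):
        picks = rng.choice(config.n_blocks, size=min(set_size, config.n_blocks), replace=False)
        sets[f"RANDOM_SET_{s + 1}"] = frozenset(f"GENE{b + 1}" for b in picks)
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


def simulate_bundle(config: SimulationConfig, out_dir=None) -> dict:
    """Generate the full input bundle for the pipeline.

    Returns a dict with keys ``panel``, ``exposure``, ``outcome``, ``qtl``,
    ``catalogue``, ``truth``; when ``out_dir`` is given also writes
    ``exposure_gwas.tsv``, ``outcome_gwas.tsv``, ``qtl.tsv``,
    ``catalogue.tsv``, ``ld_dosages.tsv`` and ``truth.json`` there.
    """
    panel = gen_ld_panel(config)
    stats_dict = gen_summary_stats(panel, config)
    truth = stats_dict["truth"]
    catalogue = gen_rnam_catalogue(list(panel.snp_info["rsid"]), truth, config)
    qtl = gen_qtl_stats(panel, config)
    gene_sets = gen_gene_sets(config, truth)
    bundle = {
        "panel": panel,
        "exposure": stats_dict["exposure"],
        "outcome": stats_dict["outcome"],
        "qtl": qtl,
        "catalogue": catalogue,
        "gene_sets": gene_sets,
        "truth": truth,
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_results(
            {
                "exposure_gwas": bundle["exposure"],
                "outcome_gwas": bundle["outcome"],
                "qtl": qtl,
                "catalogue": catalogue,
            },
            out_dir,
        )
        write_ld_dosages(panel, os.path.join(out_dir, "ld_dosages.tsv"))
        from .io_formats import write_gmt

        write_gmt(gene_sets, os.path.join(out_dir, "gene_sets.gmt"))
        truth.to_json(os.path.join(out_dir, "truth.json"))
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=1, default=list)
    return bundle
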