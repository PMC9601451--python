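"""Two-sample Mendelian randomization estimators and pleiotropy diagnostics.

Implements, from first principles on summary statistics:

* the per-SNP Wald ratio ``theta_j = beta_Yj / beta_Xj``;
* inverse-variance-weighted (IVW) meta-analysis of the ratios, equivalent to
  weighted zero-intercept regression of outcome on exposure effects with
  weights ``1 / se_Yj**2`` — multiplicative random-effects by default, with
  the SE inflation floored at 1;
* MR-Egger weighted regression with a free intercept (the intercept
  estimates directional pleiotropy) after orienting all instruments to
  positive exposure effects;
* the weighted median estimator with a parametric-bootstrap SE;
* the three-step MR-PRESSO procedure (global RSS test, per-SNP outlier
  test with Bonferroni adjustment, distortion test), with +1-corrected
  empirical p-values (raw fractions are also reported).

Instrument tables are DataFrames with columns ``rsid``, ``beta_exposure``,
``se_exposure``, ``beta_outcome``, ``se_outcome`` (the layout produced by
:func:`rnamsnp.instruments.harmonize`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import as_rng

__all__ = ["MrResult", "PressoResult", "ratio_estimates", "ivw", "mr_egger", "weighted_median", "mr_presso"]


@dataclass
class MrResult:
    method: str
    estimate: float
    se: float
    pvalue: float
    ci95: tuple
    n_snps: int
    q_stat: float = float("nan")
    q_pvalue: float = float("nan")
    egger_intercept: float = float("nan")
    egger_intercept_se: float = float("nan")
    egger_intercept_p: float = float("nan")
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "pvalue": self.pvalue,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "n_snps": self.n_snps,
            "q_stat": self.q_stat,
            "q_pvalue": self.q_pvalue,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
        }


@dataclass
class PressoResult:
    global_rss_observed: float
    global_p: float
    global_p_raw: float
    n_sim: int
    outlier_pvalues: pd.DataFrame  # per-SNP raw and Bonferroni-adjusted empirical p
    outliers: list
    estimate_all: MrResult
    estimate_outlier_corrected: MrResult | None
    distortion_coefficient: float
    distortion_p: float
    seed: object
    all_outliers: bool = False


def _extract(instruments: pd.DataFrame):
    bx = instruments["beta_exposure"].to_numpy(dtype=float)
    sx = instruments["se_exposure"].to_numpy(dtype=float)
    by = instruments["beta_outcome"].to_numpy(dtype=float)
    sy = instruments["se_outcome"].to_numpy(dtype=float)
    rsid = instruments["rsid"].astype(str).to_numpy() if "rsid" in instruments else np.array(
        [f"snp{i}" for i in range(len(bx))]
    )
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("all standard errors must be positive")
    zero = rsid[bx == 0.0]
    if len(zero):
        raise ValueError(f"zero exposure effect for instrument(s): {', '.join(zero)}")
    return rsid, bx, sx, by, sy


def ratio_estimates(instruments: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP Wald ratios with first-order SEs: theta = bY/bX, se = seY/|bX|."""
    rsid, bx, _sx, by, sy = _extract(instruments)
    theta = by / bx
    se = sy / np.abs(bx)
    return pd.DataFrame({"rsid": rsid, "theta": theta, "se_theta": se, "weight": 1.0 / se**2})


def _ci(est: float, se: float) -> tuple:
    return (est - 1.96 * se, est + 1.96 * se)


def ivw(instruments: pd.DataFrame, model: str = "random") -> MrResult:
    """Inverse-variance-weighted estimate of the causal effect.

    ``estimate = sum(w theta) / sum(w)`` with ``theta_j = bY_j/bX_j`` and
    ``w_j = bX_j**2 / seY_j**2``.  Fixed-effect SE is ``sum(w)**-0.5``;
    the multiplicative random-effects model (default) inflates it by
    ``max(1, sqrt(Q/(n-1)))`` and refers the estimate to a t distribution
    with n-1 df.  A single instrument degenerates to the Wald ratio with a
    normal reference and undefined Q.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    _rsid, bx, _sx, by, sy = _extract(instruments)
    n = len(bx)
    if n < 1:
        raise ValueError("at least one instrument required")
    theta = by / bx
    if n == 1:
        est = float(theta[0])
        se = float(sy[0] / abs(bx[0]))
        p = 2.0 * stats.norm.sf(abs(est / se))
        return MrResult("ivw", est, se, float(p), _ci(est, se), 1)
    w = bx**2 / sy**2
    est = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - est) ** 2))
    q_p = float(stats.chi2.sf(q, df=n - 1))
    se_fixed = float(np.sum(w) ** -0.5)
    if model == "fixed":
        se = se_fixed
        p = 2.0 * stats.norm.sf(abs(est / se))
    else:
        se = se_fixed * max(1.0, np.sqrt(q / (n - 1)))
        p = 2.0 * stats.t.sf(abs(est / se), df=n - 1)
    return MrResult(f"ivw_{model}", est, se, float(p), _ci(est, se), n, q_stat=q, q_pvalue=q_p)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares via normal equations; returns (coef, cov_unit, dof_resid_ss).

    cov_unit is (X' W X)^-1; the residual weighted SS is returned for the
    dispersion estimate.
    """
    W = w[:, None]
    xtwx = X.T @ (W * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    rss = float(np.sum(w * resid**2))
    cov_unit = np.linalg.inv(xtwx)
    return coef, cov_unit, rss


def mr_egger(instruments: pd.DataFrame) -> MrResult:
    """MR-Egger regression: weighted fit of bY on bX with a free intercept.

    Instruments are oriented so every exposure effect is positive (both
    betas negated where needed).  Weights are ``1/seY**2``; SEs are
    inflated by ``max(1, sqrt(Q/(n-2)))`` and referred to a t distribution
    with n-2 df.  The intercept estimates directional pleiotropy.
    """
    _rsid, bx, _sx, by, sy = _extract(instruments)
    n = len(bx)
    if n < 3:
        raise ValueError(f"MR-Egger requires at least 3 instruments, got {n}")
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), bx])
    coef, cov_unit, rss = _wls(X, by, w)
    infl = max(1.0, np.sqrt(rss / (n - 2)))
    ses = np.sqrt(np.diag(cov_unit)) * infl
    slope, slope_se = float(coef[1]), float(ses[1])
    icept, icept_se = float(coef[0]), float(ses[0])
    p_slope = 2.0 * stats.t.sf(abs(slope / slope_se), df=n - 2)
    p_icept = 2.0 * stats.t.sf(abs(icept / icept_se), df=n - 2)
    q_p = float(stats.chi2.sf(rss, df=n - 2))
    return MrResult(
        "mr_egger",
        slope,
        slope_se,
        float(p_slope),
        _ci(slope, slope_se),
        n,
        q_stat=rss,
        q_pvalue=q_p,
        egger_intercept=icept,
        egger_intercept_se=icept_se,
        egger_intercept_p=float(p_icept),
    )


def _egger_zero_intercept(instruments: pd.DataFrame) -> MrResult:
    """Egger with the intercept constrained to zero; reproduces IVW exactly.

    Test hook: weighted zero-intercept regression with weights 1/seY**2 is
    algebraically the IVW weighted average.
    """
    _rsid, bx, _sx, by, sy = _extract(instruments)
    n = len(bx)
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = bx[:, None]
    coef, cov_unit, rss = _wls(X, by, w)
    infl = max(1.0, np.sqrt(rss / (n - 1))) if n > 1 else 1.0
    se = float(np.sqrt(cov_unit[0, 0]) * infl)
    est = float(coef[0])
    p = 2.0 * stats.t.sf(abs(est / se), df=max(n - 1, 1))
    return MrResult("egger_zero_intercept", est, se, float(p), _ci(est, se), n, q_stat=rss)


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    ww = w[order]
    s = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
    return float(np.interp(0.5, s, th))


def _ratio_se(bx, sx, by, sy, second_order: bool):
    if second_order:
        return np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return sy / np.abs(bx)


def weighted_median(
    instruments: pd.DataFrame, n_boot: int = 1000, seed=None, second_order: bool = False
) -> MrResult:
    """Weighted median of the per-SNP ratios.

    Ratios are ordered and the estimate interpolates theta at standardized
    cumulative weight 0.5, with inverse-variance weights from the
    first-order ratio SE ``seY/|bX|`` (``second_order=True`` adds the
    exposure-error term of the delta method).  The SE is the standard
    deviation of the estimator over ``n_boot`` parametric-bootstrap draws
    in which each ``bX_j``/``bY_j`` is perturbed by its own SE.  Consistent
    when at least half the total weight comes from valid instruments.
    """
    _rsid, bx, sx, by, sy = _extract(instruments)
    n = len(bx)
    if n < 3:
        raise ValueError(f"weighted median requires at least 3 instruments, got {n}")
    rng = as_rng(seed)
    theta = by / bx
    w = 1.0 / _ratio_se(bx, sx, by, sy, second_order) ** 2
    est = _weighted_median_point(theta, w)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(n)
        bys = by + sy * rng.standard_normal(n)
        bxs[bxs == 0.0] = 1e-12
        draws[b] = _weighted_median_point(
            bys / bxs, 1.0 / _ratio_se(bxs, sx, bys, sy, second_order) ** 2
        )
    se = float(np.std(draws, ddof=1))
    p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else float(est == 0.0)
    return MrResult(
        "weighted_median", est, se, float(p), _ci(est, se), n, extras={"n_boot": n_boot}
    )


def _loo_ivw_slopes(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slope for each SNP (vectorized)."""
    w = bx**2 / sy**2
    theta = by / bx
    sw = np.sum(w)
    swt = np.sum(w * theta)
    return (swt - w * theta) / (sw - w)


def _loo_ivw_slopes_matrix(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Row-wise leave-one-out IVW slopes for a (n_sim, n) matrix of draws."""
    w = bx**2 / sy**2
    wt = w * (by / bx)
    sw = w.sum(axis=1, keepdims=True)
    swt = wt.sum(axis=1, keepdims=True)
    return (swt - wt) / (sw - w)


def mr_presso(
    instruments: pd.DataFrame,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed=None,
) -> PressoResult:
    """MR-PRESSO: global heterogeneity, per-SNP outlier and distortion tests.

    Global: the observed residual sum of squares
    ``RSS = sum_j (bY_j - b_loo_j * bX_j)**2`` (b_loo_j the leave-one-out
    IVW slope) is compared against ``n_sim`` parametric replicates drawn
    under no horizontal pleiotropy (``bX* ~ N(bX, seX)``,
    ``bY*_j ~ N(b_loo_j bX_j, seY_j)``).  Outlier: each SNP's observed
    squared residual against its simulated distribution, Bonferroni-scaled
    by n.  Distortion: percent change of the IVW estimate after removing
    the flagged outliers, compared against removals of random same-size
    subsets.
    """
    rsid, bx, sx, by, sy = _extract(instruments)
    n = len(bx)
    if n < 4:
        raise ValueError(f"MR-PRESSO requires at least 4 instruments, got {n}")
    rng = as_rng(seed)

    b_loo = _loo_ivw_slopes(bx, by, sy)
    resid2_obs = (by - b_loo * bx) ** 2
    rss_obs = float(np.sum(resid2_obs))

    bx_sim = bx + sx * rng.standard_normal((n_sim, n))
    by_sim = b_loo * bx + sy * rng.standard_normal((n_sim, n))
    bx_sim[bx_sim == 0.0] = 1e-12
    b_loo_sim = _loo_ivw_slopes_matrix(bx_sim, by_sim, np.broadcast_to(sy, (n_sim, n)))
    resid2_sim = (by_sim - b_loo_sim * bx_sim) ** 2
    rss_sim = resid2_sim.sum(axis=1)

    n_ge = int(np.sum(rss_sim >= rss_obs))
    global_p = (1 + n_ge) / (1 + n_sim)
    global_p_raw = n_ge / n_sim

    n_ge_snp = (resid2_sim >= resid2_obs).sum(axis=0)
    p_out = (1 + n_ge_snp) / (1 + n_sim)
    p_adj = np.minimum(1.0, p_out * n)
    outlier_pvalues = pd.DataFrame(
        {
            "outlier_p_raw": n_ge_snp / n_sim,
            "outlier_p_bonferroni": p_adj,
        },
        index=rsid,
    )
    outliers = list(np.asarray(rsid)[p_adj < outlier_alpha])

    est_all = ivw(instruments)
    if not outliers:
        return PressoResult(
            global_rss_observed=rss_obs,
            global_p=global_p,
            global_p_raw=global_p_raw,
            n_sim=n_sim,
            outlier_pvalues=outlier_pvalues,
            outliers=[],
            estimate_all=est_all,
            estimate_outlier_corrected=est_all,
            distortion_coefficient=0.0,
            distortion_p=float("nan"),
            seed=seed,
        )
    keep = ~np.isin(rsid, outliers)
    if not keep.any():
        return PressoResult(
            global_rss_observed=rss_obs,
            global_p=global_p,
            global_p_raw=global_p_raw,
            n_sim=n_sim,
            outlier_pvalues=outlier_pvalues,
            outliers=outliers,
            estimate_all=est_all,
            estimate_outlier_corrected=None,
            distortion_coefficient=float("nan"),
            distortion_p=float("nan"),
            seed=seed,
            all_outliers=True,
        )
    est_corr = ivw(instruments[np.asarray(keep)])
    distortion = 100.0 * (est_all.estimate - est_corr.estimate) / abs(est_corr.estimate)

    k = len(outliers)
    dist_rand = np.empty(n_sim)
    w_all = bx**2 / sy**2
    theta_all = by / bx
    for s in range(n_sim):
        drop = rng.choice(n, size=k, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[drop] = False
        b_sub = float(np.sum(w_all[mask] * theta_all[mask]) / np.sum(w_all[mask]))
        dist_rand[s] = 100.0 * (est_all.estimate - b_sub) / abs(b_sub)
    distortion_p = float(np.mean(np.abs(dist_rand) >= abs(distortion)))

    return PressoResult(
        global_rss_observed=rss_obs,
        global_p=global_p,
        global_p_raw=global_p_raw,
        n_sim=n_sim,
        outlier_pvalues=outlier_pvalues,
        outliers=outliers,
        estimate_all=est_all,
        estimate_outlier_corrected=est_corr,
        distortion_coefficient=float(distortion),
        distortion_p=distortion_p,
        seed=seed,
    )


def run_all_methods(instruments: pd.DataFrame, n_boot: int = 1000, n_sim: int = 1000, seed=None) -> pd.DataFrame:
    """Convenience: IVW, weighted median, Egger and PRESSO on one table."""
    rng = as_rng(seed)
    rows = [ivw(instruments).as_row()]
    n = len(instruments)
    if n >= 3:
        rows.append(weighted_median(instruments, n_boot=n_boot, seed=rng).as_row())
        rows.append(mr_egger(instruments).as_row())
    if n >= 4:
        presso = mr_presso(instruments, n_sim=n_sim, seed=rng)
        row = presso.estimate_all.as_row()
        row.update(
            method="mr_presso_raw",
            estimate=presso.estimate_all.estimate,
        )
        rows.append(row)
        if presso.estimate_outlier_corrected is not None:
            row2 = presso.estimate_outlier_corrected.as_row()
            row2.update(method="mr_presso_outlier_corrected")
            rows.append(row2)
        rows[-1]["q_stat"] = presso.global_rss_observed
        rows[-1]["q_pvalue"] = presso.global_p
    return pd.DataFrame(rows)
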