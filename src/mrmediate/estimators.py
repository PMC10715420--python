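"""Univariable MR estimators and diagnostics.

All estimators consume a single-exposure :class:`~mrmediate.gwas_io.HarmonizedSet`
with per-SNP exposure effects gamma_j (SE sigma_gamma_j) and outcome
effects Gamma_j (SE sigma_Gamma_j), and return causal-effect estimates on
the outcome scale (log-odds for a binary outcome).

Implemented methods:

* Wald ratio — the per-SNP estimate Gamma_j / gamma_j.
* IVW — inverse-variance-weighted combination, equivalent to weighted
  regression of Gamma on gamma through the origin; the random-effects
  flavour inflates the SE multiplicatively by sqrt(Q/(J-1)), floored at 1.
* MR-Egger — the same weighted regression with a free intercept; the
  intercept estimates average directional pleiotropy (valid under the
  InSIDE assumption), with t(J-2) inference and multiplicative
  overdispersion.
* Weighted median — consistent when under half of the weight comes from
  invalid instruments; SE by parametric bootstrap.
* Cochran's Q — heterogeneity of the per-SNP ratios about the IVW fit.
* MR-PRESSO — simulation-based residual-sum-of-squares global test for
  horizontal pleiotropy, per-SNP outlier detection, an outlier-corrected
  IVW estimate and a distortion test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError
from .gwas_io import HarmonizedSet

log = logging.getLogger(__name__)


@dataclass
class MREstimate:
    """A causal-effect estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int

    def odds_ratio(self, level: float = 0.95) -> tuple[float, float, float]:
        return summarize_or(self, level)


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


@dataclass
class QResult:
    Q: float
    df: int
    pvalue: float


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_ids: list
    outlier_p: list
    distortion_p: float | None
    corrected: MREstimate | None
    n_sim: int
    seed: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _extract(h: HarmonizedSet, min_snp: int, method: str):
    """Pull effect arrays in canonical (variant_id-sorted) order.

    Rows with gamma = 0 have an undefined Wald ratio and are excluded
    with a logged count.
    """
    hs = h.sorted_by_variant()
    g = hs.gamma
    sg = hs.sigma_gamma
    G = hs.Gamma
    sG = hs.sigma_Gamma
    vids = np.asarray(hs.variant_ids)
    nz = g != 0
    n_zero = int((~nz).sum())
    if n_zero:
        log.info("%s: excluded %d SNP(s) with zero exposure effect", method, n_zero)
        g, sg, G, sG, vids = g[nz], sg[nz], G[nz], sG[nz], vids[nz]
    if g.shape[0] < min_snp:
        raise DataError(
            f"{method} requires at least {min_snp} SNPs; got {g.shape[0]}"
        )
    return g, sg, G, sG, vids


def _norm_p(z: np.ndarray | float) -> np.ndarray | float:
    return 2.0 * sps.norm.sf(np.abs(z))


def _ivw_arrays(g, G, sG) -> tuple[float, float]:
    """Fixed-effect IVW slope and SE from raw arrays."""
    w = 1.0 / sG**2
    den = float(np.sum(w * g * g))
    beta = float(np.sum(w * g * G)) / den
    se = den**-0.5
    return beta, se


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(
    gamma: float, sigma_gamma: float, Gamma: float, sigma_Gamma: float
) -> MREstimate:
    """Single-SNP causal estimate Gamma/gamma with first-order SE."""
    if gamma == 0:
        raise DataError("Wald ratio undefined for gamma = 0")
    beta = Gamma / gamma
    se = sigma_Gamma / abs(gamma)
    return MREstimate("wald", float(beta), float(se), float(_norm_p(beta / se)), 1)


def ivw(h: HarmonizedSet, model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``model="random"`` is the multiplicative random-effects flavour: the
    fixed-effect SE is scaled by max(1, sqrt(Q/(J-1))).
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    min_snp = 1 if model == "fixed" else 2
    g, sg, G, sG, _ = _extract(h, min_snp, f"ivw_{model}")
    beta, se = _ivw_arrays(g, G, sG)
    method = "ivw_fe"
    if model == "random":
        J = g.shape[0]
        v = (g / sG) ** 2
        Q = float(np.sum(v * (G / g - beta) ** 2))
        se *= max(1.0, np.sqrt(Q / (J - 1)))
        method = "ivw_re"
    return MREstimate(method, beta, se, float(_norm_p(beta / se)), g.shape[0])


def mr_egger(h: HarmonizedSet, intercept: bool = True) -> EggerResult:
    """MR-Egger weighted regression of Gamma on gamma with intercept.

    SNPs are first oriented so gamma_j >= 0 (negating both effects where
    needed); weights are 1/sigma_Gamma^2; SEs carry a multiplicative
    overdispersion factor floored at 1, and p-values use t with J-2 df.
    ``intercept=False`` is a diagnostic mode that reduces to IVW.
    """
    g, sg, G, sG, _ = _extract(h, 3, "mr_egger")
    flip = np.sign(g)
    flip[flip == 0] = 1.0
    g = g * flip
    G = G * flip
    if np.allclose(g, g[0]):
        raise DataError("MR-Egger unidentifiable: all |gamma| equal (collinear)")
    w = 1.0 / sG**2
    J = g.shape[0]
    if intercept:
        X = np.column_stack([np.ones(J), g])
    else:
        X = g[:, None]
    XtW = X.T * w
    xtwx = XtW @ X
    coef = np.linalg.solve(xtwx, XtW @ G)
    resid = G - X @ coef
    dof = J - X.shape[1]
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, rss_w / dof) if dof > 0 else 1.0
    cov = phi * np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov))
    tvals = coef / ses
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
    if intercept:
        slope = MREstimate("egger", float(coef[1]), float(ses[1]), float(pvals[1]), J)
        return EggerResult(slope, float(coef[0]), float(ses[0]), float(pvals[0]))
    slope = MREstimate("egger", float(coef[0]), float(ses[0]), float(pvals[0]), J)
    return EggerResult(slope, 0.0, float("nan"), float("nan"))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP ratios are ordered ascending; with normalized weights
    w_j = gamma_j^2/sigma_Gamma_j^2 the estimate interpolates the ratio at
    cumulative midpoint 0.5. The SE is the SD of the estimate over
    ``n_boot`` parametric resamples of (gamma, Gamma).
    """
    g, sg, G, sG, _ = _extract(h, 3, "weighted_median")

    def _wm(gv, Gv, sGv):
        ratios = Gv / gv
        w = gv**2 / sGv**2
        w = w / w.sum()
        order = np.argsort(ratios, kind="mergesort")
        r = ratios[order]
        ww = w[order]
        s = np.cumsum(ww) - ww / 2.0
        return float(np.interp(0.5, s, r))

    est = _wm(g, G, sG)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        gb = rng.normal(g, sg)
        Gb = rng.normal(G, sG)
        gb[gb == 0] = np.finfo(float).tiny
        boots[b] = _wm(gb, Gb, sG)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny
    return MREstimate(
        "weighted_median", est, se, float(_norm_p(est / se)), g.shape[0]
    )


def cochran_q(h: HarmonizedSet) -> QResult:
    """Cochran's Q heterogeneity test of per-SNP ratios about the IVW fit."""
    g, sg, G, sG, _ = _extract(h, 2, "cochran_q")
    beta, _ = _ivw_arrays(g, G, sG)
    v = (g / sG) ** 2
    Q = float(np.sum(v * (G / g - beta) ** 2))
    df = g.shape[0] - 1
    p = float(sps.chi2.sf(Q, df))
    return QResult(Q, df, p)


def leave_one_out(h: HarmonizedSet):
    """IVW fixed-effect estimate omitting each SNP in turn.

    Returns a list of (omitted variant_id, MREstimate).
    """
    g, sg, G, sG, vids = _extract(h, 2, "leave_one_out")
    betas, ses = _loo_slopes(g, G, sG)
    out = []
    for j in range(g.shape[0]):
        b, s = float(betas[j]), float(ses[j])
        out.append(
            (str(vids[j]), MREstimate("ivw_fe", b, s, float(_norm_p(b / s)), g.shape[0] - 1))
        )
    return out


def _loo_slopes(g, G, sG):
    """Vectorized leave-one-out IVW slopes and SEs."""
    w = 1.0 / sG**2
    num = w * g * G
    den = w * g * g
    S_num = num.sum()
    S_den = den.sum()
    betas = (S_num - num) / (S_den - den)
    ses = (S_den - den) ** -0.5
    return betas, ses


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global pleiotropy test, outlier search, distortion test.

    The observed statistic is the weighted residual sum of squares of each
    Gamma_j about its leave-one-out IVW prediction gamma_j * beta_(-j).
    Its null distribution is simulated by drawing gamma*_j ~ N(gamma_j,
    sigma_gamma_j^2) and Gamma*_j ~ N(gamma_j beta_(-j), sigma_Gamma_j^2)
    and recomputing the statistic (with leave-one-out slopes re-estimated
    on the simulated data). Per-SNP outliers are flagged when the
    empirical tail probability of the j-th residual contribution falls
    below ``outlier_alpha`` after Bonferroni correction across SNPs. When
    outliers are found, the corrected estimate is IVW on the outlier-free
    set and the distortion p-value compares the observed change in the
    estimate against removals of randomly chosen pseudo-outliers.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    g, sg, G, sG, vids = _extract(h, 4, "mr_presso")
    J = g.shape[0]
    w = 1.0 / sG**2

    loo, _ = _loo_slopes(g, G, sG)
    res_obs = w * (G - g * loo) ** 2
    rss_obs = float(res_obs.sum())

    rng = np.random.default_rng(seed)
    g_star = rng.normal(g, sg, size=(n_sim, J))
    G_star = rng.normal(g * loo, sG, size=(n_sim, J))
    num = w * g_star * G_star
    den = w * g_star * g_star
    loo_star = (num.sum(axis=1, keepdims=True) - num) / (
        den.sum(axis=1, keepdims=True) - den
    )
    res_star = w * (G_star - g_star * loo_star) ** 2
    rss_star = res_star.sum(axis=1)
    global_p = float(np.mean(rss_star >= rss_obs))

    outlier_p = np.mean(res_star >= res_obs[None, :], axis=0)
    is_out = outlier_p < outlier_alpha / J
    outlier_ids = [str(v) for v in vids[is_out]]

    corrected = None
    distortion_p = None
    if outlier_ids:
        keep = ~is_out
        if keep.sum() < 2:
            raise DataError("too few SNPs remain after outlier removal")
        b_all, _ = _ivw_arrays(g, G, sG)
        b_cor, se_cor = _ivw_arrays(g[keep], G[keep], sG[keep])
        corrected = MREstimate(
            "ivw_fe",
            b_cor,
            se_cor,
            float(_norm_p(b_cor / se_cor)),
            int(keep.sum()),
        )
        d_obs = b_cor - b_all
        n_out = int(is_out.sum())
        keep_idx = np.flatnonzero(keep)
        d_sim = np.empty(n_sim)
        for b in range(n_sim):
            pseudo = rng.choice(keep_idx, size=min(n_out, len(keep_idx) - 2), replace=False)
            mask = np.ones(J, bool)
            mask[pseudo] = False
            bb, _ = _ivw_arrays(g[mask], G[mask], sG[mask])
            d_sim[b] = bb - b_all
        distortion_p = float(np.mean(np.abs(d_sim) >= abs(d_obs)))

    return PressoResult(
        rss_obs,
        global_p,
        outlier_ids,
        [float(p) for p in outlier_p],
        distortion_p,
        corrected,
        int(n_sim),
        int(seed),
    )


def summarize_or(est: MREstimate, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio and confidence interval from a log-odds estimate."""
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0, 1); got {level}")
    z = sps.norm.ppf((1.0 + level) / 2.0)
    lo = np.exp(est.beta - z * est.se)
    hi = np.exp(est.beta + z * est.se)
    return float(np.exp(est.beta)), float(lo), float(hi)


def se_from_or_p(odds_ratio: float, pvalue: float) -> float:
    """Recover the Wald SE implied by a printed (OR, p) pair.

    Inverts p = 2*Phi(-|log OR| / se).
    """
    z = sps.norm.isf(pvalue / 2.0)
    return abs(np.log(odds_ratio)) / z
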