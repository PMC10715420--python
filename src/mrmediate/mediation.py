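"""Multivariable MR, mediation decomposition, routing and multiplicity.

Two-step (network) MR decomposes the total effect of an exposure on the
outcome into a direct part and a part running through a mediator:

* total      — univariable MR of exposure on outcome,
* direct     — the exposure's coefficient in multivariable MR (MVMR)
               adjusting for the mediator,
* indirect   — total - direct (difference method),
* proportion — indirect / total,

with the product step1 x step2 (exposure->mediator times
mediator->outcome) emitted as a cross-check. The module also implements
per-taxonomic-level Bonferroni correction and the sensitivity-based
routing of the primary estimate (Egger when the Egger intercept signals
directional pleiotropy, random-effects IVW under heterogeneity,
fixed-effect IVW otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError
from .estimators import EggerResult, MREstimate, PressoResult, QResult
from .gwas_io import HarmonizedSet


@dataclass
class MVMRResult:
    """Direct effects of several exposures estimated jointly."""

    exposure_names: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvalues: np.ndarray
    n_snp: int
    conditional_F: np.ndarray | None = None

    def estimate_for(self, exposure: str) -> MREstimate:
        k = self.exposure_names.index(exposure)
        return MREstimate(
            "mvmr_ivw",
            float(self.betas[k]),
            float(self.ses[k]),
            float(self.pvalues[k]),
            self.n_snp,
        )


@dataclass
class MediationResult:
    """Difference-method decomposition for one exposure-mediator-outcome triple.

    ``proportion`` is reported verbatim (possibly outside [0, 1]);
    ``sign_consistent`` is False for inconsistent mediation, where direct
    and indirect effects oppose each other.
    """

    exposure: str
    mediator: str
    outcome: str
    total: MREstimate
    direct: MREstimate
    indirect: float
    proportion: float
    step1: MREstimate | None
    step2: MREstimate | None
    product_indirect: float | None
    sign_consistent: bool


def mvmr_ivw(h: HarmonizedSet) -> MVMRResult:
    """Multivariable IVW: weighted regression of Gamma on all exposure effects.

    No intercept; weights 1/sigma_Gamma^2; SEs from the weighted normal
    equations with a multiplicative overdispersion factor floored at 1;
    two-sided normal p-values.
    """
    if len(h.exposure_names) < 2:
        raise DataError("MVMR requires at least two exposures")
    hs = h.sorted_by_variant()
    X = hs.gamma_matrix()
    G = hs.Gamma
    sG = hs.sigma_Gamma
    J, K = X.shape
    if J < K + 1:
        raise DataError(f"MVMR needs n_snp >= exposures + 1 (J={J}, K={K})")
    w = 1.0 / sG**2
    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(Xw) < K:
        raise DataError(
            "collinear exposure effects in MVMR design: " + ", ".join(h.exposure_names)
        )
    XtW = X.T * w
    xtwx = XtW @ X
    betas = np.linalg.solve(xtwx, XtW @ G)
    resid = G - X @ betas
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, rss_w / (J - K))
    cov = phi * np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov))
    pvals = 2.0 * sps.norm.sf(np.abs(betas / ses))
    return MVMRResult(list(h.exposure_names), betas, ses, pvals, J)


def decompose_mediation(
    total: MREstimate,
    direct: MREstimate,
    step1: MREstimate | None = None,
    step2: MREstimate | None = None,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Difference-method decomposition: indirect = total - direct.

    ``proportion = indirect / total`` on the log-odds scale;
    ``product_indirect = step1.beta * step2.beta`` is the two-step
    cross-check when both path estimates are supplied.
    """
    if total.beta == 0:
        raise DataError("proportion mediated undefined: total effect is zero")
    indirect = total.beta - direct.beta
    proportion = indirect / total.beta
    product = step1.beta * step2.beta if step1 is not None and step2 is not None else None
    sign_consistent = 0.0 <= proportion <= 1.0
    return MediationResult(
        exposure,
        mediator,
        outcome,
        total,
        direct,
        float(indirect),
        float(proportion),
        step1,
        step2,
        None if product is None else float(product),
        bool(sign_consistent),
    )


def bonferroni_by_level(
    results: pd.DataFrame, level_counts: dict[str, int]
) -> pd.DataFrame:
    """Bonferroni-correct p-values within each taxonomic level.

    ``results`` needs columns ``taxonomic_level`` and ``pvalue``;
    ``level_counts`` maps each level to the number of taxa tested at that
    level (m). Adds ``m_level``, ``p_bonferroni`` (= min(1, p*m)) and
    ``significant_bonferroni`` at 0.05.
    """
    missing = set(results["taxonomic_level"]) - set(level_counts)
    if missing:
        raise ConfigError(f"no Bonferroni m for level(s): {sorted(missing)}")
    out = results.copy()
    out["m_level"] = out["taxonomic_level"].map(level_counts).astype(int)
    out["p_bonferroni"] = np.minimum(1.0, out["pvalue"] * out["m_level"])
    out["significant_bonferroni"] = out["p_bonferroni"] < 0.05
    return out


def route_primary(
    ivw_fe: MREstimate,
    ivw_re: MREstimate | None,
    egger: EggerResult | None,
    q: QResult | None,
    presso: PressoResult | None = None,
    alpha: float = 0.05,
) -> tuple[str, MREstimate, dict]:
    """Choose the primary estimate from the sensitivity diagnostics.

    Significant Egger intercept (directional pleiotropy) -> Egger slope;
    otherwise significant Cochran's Q (heterogeneity) -> random-effects
    IVW; otherwise fixed-effect IVW. Decision flags are returned for the
    audit trail.
    """
    pleiotropy = egger is not None and egger.intercept_p < alpha
    heterogeneity = q is not None and q.pvalue < alpha
    presso_pleiotropy = presso is not None and presso.global_p < alpha
    flags = {
        "pleiotropy": bool(pleiotropy),
        "heterogeneity": bool(heterogeneity),
        "presso_pleiotropy": bool(presso_pleiotropy),
    }
    if pleiotropy:
        return "egger", egger.slope, flags
    if heterogeneity and ivw_re is not None:
        return "ivw_re", ivw_re, flags
    return "ivw_fe", ivw_fe, flags


def screen_mediators(
    exposure_results: pd.DataFrame,
    mediator_outcome_results: pd.DataFrame,
    exposure_mediator_results: pd.DataFrame,
    alpha: float = 0.05,
) -> list[tuple[str, str]]:
    """Select (exposure, mediator) triples for mediation decomposition.

    A triple survives when all three paths are nominally significant:
    exposure->outcome (``exposure_results``: columns exposure, pvalue),
    mediator->outcome (``mediator_outcome_results``: mediator, pvalue),
    exposure->mediator (``exposure_mediator_results``: exposure,
    mediator, pvalue).
    """
    sig_exp = set(
        exposure_results.loc[exposure_results["pvalue"] < alpha, "exposure"]
    )
    sig_med = set(
        mediator_outcome_results.loc[
            mediator_outcome_results["pvalue"] < alpha, "mediator"
        ]
    )
    out: list[tuple[str, str]] = []
    for row in exposure_mediator_results.itertuples(index=False):
        if (
            row.exposure in sig_exp
            and row.mediator in sig_med
            and row.pvalue < alpha
        ):
            out.append((row.exposure, row.mediator))
    return out
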