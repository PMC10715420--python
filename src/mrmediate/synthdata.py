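"""Synthetic GWAS summary statistics for an exposure -> mediator -> outcome chain.

The generator emulates the structure of the study data a microbiome MR
analysis consumes — a microbiota-abundance exposure GWAS (default
N = 18,340, the MiBioGen panel size), an immune-cell-trait mediator GWAS
(default N = 3,757) and a binary-disease outcome GWAS on the log-odds
scale (default N = 365,946, the FinnGen GPA case+control total) — over
one shared variant panel.

Generative model per SNP j:

* eaf_j ~ Uniform(eaf_range), true instrument effect
  gamma_j ~ Normal(0, gamma_sd^2) for the exposure's own instruments,
* mediator effect m_j = alpha_em * gamma_j, plus the mediator's own
  instruments on disjoint SNPs with zero exposure effect,
* outcome effect Gamma_j = theta_direct * gamma_j + theta_m * m_j + pi_j,
  where pi_j is a horizontal-pleiotropy offset carried by an invalid
  fraction of the exposure instruments,
* per-trait SE s_j = 1/sqrt(2 N eaf_j (1 - eaf_j)); observed effects are
  truth plus independent Normal(0, s_j^2) sampling noise.

Directional pleiotropy is applied in the orientation of each SNP's true
exposure effect (sign(gamma_j) * Normal(mean, sd)), so its mean does not
cancel across SNPs of opposite sign; this is the frame in which the
InSIDE assumption (offsets independent of instrument strength) holds and
in which MR-Egger's intercept is interpretable.

Truth identities: total = theta_direct + alpha_em * theta_m;
proportion mediated = alpha_em * theta_m / total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gwas_io import HarmonizedSet, SummaryStatsTable
from .instruments import LDMatrix

#: Non-palindromic allele pairs cycled over the variant panel.
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic chain study.

    Defaults mirror the real data sources' scale: many weak-to-moderate
    instruments, sample-size-driven SEs, a binary outcome on the log-odds
    scale.
    """

    n_snp: int = 100
    n_exposure: int = 18_340
    n_mediator: int = 3_757
    n_outcome: int = 365_946
    theta_direct: float = 0.35
    alpha_em: float = 0.3
    theta_m: float = 0.5
    gamma_sd: float = 0.05
    eaf_range: tuple[float, float] = (0.05, 0.5)
    pleiotropy: str = "none"  # "none" | "balanced" | "directional"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    frac_invalid: float = 0.0
    mediator_own_instruments: int = 20
    ld_block_size: int = 0  # 0 -> no LD matrix emitted
    ld_rho: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snp < 1:
            raise ConfigError("n_snp must be positive")
        if min(self.n_exposure, self.n_mediator, self.n_outcome) <= 0:
            raise ConfigError("sample sizes must be positive")
        if not 0.0 <= self.frac_invalid <= 1.0:
            raise ConfigError("frac_invalid must lie in [0, 1]")
        lo, hi = self.eaf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("eaf_range must be within (0, 0.5]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if self.ld_rho < 0 or self.ld_rho >= 1:
            raise ConfigError("ld_rho must lie in [0, 1)")


@dataclass
class TruthSet:
    """The simulator's generating truth, for recovery tests."""

    config: SimulationConfig
    total_true: float
    direct_true: float
    indirect_true: float
    proportion_true: float
    gamma_true: np.ndarray = field(repr=False, default=None)
    m_true: np.ndarray = field(repr=False, default=None)
    Gamma_true: np.ndarray = field(repr=False, default=None)
    pleiotropy_offsets: np.ndarray = field(repr=False, default=None)
    exposure_instrument_ids: list = field(default_factory=list)
    mediator_instrument_ids: list = field(default_factory=list)

    def to_flat(self) -> dict:
        return {
            "total_true": self.total_true,
            "direct_true": self.direct_true,
            "indirect_true": self.indirect_true,
            "proportion_true": self.proportion_true,
        }


def _table(name, level, vids, chrom, pos, ea, oa, eaf, beta, se, N) -> SummaryStatsTable:
    z = beta / se
    from scipy import stats as sps

    p = np.maximum(2.0 * sps.norm.sf(np.abs(z)), np.finfo(float).tiny)
    df = pd.DataFrame(
        {
            "variant_id": vids,
            "chromosome": chrom,
            "position": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": p,
            "n": N,
        }
    )
    return SummaryStatsTable(name, df, level)


def simulate_chain(
    config: SimulationConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, SummaryStatsTable, TruthSet, LDMatrix | None]:
    """Generate exposure, mediator and outcome summary-statistics tables.

    Returns (exposure, mediator, outcome, truth, ld); ``ld`` is None
    unless the config asks for LD blocks. The variant panel is shared by
    all three tables and deterministic under the config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    J_exp = config.n_snp
    J = J_exp + config.mediator_own_instruments

    vids = [f"rs{j + 1:06d}" for j in range(J)]
    chrom = np.full(J, "1")
    pos = 1 + np.arange(J, dtype=int) * 100_000
    ea = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][0] for j in range(J)]
    oa = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][1] for j in range(J)]
    eaf = rng.uniform(*config.eaf_range, size=J)

    gamma_true = np.zeros(J)
    gamma_true[:J_exp] = rng.normal(0.0, config.gamma_sd, size=J_exp)
    m_true = config.alpha_em * gamma_true
    if config.mediator_own_instruments:
        m_true[J_exp:] = rng.normal(
            0.0, config.gamma_sd, size=config.mediator_own_instruments
        )

    pi = np.zeros(J)
    n_invalid = int(round(config.frac_invalid * J_exp))
    if config.pleiotropy != "none" and n_invalid:
        invalid = rng.choice(J_exp, size=n_invalid, replace=False)
        if config.pleiotropy == "balanced":
            pi[invalid] = rng.normal(0.0, config.pleiotropy_sd, size=n_invalid)
        else:  # directional, oriented to the exposure-increasing allele
            draw = rng.normal(
                config.pleiotropy_mean, config.pleiotropy_sd, size=n_invalid
            )
            sgn = np.sign(gamma_true[invalid])
            sgn[sgn == 0] = 1.0
            pi[invalid] = sgn * draw
    Gamma_true = config.theta_direct * gamma_true + config.theta_m * m_true + pi

    se_exp = 1.0 / np.sqrt(2.0 * config.n_exposure * eaf * (1.0 - eaf))
    se_med = 1.0 / np.sqrt(2.0 * config.n_mediator * eaf * (1.0 - eaf))
    se_out = 1.0 / np.sqrt(2.0 * config.n_outcome * eaf * (1.0 - eaf))

    beta_exp = gamma_true + rng.normal(0.0, se_exp)
    beta_med = m_true + rng.normal(0.0, se_med)
    beta_out = Gamma_true + rng.normal(0.0, se_out)

    exposure = _table(
        "exposure", "genus", vids, chrom, pos, ea, oa, eaf, beta_exp, se_exp,
        config.n_exposure,
    )
    mediator = _table(
        "mediator", "immune", vids, chrom, pos, ea, oa, eaf, beta_med, se_med,
        config.n_mediator,
    )
    outcome = _table(
        "outcome", "disease", vids, chrom, pos, ea, oa, eaf, beta_out, se_out,
        config.n_outcome,
    )

    indirect = config.alpha_em * config.theta_m
    total = config.theta_direct + indirect
    truth = TruthSet(
        config=replace(config),
        total_true=total,
        direct_true=config.theta_direct,
        indirect_true=indirect,
        proportion_true=indirect / total if total != 0 else float("nan"),
        gamma_true=gamma_true,
        m_true=m_true,
        Gamma_true=Gamma_true,
        pleiotropy_offsets=pi,
        exposure_instrument_ids=vids[:J_exp],
        mediator_instrument_ids=vids[J_exp:],
    )

    ld = None
    if config.ld_block_size > 1:
        ld = make_ld_blocks(vids, config.ld_block_size, config.ld_rho)
    return exposure, mediator, outcome, truth, ld


def make_ld_blocks(variant_ids, block_size: int, rho: float) -> LDMatrix:
    """Block-diagonal LD with within-block r^2(i, j) = rho^(2|i-j|)."""
    if not 0.0 <= rho < 1.0:
        raise ConfigError("rho must lie in [0, 1)")
    J = len(variant_ids)
    r2 = np.eye(J)
    if block_size > 1 and rho > 0:
        for start in range(0, J, block_size):
            stop = min(start + block_size, J)
            idx = np.arange(start, stop)
            d = np.abs(idx[:, None] - idx[None, :])
            r2[start:stop, start:stop] = rho ** (2 * d)
    return LDMatrix(list(variant_ids), r2)


def simulate_study(
    n_exposures: int = 10,
    n_mediators: int = 5,
    seed: int = 0,
    n_snp_per_trait: int = 30,
    n_exposure: int = 200_000,
    n_mediator: int = 200_000,
    n_outcome: int = 200_000,
    gamma_sd: float = 0.1,
    theta_direct: float = 0.35,
    alpha_em: float = 0.3,
    theta_m: float = 0.5,
    eaf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[list[SummaryStatsTable], list[SummaryStatsTable], SummaryStatsTable, dict]:
    """A multi-exposure, multi-mediator study over one shared variant panel.

    The panel is partitioned into disjoint instrument blocks, one per
    exposure and one per mediator; every trait table covers the full
    panel (complete overlap). Even-indexed exposures carry a true direct
    effect ``theta_direct`` on the outcome and act on one mediator with
    effect ``alpha_em``; every mediator affects the outcome with
    ``theta_m``. Odd-indexed exposures are pure nulls. Returns
    (exposures, mediators, outcome, truth) where ``truth`` maps each
    exposure name to its (total, direct, indirect, proportion).
    """
    if n_exposures < 1 or n_mediators < 1:
        raise ConfigError("need at least one exposure and one mediator")
    rng = np.random.default_rng(seed)
    B = n_snp_per_trait
    J = (n_exposures + n_mediators) * B
    vids = [f"rs{j + 1:06d}" for j in range(J)]
    # one chromosome per block keeps blocks outside each other's clump window
    chrom = np.repeat(
        [str(1 + b % 22) for b in range(n_exposures + n_mediators)], B
    )
    pos = np.tile(1 + np.arange(B, dtype=int) * 100_000, n_exposures + n_mediators)
    ea = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][0] for j in range(J)]
    oa = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][1] for j in range(J)]
    eaf = rng.uniform(*eaf_range, size=J)

    levels = ["genus", "family", "phylum"]
    gamma = np.zeros((n_exposures, J))
    for e in range(n_exposures):
        sl = slice(e * B, (e + 1) * B)
        gamma[e, sl] = rng.normal(0.0, gamma_sd, size=B)
    m_true = np.zeros((n_mediators, J))
    for k in range(n_mediators):
        sl = slice((n_exposures + k) * B, (n_exposures + k + 1) * B)
        m_true[k, sl] = rng.normal(0.0, gamma_sd, size=B)

    theta_e = np.array(
        [theta_direct if e % 2 == 0 else 0.0 for e in range(n_exposures)]
    )
    alpha = np.zeros((n_exposures, n_mediators))
    for e in range(n_exposures):
        if theta_e[e] != 0.0:
            alpha[e, e % n_mediators] = alpha_em
    for e in range(n_exposures):
        for k in range(n_mediators):
            if alpha[e, k]:
                m_true[k] = m_true[k] + alpha[e, k] * gamma[e]

    Gamma_true = theta_e @ gamma + np.full(n_mediators, theta_m) @ m_true

    se_exp = 1.0 / np.sqrt(2.0 * n_exposure * eaf * (1.0 - eaf))
    se_med = 1.0 / np.sqrt(2.0 * n_mediator * eaf * (1.0 - eaf))
    se_out = 1.0 / np.sqrt(2.0 * n_outcome * eaf * (1.0 - eaf))

    exposures = []
    for e in range(n_exposures):
        beta = gamma[e] + rng.normal(0.0, se_exp)
        exposures.append(
            _table(
                f"taxon_{e + 1:02d}", levels[e % len(levels)],
                vids, chrom, pos, ea, oa, eaf, beta, se_exp, n_exposure,
            )
        )
    mediators = []
    for k in range(n_mediators):
        beta = m_true[k] + rng.normal(0.0, se_med)
        mediators.append(
            _table(
                f"immune_{k + 1:02d}", "immune",
                vids, chrom, pos, ea, oa, eaf, beta, se_med, n_mediator,
            )
        )
    beta_out = Gamma_true + rng.normal(0.0, se_out)
    outcome = _table(
        "disease", "disease", vids, chrom, pos, ea, oa, eaf, beta_out, se_out,
        n_outcome,
    )

    truth = {}
    for e in range(n_exposures):
        indirect = float(alpha[e] @ np.full(n_mediators, theta_m))
        total = float(theta_e[e] + indirect)
        truth[exposures[e].trait_name] = {
            "direct": float(theta_e[e]),
            "indirect": indirect,
            "total": total,
            "proportion": indirect / total if total else float("nan"),
            "mediator": (
                mediators[e % n_mediators].trait_name if indirect else None
            ),
        }
    return exposures, mediators, outcome, truth


# ---------------------------------------------------------------------------
# Fast harmonized views (the panel is shared and already allele-aligned,
# so simulation studies can skip the string-level harmonization path).
# ---------------------------------------------------------------------------

def harmonized_exposure_outcome(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    variant_ids=None,
) -> HarmonizedSet:
    """Aligned exposure->outcome effect arrays for simulated tables."""
    return _aligned([exposure], outcome, variant_ids)


def harmonized_multivariable(
    exposures: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    variant_ids=None,
) -> HarmonizedSet:
    """Aligned multi-exposure (MVMR) effect arrays for simulated tables."""
    return _aligned(exposures, outcome, variant_ids)


def _aligned(exposures, outcome, variant_ids) -> HarmonizedSet:
    base = exposures[0].records
    if variant_ids is None:
        variant_ids = base["variant_id"].tolist()
    keep = list(variant_ids)
    mats, sigs = [], []
    for t in exposures:
        ix = t.records.set_index("variant_id").loc[keep]
        mats.append(ix["beta"].to_numpy(float))
        sigs.append(ix["se"].to_numpy(float))
    ox = outcome.records.set_index("variant_id").loc[keep]
    if len(exposures) == 1:
        return HarmonizedSet.from_arrays(
            mats[0], sigs[0], ox["beta"].to_numpy(float), ox["se"].to_numpy(float),
            exposure_name=exposures[0].trait_name, variant_ids=keep,
        )
    return HarmonizedSet.from_matrix(
        np.column_stack(mats),
        np.column_stack(sigs),
        ox["beta"].to_numpy(float),
        ox["se"].to_numpy(float),
        [t.trait_name for t in exposures],
        variant_ids=keep,
    )
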