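"""End-to-end orchestration: forward MR screen, reverse MR, mediation.

The pipeline reproduces the study design of a microbiota -> immune-trait
-> disease MR analysis from a single config: for every exposure it
selects instruments (significance ladder + greedy LD clumping),
harmonizes against the outcome, runs the full estimator suite with
diagnostics, routes the primary estimate by the sensitivity results and
applies per-taxonomic-level Bonferroni correction; mediator screening
and the MVMR-based mediation decomposition follow, plus a reverse MR
mode with outcome and exposures swapped. Per-trait failures (e.g. no
overlapping SNPs) are logged and skipped, never fatal — the real study
screens hundreds of taxa and traits.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .estimators import (
    cochran_q,
    ivw,
    mr_egger,
    mr_presso,
    summarize_or,
    weighted_median,
)
from .gwas_io import (
    DEFAULT_AMBIGUITY_WINDOW,
    HarmonizedSet,
    SummaryStatsTable,
    harmonize,
    read_summary_stats,
)
from .instruments import (
    DEFAULT_CLUMP_R2,
    DEFAULT_MIN_SNPS,
    DEFAULT_P_LADDER,
    DEFAULT_WINDOW_KB,
    LDMatrix,
    choose_threshold,
    clump_greedy,
    instrument_strength,
)
from .mediation import (
    bonferroni_by_level,
    decompose_mediation,
    mvmr_ivw,
    route_primary,
    screen_mediators,
)

log = logging.getLogger(__name__)

SCREEN_COLUMNS = [
    "exposure",
    "outcome",
    "taxonomic_level",
    "p_threshold",
    "threshold_warning",
    "n_candidates",
    "n_snp",
    "R2",
    "F",
    "method_primary",
    "beta",
    "se",
    "pvalue",
    "OR",
    "CI_low",
    "CI_high",
    "Q",
    "Q_p",
    "egger_intercept",
    "egger_intercept_p",
    "presso_global_p",
    "heterogeneity",
    "pleiotropy",
    "n_dropped_palindromic",
    "n_dropped_mismatch",
]

MR_RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "method",
    "n_snp",
    "beta",
    "se",
    "pvalue",
    "OR",
    "CI_low",
    "CI_high",
    "Q",
    "Q_p",
    "egger_intercept",
    "egger_intercept_p",
    "presso_global_p",
]

MEDIATION_COLUMNS = [
    "exposure",
    "mediator",
    "outcome",
    "total_beta",
    "direct_beta",
    "indirect",
    "proportion_pct",
    "step1_beta",
    "step2_beta",
    "product_indirect",
    "sign_consistent",
    "method_primary_total",
    "method_primary_direct",
]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; every analysis is derived from it."""

    exposures: list[SummaryStatsTable]
    outcome: SummaryStatsTable
    mediators: list[SummaryStatsTable] = field(default_factory=list)
    ld: LDMatrix | None = None
    p_ladder: tuple = DEFAULT_P_LADDER
    min_snps: int = DEFAULT_MIN_SNPS
    clump_r2_max: float = DEFAULT_CLUMP_R2
    window_kb: float = DEFAULT_WINDOW_KB
    ambiguity_window: tuple = DEFAULT_AMBIGUITY_WINDOW
    alpha: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int | None = None
    f_variant: str = "paper"
    level_counts: dict | None = None
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory in the pipeline config")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config and read all referenced tables."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: not a mapping")
    paths = raw.get("paths", {})
    base = Path(path).parent

    def _read(entry, default_level=None):
        p = base / entry["path"] if not Path(entry["path"]).is_absolute() else Path(entry["path"])
        return read_summary_stats(
            p,
            column_map=entry.get("column_map"),
            trait_name=entry.get("name", Path(entry["path"]).stem),
            trait_level=entry.get("level", default_level),
        )

    try:
        exposures = [_read(e) for e in paths["exposures"]]
        outcome = _read(paths["outcome"], default_level="disease")
    except KeyError as exc:
        raise ConfigError(f"{path}: missing paths section {exc}") from exc
    mediators = [_read(e, "immune") for e in paths.get("mediators", [])]
    ld = None
    if paths.get("ld"):
        ldp = base / paths["ld"] if not Path(paths["ld"]).is_absolute() else Path(paths["ld"])
        ld = LDMatrix.from_file(ldp)

    thr = raw.get("thresholds", {})
    ana = raw.get("analysis", {})
    if "seed" not in ana:
        raise ConfigError(f"{path}: analysis.seed is mandatory")
    return PipelineConfig(
        exposures=exposures,
        outcome=outcome,
        mediators=mediators,
        ld=ld,
        p_ladder=tuple(thr.get("p_ladder", DEFAULT_P_LADDER)),
        min_snps=int(thr.get("min_snps", DEFAULT_MIN_SNPS)),
        clump_r2_max=float(thr.get("clump_r2_max", DEFAULT_CLUMP_R2)),
        window_kb=float(thr.get("window_kb", DEFAULT_WINDOW_KB)),
        ambiguity_window=tuple(thr.get("ambiguity_window", DEFAULT_AMBIGUITY_WINDOW)),
        alpha=float(ana.get("alpha", 0.05)),
        n_boot=int(ana.get("n_boot", 1000)),
        n_sim=int(ana.get("n_sim", 1000)),
        seed=int(ana["seed"]),
        f_variant=str(ana.get("f_variant", "paper")),
        level_counts=ana.get("level_counts"),
        output_dir=raw.get("output_dir"),
    )


def _subseed(seed: int, tag: str) -> int:
    """Stable per-task sub-seed derived from the run seed."""
    return (int(seed) ^ zlib.crc32(tag.encode())) % (2**31)


@dataclass
class PairResult:
    """Everything estimated for one exposure -> outcome pair."""

    row: dict
    harmonized: HarmonizedSet
    instrument_ids: list
    estimates: dict


def analyse_pair(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    config: PipelineConfig,
    tag: str,
) -> PairResult:
    """Instrument selection -> harmonization -> estimator suite for one pair."""
    t0 = time.perf_counter()
    thr, cands, warned = choose_threshold(exposure, config.p_ladder, config.min_snps)
    if cands.empty:
        raise DataError(
            f"{exposure.trait_name}: no candidate instruments at the ladder floor"
        )
    iset = clump_greedy(
        cands,
        config.ld,
        config.clump_r2_max,
        config.window_kb,
        trait_name=exposure.trait_name,
        p_threshold_used=thr,
    )
    sub = SummaryStatsTable(
        exposure.trait_name,
        exposure.records[
            exposure.records["variant_id"].isin(iset.variant_ids)
        ].reset_index(drop=True),
        exposure.trait_level,
    )
    h = harmonize(sub, outcome, config.ambiguity_window)
    J = h.n_snp

    est_fe = ivw(h, "fixed")
    est_re = ivw(h, "random") if J >= 2 else None
    q = cochran_q(h) if J >= 2 else None
    egger = None
    if J >= 3:
        try:
            egger = mr_egger(h)
        except DataError:
            egger = None
    wm = (
        weighted_median(h, config.n_boot, _subseed(config.seed, tag + ":wm"))
        if J >= 3
        else None
    )
    presso = (
        mr_presso(h, config.n_sim, _subseed(config.seed, tag + ":presso"), config.alpha)
        if J >= 4
        else None
    )
    method, primary, flags = route_primary(est_fe, est_re, egger, q, presso, config.alpha)
    N = int(exposure.records["n"].median())
    strength = instrument_strength(h, N, config.f_variant)
    odds, lo, hi = summarize_or(primary)

    row = {
        "exposure": exposure.trait_name,
        "outcome": outcome.trait_name,
        "taxonomic_level": exposure.trait_level or "",
        "p_threshold": thr,
        "threshold_warning": warned,
        "n_candidates": iset.n_candidates_pre_clump,
        "n_snp": J,
        "R2": strength.R2_total,
        "F": strength.F,
        "method_primary": method,
        "beta": primary.beta,
        "se": primary.se,
        "pvalue": primary.pvalue,
        "OR": odds,
        "CI_low": lo,
        "CI_high": hi,
        "Q": q.Q if q else float("nan"),
        "Q_p": q.pvalue if q else float("nan"),
        "egger_intercept": egger.intercept if egger else float("nan"),
        "egger_intercept_p": egger.intercept_p if egger else float("nan"),
        "presso_global_p": presso.global_p if presso else float("nan"),
        "heterogeneity": flags["heterogeneity"],
        "pleiotropy": flags["pleiotropy"],
        "n_dropped_palindromic": len(h.dropped_palindromes),
        "n_dropped_mismatch": len(h.dropped_mismatch),
    }
    estimates = {
        "ivw_fe": est_fe,
        "ivw_re": est_re,
        "egger": egger,
        "weighted_median": wm,
        "q": q,
        "presso": presso,
        "primary": primary,
        "method_primary": method,
    }
    log.info(
        "pair %s -> %s: n_candidates=%d n_snp=%d primary=%s beta=%.4f p=%.3g (%.2fs)",
        exposure.trait_name,
        outcome.trait_name,
        len(cands),
        J,
        method,
        primary.beta,
        primary.pvalue,
        time.perf_counter() - t0,
    )
    return PairResult(row, h, list(h.variant_ids), estimates)


def _mr_result_rows(pair: PairResult) -> list[dict]:
    rows = []
    est = pair.estimates
    q = est["q"]
    egger = est["egger"]
    presso = est["presso"]
    common = {
        "exposure": pair.row["exposure"],
        "outcome": pair.row["outcome"],
        "Q": q.Q if q else float("nan"),
        "Q_p": q.pvalue if q else float("nan"),
        "egger_intercept": egger.intercept if egger else float("nan"),
        "egger_intercept_p": egger.intercept_p if egger else float("nan"),
        "presso_global_p": presso.global_p if presso else float("nan"),
    }
    for name in ("ivw_fe", "ivw_re", "weighted_median"):
        e = est[name]
        if e is None:
            continue
        odds, lo, hi = summarize_or(e)
        rows.append(
            dict(
                common,
                method=e.method,
                n_snp=e.n_snp,
                beta=e.beta,
                se=e.se,
                pvalue=e.pvalue,
                OR=odds,
                CI_low=lo,
                CI_high=hi,
            )
        )
    if egger is not None:
        e = egger.slope
        odds, lo, hi = summarize_or(e)
        rows.append(
            dict(
                common,
                method="egger",
                n_snp=e.n_snp,
                beta=e.beta,
                se=e.se,
                pvalue=e.pvalue,
                OR=odds,
                CI_low=lo,
                CI_high=hi,
            )
        )
    return rows


@dataclass
class StageResult:
    screening: pd.DataFrame
    mr_results: pd.DataFrame
    failures: list = field(default_factory=list)
    pairs: dict = field(default_factory=dict)


def _run_screen(
    exposures: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    config: PipelineConfig,
    stage: str,
    apply_bonferroni: bool,
) -> StageResult:
    rows, mr_rows, failures = [], [], []
    pairs: dict = {}
    for exp in exposures:
        tag = f"{stage}:{exp.trait_name}"
        try:
            pair = analyse_pair(exp, outcome, config, tag)
        except DataError as exc:
            log.warning("%s: skipped %s (%s)", stage, exp.trait_name, exc)
            failures.append({"exposure": exp.trait_name, "error": str(exc)})
            continue
        rows.append(pair.row)
        mr_rows.extend(_mr_result_rows(pair))
        pairs[exp.trait_name] = pair
    screening = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    if apply_bonferroni and not screening.empty:
        counts = config.level_counts
        if counts is None:
            counts = screening["taxonomic_level"].value_counts().to_dict()
        screening = bonferroni_by_level(screening, counts)
    mr_results = pd.DataFrame(mr_rows, columns=MR_RESULT_COLUMNS)
    return StageResult(screening, mr_results, failures, pairs)


def run_forward(config: PipelineConfig) -> StageResult:
    """Forward screen: every exposure against the outcome, with Bonferroni."""
    return _run_screen(config.exposures, config.outcome, config, "forward", True)


def run_reverse(config: PipelineConfig) -> StageResult:
    """Reverse MR: instruments from the outcome GWAS, exposures as outcomes."""
    rows, mr_rows, failures = [], [], []
    pairs: dict = {}
    for exp in config.exposures:
        tag = f"reverse:{exp.trait_name}"
        try:
            pair = analyse_pair(config.outcome, exp, config, tag)
        except DataError as exc:
            log.warning("reverse: skipped %s (%s)", exp.trait_name, exc)
            failures.append({"exposure": config.outcome.trait_name,
                             "outcome": exp.trait_name, "error": str(exc)})
            continue
        rows.append(pair.row)
        mr_rows.extend(_mr_result_rows(pair))
        pairs[exp.trait_name] = pair
    return StageResult(
        pd.DataFrame(rows, columns=SCREEN_COLUMNS),
        pd.DataFrame(mr_rows, columns=MR_RESULT_COLUMNS),
        failures,
        pairs,
    )


def run_mediation(config: PipelineConfig, forward: StageResult) -> pd.DataFrame:
    """Two-step mediation over all screened (exposure, mediator) triples."""
    alpha = config.alpha
    screening = forward.screening
    if screening.empty or not config.mediators:
        return pd.DataFrame(columns=MEDIATION_COLUMNS)

    med_out = _run_screen(config.mediators, config.outcome, config, "med_out", False)
    med_out_tab = med_out.screening.rename(columns={"exposure": "mediator"})

    sig_exp = screening.loc[screening["pvalue"] < alpha, "exposure"].tolist()
    sig_med = med_out_tab.loc[med_out_tab["pvalue"] < alpha, "mediator"].tolist()
    med_by_name = {m.trait_name: m for m in config.mediators}
    exp_by_name = {e.trait_name: e for e in config.exposures}

    em_rows = []
    em_pairs: dict = {}
    for e_name in sig_exp:
        for m_name in sig_med:
            tag = f"exp_med:{e_name}:{m_name}"
            try:
                pair = analyse_pair(exp_by_name[e_name], med_by_name[m_name], config, tag)
            except DataError as exc:
                log.warning("mediation step1 skipped %s->%s (%s)", e_name, m_name, exc)
                continue
            em_rows.append(
                {"exposure": e_name, "mediator": m_name, "pvalue": pair.row["pvalue"]}
            )
            em_pairs[(e_name, m_name)] = pair

    if not em_rows:
        return pd.DataFrame(columns=MEDIATION_COLUMNS)
    triples = screen_mediators(
        screening[["exposure", "pvalue"]],
        med_out_tab[["mediator", "pvalue"]],
        pd.DataFrame(em_rows),
        alpha,
    )

    rows = []
    for e_name, m_name in triples:
        try:
            row = _decompose_triple(
                config, forward, med_out, em_pairs[(e_name, m_name)], e_name, m_name
            )
        except DataError as exc:
            log.warning("mediation triple %s/%s failed (%s)", e_name, m_name, exc)
            continue
        rows.append(row)
    return pd.DataFrame(rows, columns=MEDIATION_COLUMNS)


def _decompose_triple(config, forward, med_out, step1_pair, e_name, m_name) -> dict:
    exp_pair = forward.pairs[e_name]
    med_pair = med_out.pairs[m_name]
    exposure = next(e for e in config.exposures if e.trait_name == e_name)
    mediator = next(m for m in config.mediators if m.trait_name == m_name)

    # MVMR instrument set: union of both traits' instruments, re-clumped
    # jointly by the smaller of the two association p-values.
    union = set(exp_pair.instrument_ids) | set(med_pair.instrument_ids)
    exp_ix = exposure.indexed()
    med_ix = mediator.indexed()
    union = [v for v in union if v in exp_ix.index and v in med_ix.index]
    cand = exp_ix.loc[union].reset_index(drop=True)
    cand["pvalue"] = np.minimum(
        exp_ix.loc[union, "pvalue"].to_numpy(),
        med_ix.loc[union, "pvalue"].to_numpy(),
    )
    cand = cand.sort_values(["pvalue", "variant_id"], kind="mergesort").reset_index(
        drop=True
    )
    iset = clump_greedy(cand, config.ld, config.clump_r2_max, config.window_kb)
    ids = iset.variant_ids

    exp_sub = SummaryStatsTable(
        e_name,
        exposure.records[exposure.records["variant_id"].isin(ids)].reset_index(drop=True),
        exposure.trait_level,
    )
    med_sub = SummaryStatsTable(
        m_name,
        mediator.records[mediator.records["variant_id"].isin(ids)].reset_index(drop=True),
        mediator.trait_level,
    )
    h = harmonize([exp_sub, med_sub], config.outcome, config.ambiguity_window)
    mv = mvmr_ivw(h)
    direct = mv.estimate_for(e_name)
    total = exp_pair.estimates["primary"]
    step1 = step1_pair.estimates["primary"]
    step2 = med_pair.estimates["primary"]
    res = decompose_mediation(
        total, direct, step1, step2,
        exposure=e_name, mediator=m_name, outcome=config.outcome.trait_name,
    )
    return {
        "exposure": e_name,
        "mediator": m_name,
        "outcome": config.outcome.trait_name,
        "total_beta": res.total.beta,
        "direct_beta": res.direct.beta,
        "indirect": res.indirect,
        "proportion_pct": 100.0 * res.proportion,
        "step1_beta": step1.beta,
        "step2_beta": step2.beta,
        "product_indirect": res.product_indirect,
        "sign_consistent": res.sign_consistent,
        "method_primary_total": exp_pair.estimates["method_primary"],
        "method_primary_direct": "mvmr_ivw",
    }


def run_pipeline(config: PipelineConfig, output_dir=None) -> dict:
    """Forward + reverse + mediation; write TSV reports and a run report.

    Output files are written with a fixed float format so identical
    config + seed reproduces them byte for byte.
    """
    out = Path(output_dir or config.output_dir or ".")
    out.mkdir(parents=True, exist_ok=True)

    forward = run_forward(config)
    reverse = run_reverse(config)
    med = run_mediation(config, forward)

    _write(forward.screening, out / "forward_screening.tsv")
    _write(forward.mr_results, out / "forward_mr_results.tsv")
    _write(reverse.screening, out / "reverse_screening.tsv")
    _write(reverse.mr_results, out / "reverse_mr_results.tsv")
    _write(med, out / "mediation_results.tsv")

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_exposures": len(config.exposures),
        "n_mediators": len(config.mediators),
        "forward_rows": int(len(forward.screening)),
        "forward_failures": forward.failures,
        "reverse_rows": int(len(reverse.screening)),
        "reverse_failures": reverse.failures,
        "mediation_rows": int(len(med)),
        "config": {
            "p_ladder": list(config.p_ladder),
            "min_snps": config.min_snps,
            "clump_r2_max": config.clump_r2_max,
            "window_kb": config.window_kb,
            "ambiguity_window": list(config.ambiguity_window),
            "alpha": config.alpha,
            "n_boot": config.n_boot,
            "n_sim": config.n_sim,
            "f_variant": config.f_variant,
        },
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
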