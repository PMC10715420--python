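"""Instrument selection: significance thresholding, LD clumping, strength.

Instruments are SNPs robustly associated with the exposure. Selection
follows the usual two-sample MR recipe: filter by a genome-wide p-value
threshold (relaxing down a ladder when too few SNPs survive), greedily
clump to approximate independence under an LD r-squared / distance rule,
and summarise strength with the variance explained R^2 and an
F-statistic (F > 10 is the conventional adequacy bar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .gwas_io import HarmonizedSet, SummaryStatsTable

#: Default significance ladder: genome-wide, then the relaxed threshold.
DEFAULT_P_LADDER = (5e-8, 5e-5)
DEFAULT_MIN_SNPS = 20
DEFAULT_CLUMP_R2 = 0.01
DEFAULT_WINDOW_KB = 10_000.0


@dataclass
class LDMatrix:
    """Squared-correlation (r^2) matrix over an ordered variant panel."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape does not match variant_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise DataError(f"variant {exc.args[0]!r} missing from LD matrix") from exc

    @classmethod
    def from_file(cls, path) -> "LDMatrix":
        with open(path) as fh:
            header = fh.readline().split()
            mat = np.loadtxt(fh)
        if mat.ndim == 1:
            mat = mat.reshape(1, 1)
        return cls(header, mat)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(" ".join(self.variant_ids) + "\n")
            np.savetxt(fh, self.r2, fmt="%.10g")


@dataclass
class InstrumentSet:
    """Clumped instruments for one trait."""

    trait_name: str
    p_threshold_used: float
    variant_ids: list[str]
    n_candidates_pre_clump: int
    clump_r2_max: float
    clump_window_kb: float
    independence_assumed: bool = False
    threshold_warning: bool = False


@dataclass
class StrengthReport:
    """Instrument-strength summary.

    ``formula_variant="paper"`` computes F = R^2 * [(N-1-k)/k] * (1-R^2);
    ``"standard"`` computes the textbook F = [R^2/(1-R^2)] * [(N-1-k)/k].
    """

    R2_total: float
    F: float
    N: int
    k: int
    formula_variant: str
    per_snp_r2: list = field(default_factory=list)


def select_candidates(stats: SummaryStatsTable, p_threshold: float) -> pd.DataFrame:
    """SNPs with p below ``p_threshold``, sorted by ascending p.

    Ties in p break lexicographically on variant_id so downstream clumping
    is deterministic.
    """
    if not (0 < p_threshold <= 1):
        raise ConfigError(f"p_threshold must be in (0, 1]; got {p_threshold}")
    df = stats.records
    out = df[df["pvalue"] < p_threshold].sort_values(
        ["pvalue", "variant_id"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def choose_threshold(
    stats: SummaryStatsTable,
    ladder=DEFAULT_P_LADDER,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> tuple[float, pd.DataFrame, bool]:
    """Pick the most stringent ladder threshold yielding >= min_snps SNPs.

    Falls back to the least stringent rung (with a warning flag) when no
    rung reaches ``min_snps``. Returns (threshold, candidates, warned).
    """
    ladder = list(ladder)
    if not ladder:
        raise ConfigError("empty significance ladder")
    for thr in ladder:
        cands = select_candidates(stats, thr)
        if len(cands) >= min_snps:
            return thr, cands, False
    thr = ladder[-1]
    return thr, select_candidates(stats, thr), True


def clump_greedy(
    candidates: pd.DataFrame,
    ld: LDMatrix | None,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_WINDOW_KB,
    trait_name: str = "",
    p_threshold_used: float = float("nan"),
) -> InstrumentSet:
    """Greedy p-value clumping.

    Iterate candidates by ascending p; keep a SNP iff its r^2 with every
    already-kept SNP on the same chromosome within ``window_kb`` is
    <= ``r2_max``. With no LD matrix all candidates are kept and the set
    is flagged ``independence_assumed``.
    """
    kept: list[int] = []
    vids = candidates["variant_id"].tolist()
    if ld is None:
        kept = list(range(len(vids)))
        return InstrumentSet(
            trait_name,
            p_threshold_used,
            [vids[i] for i in kept],
            len(vids),
            r2_max,
            window_kb,
            independence_assumed=True,
        )
    chrom = candidates["chromosome"].astype(str).to_numpy()
    pos = candidates["position"].to_numpy(float)
    window_bp = window_kb * 1000.0
    for i in range(len(vids)):
        ok = True
        for j in kept:
            if chrom[i] != chrom[j] or abs(pos[i] - pos[j]) > window_bp:
                continue
            if ld.lookup(vids[i], vids[j]) > r2_max:
                ok = False
                break
        if ok:
            kept.append(i)
    return InstrumentSet(
        trait_name,
        p_threshold_used,
        [vids[i] for i in kept],
        len(vids),
        r2_max,
        window_kb,
    )


def instrument_strength(
    harmonized: HarmonizedSet | None,
    N: int,
    formula_variant: str = "paper",
    gamma=None,
    sigma_gamma=None,
) -> StrengthReport:
    """Variance explained and F-statistic from summary statistics.

    Per-SNP R^2 is t^2 / (t^2 + N - 2) with t = gamma/sigma_gamma; the
    total R^2 sums per-SNP contributions (independence after clumping).
    """
    if harmonized is not None:
        gamma = harmonized.gamma
        sigma_gamma = harmonized.sigma_gamma
    gamma = np.asarray(gamma, float)
    sigma_gamma = np.asarray(sigma_gamma, float)
    k = gamma.shape[0]
    if N <= k + 1:
        raise DataError(f"need N > k + 1 for the F statistic (N={N}, k={k})")
    t2 = (gamma / sigma_gamma) ** 2
    per_snp = t2 / (t2 + N - 2)
    R2 = float(per_snp.sum())
    F = f_statistic(R2, N, k, formula_variant)
    return StrengthReport(R2, F, int(N), int(k), formula_variant, per_snp.tolist())


def f_statistic(R2: float, N: int, k: int, formula_variant: str = "paper") -> float:
    """F from total R^2, sample size N and instrument count k."""
    ratio = (N - 1 - k) / k
    if formula_variant == "paper":
        return float(R2 * ratio * (1.0 - R2))
    if formula_variant == "standard":
        return float(R2 / (1.0 - R2) * ratio)
    raise ConfigError(f"unknown F formula variant {formula_variant!r}")
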