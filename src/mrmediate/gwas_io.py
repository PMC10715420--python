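"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample MR combines per-SNP effects from an exposure GWAS (gamma_j,
sigma_gamma_j) with effects from an outcome GWAS (Gamma_j, sigma_Gamma_j).
Before any estimator can run, both tables must refer to the *same* effect
allele at every SNP; ``harmonize`` performs that alignment, resolving
allele swaps and strand flips, orienting palindromic (A/T, C/G) SNPs by
allele frequency where the frequency is informative, and dropping them
where it is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, HarmonizationError

log = logging.getLogger(__name__)

#: Canonical column order for a summary-statistics table.
CANONICAL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Classification labels for :func:`classify_palindromic`.
NOT_PALINDROMIC = "not_palindromic"
PALINDROMIC_INFERABLE = "palindromic_inferable"
PALINDROMIC_AMBIGUOUS = "palindromic_ambiguous"

#: Default EAF window inside which a palindromic SNP cannot be oriented.
DEFAULT_AMBIGUITY_WINDOW = (0.42, 0.58)


@dataclass
class SummaryStatsTable:
    """One GWAS trait's per-variant association records.

    ``records`` is a DataFrame with the canonical columns; ``variant_id``
    is unique. ``trait_level`` carries the taxonomic level for microbiota
    taxa (phylum/class/order/family/genus) or ``"immune"``/``"disease"``.
    """

    trait_name: str
    records: pd.DataFrame
    trait_level: str | None = None

    def __post_init__(self) -> None:
        if self.records.empty:
            raise EmptyInputError(f"{self.trait_name}: no records")
        if self.records["variant_id"].duplicated().any():
            dup = self.records.loc[
                self.records["variant_id"].duplicated(), "variant_id"
            ].iloc[0]
            raise FormatError(f"{self.trait_name}: duplicate variant_id {dup!r}")

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def indexed(self) -> pd.DataFrame:
        """Records indexed by variant_id (copy-free view where possible)."""
        return self.records.set_index("variant_id", drop=False)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class HarmonizedSet:
    """Exposure(+mediator) and outcome effects aligned to one effect allele.

    ``table`` has one row per retained instrument SNP with columns
    ``variant_id``, ``gamma.<exposure>``, ``sigma_gamma.<exposure>``,
    ``eaf.<exposure>`` per exposure, plus ``Gamma``, ``sigma_Gamma``,
    ``eaf_outcome`` and the audit flag ``flipped`` (outcome effect was
    sign-flipped to match the exposure's effect allele).
    """

    exposure_names: list[str]
    table: pd.DataFrame
    dropped_palindromes: list[tuple[str, str]] = field(default_factory=list)
    dropped_mismatch: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        dropped = {vid for vid, _ in self.dropped_palindromes}
        retained = set(self.table["variant_id"])
        if retained & dropped:
            raise ValueError("retained variant appears in dropped_palindromes")
        for name in self.exposure_names:
            if (self.table[f"sigma_gamma.{name}"] <= 0).any():
                raise ValueError("sigma_gamma must be positive")
        if len(self.table) and (self.table["sigma_Gamma"] <= 0).any():
            raise ValueError("sigma_Gamma must be positive")

    # -- array accessors -------------------------------------------------
    @property
    def n_snp(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    def _single(self) -> str:
        if len(self.exposure_names) != 1:
            raise ValueError(
                "operation requires a single-exposure HarmonizedSet; "
                f"got exposures {self.exposure_names}"
            )
        return self.exposure_names[0]

    @property
    def gamma(self) -> np.ndarray:
        return self.table[f"gamma.{self._single()}"].to_numpy(float)

    @property
    def sigma_gamma(self) -> np.ndarray:
        return self.table[f"sigma_gamma.{self._single()}"].to_numpy(float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.table["Gamma"].to_numpy(float)

    @property
    def sigma_Gamma(self) -> np.ndarray:
        return self.table["sigma_Gamma"].to_numpy(float)

    def gamma_matrix(self) -> np.ndarray:
        """(J, K) matrix of exposure effects, one column per exposure."""
        return np.column_stack(
            [self.table[f"gamma.{n}"].to_numpy(float) for n in self.exposure_names]
        )

    def sigma_gamma_matrix(self) -> np.ndarray:
        return np.column_stack(
            [
                self.table[f"sigma_gamma.{n}"].to_numpy(float)
                for n in self.exposure_names
            ]
        )

    def sorted_by_variant(self) -> "HarmonizedSet":
        """Canonical row order (lexicographic variant_id)."""
        tab = self.table.sort_values("variant_id", kind="mergesort").reset_index(
            drop=True
        )
        return HarmonizedSet(
            list(self.exposure_names),
            tab,
            list(self.dropped_palindromes),
            list(self.dropped_mismatch),
        )

    def subset(self, variant_ids: Iterable[str]) -> "HarmonizedSet":
        keep = set(variant_ids)
        tab = self.table[self.table["variant_id"].isin(keep)].reset_index(drop=True)
        return HarmonizedSet(list(self.exposure_names), tab, [], [])

    @classmethod
    def from_arrays(
        cls,
        gamma,
        sigma_gamma,
        Gamma,
        sigma_Gamma,
        exposure_name: str = "exposure",
        variant_ids: Sequence[str] | None = None,
    ) -> "HarmonizedSet":
        """Build a single-exposure set directly from effect arrays."""
        gamma = np.asarray(gamma, float)
        J = gamma.shape[0]
        if variant_ids is None:
            variant_ids = [f"rs{j + 1:06d}" for j in range(J)]
        tab = pd.DataFrame(
            {
                "variant_id": list(variant_ids),
                f"gamma.{exposure_name}": gamma,
                f"sigma_gamma.{exposure_name}": np.asarray(sigma_gamma, float),
                f"eaf.{exposure_name}": np.nan,
                "Gamma": np.asarray(Gamma, float),
                "sigma_Gamma": np.asarray(sigma_Gamma, float),
                "eaf_outcome": np.nan,
                "flipped": False,
            }
        )
        return cls([exposure_name], tab)

    @classmethod
    def from_matrix(
        cls,
        gamma_matrix,
        sigma_gamma_matrix,
        Gamma,
        sigma_Gamma,
        exposure_names: Sequence[str],
        variant_ids: Sequence[str] | None = None,
    ) -> "HarmonizedSet":
        """Build a multi-exposure (MVMR) set from effect matrices."""
        G = np.asarray(gamma_matrix, float)
        S = np.asarray(sigma_gamma_matrix, float)
        J = G.shape[0]
        if variant_ids is None:
            variant_ids = [f"rs{j + 1:06d}" for j in range(J)]
        data: dict = {"variant_id": list(variant_ids)}
        for k, name in enumerate(exposure_names):
            data[f"gamma.{name}"] = G[:, k]
            data[f"sigma_gamma.{name}"] = S[:, k]
            data[f"eaf.{name}"] = np.nan
        data["Gamma"] = np.asarray(Gamma, float)
        data["sigma_Gamma"] = np.asarray(sigma_Gamma, float)
        data["eaf_outcome"] = np.nan
        data["flipped"] = False
        return cls(list(exposure_names), pd.DataFrame(data))

    def to_tsv(self, path) -> None:
        cols = ["variant_id"]
        for n in self.exposure_names:
            cols += [f"gamma.{n}", f"sigma_gamma.{n}"]
        cols += ["Gamma", "sigma_Gamma", "flipped"]
        self.table[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_level: str | None = None,
) -> SummaryStatsTable:
    """Read a tab-separated summary-statistics file.

    ``column_map`` maps canonical field names (see ``CANONICAL_COLUMNS``)
    to the file's header names; identity for fields not listed. ``eaf``
    may be absent (filled with NaN). Rows failing validation — non-ACGT
    or equal alleles (indels, multi-allelics), ``se <= 0``, p-value
    outside (0, 1], missing beta — are dropped and counted.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    column_map = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon != "eaf":
            raise FormatError(f"{path}: missing mandatory column {src!r} ({canon})")
    df = raw.rename(columns=rename)
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    df = df[CANONICAL_COLUMNS].copy()

    for col in ("position", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["chromosome"] = df["chromosome"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    n0 = len(df)
    ok_alleles = (
        df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    ok_se = df["se"] > 0
    ok_p = (df["pvalue"] > 0) & (df["pvalue"] <= 1)
    ok_beta = df["beta"].notna()
    ok_eaf = df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))
    keep = ok_alleles & ok_se & ok_p & ok_beta & ok_eaf
    dropped = {
        "non_snp_alleles": int((~ok_alleles).sum()),
        "nonpositive_se": int((ok_alleles & ~ok_se.fillna(False)).sum()),
        "bad_pvalue": int((ok_alleles & ok_se.fillna(False) & ~ok_p.fillna(False)).sum()),
    }
    df = df[keep.fillna(False)]
    df = df.drop_duplicates(subset="variant_id", keep="first").reset_index(drop=True)
    n_dropped = n0 - len(df)
    if n_dropped:
        log.info(
            "%s: dropped %d/%d rows at read (%s)", path, n_dropped, n0, dropped
        )
    if df.empty:
        raise EmptyInputError(f"{path}: zero valid rows after validation")
    name = trait_name if trait_name is not None else str(path)
    table = SummaryStatsTable(name, df, trait_level)
    table.n_dropped_at_read = n_dropped  # audit attribute
    return table


# ---------------------------------------------------------------------------
# Palindromic classification
# ---------------------------------------------------------------------------

def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return _COMPLEMENT.get(effect_allele) == other_allele


def classify_palindromic(
    effect_allele: str,
    other_allele: str,
    eaf: float | None,
    ambiguity_window: tuple[float, float] = DEFAULT_AMBIGUITY_WINDOW,
) -> str:
    """Classify an allele pair for strand-ambiguity handling.

    A/T and C/G pairs read the same on both strands, so orientation must
    come from the allele frequency; a frequency inside ``ambiguity_window``
    (or missing) makes the SNP irrecoverably ambiguous.
    """
    if not is_palindromic(effect_allele, other_allele):
        return NOT_PALINDROMIC
    lo, hi = ambiguity_window
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        return PALINDROMIC_AMBIGUOUS
    if lo <= eaf <= hi:
        return PALINDROMIC_AMBIGUOUS
    return PALINDROMIC_INFERABLE


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _align_to_reference(
    ref_ea: str,
    ref_oa: str,
    ref_eaf: float,
    ea: str,
    oa: str,
    eaf: float,
    ambiguity_window: tuple[float, float],
    action: str,
) -> str:
    """Decide how a record aligns to the reference allele pair.

    Returns one of ``"same"``, ``"flip"``, ``"ambiguous"``, ``"palindromic"``
    (drop-all mode), ``"mismatch"``.
    """
    if is_palindromic(ref_ea, ref_oa):
        if {ea, oa} != {ref_ea, ref_oa}:
            return "mismatch"
        if action == "drop":
            return "palindromic"
        ref_cls = classify_palindromic(ref_ea, ref_oa, ref_eaf, ambiguity_window)
        oth_cls = classify_palindromic(ea, oa, eaf, ambiguity_window)
        if PALINDROMIC_AMBIGUOUS in (ref_cls, oth_cls):
            return "ambiguous"
        # For a palindromic pair the allele labels cannot distinguish a
        # swap from a strand flip; the frequency side decides.
        nominal_flip = ea == ref_oa
        eaf_aligned = 1.0 - eaf if nominal_flip else eaf
        if (eaf_aligned - 0.5) * (ref_eaf - 0.5) < 0:
            nominal_flip = not nominal_flip
        return "flip" if nominal_flip else "same"
    # Non-palindromic: direct match, then strand-complement match.
    if {ea, oa} == {ref_ea, ref_oa}:
        return "same" if ea == ref_ea else "flip"
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if {cea, coa} == {ref_ea, ref_oa}:
        return "same" if cea == ref_ea else "flip"
    return "mismatch"


def harmonize(
    exposures: SummaryStatsTable | Sequence[SummaryStatsTable],
    outcome: SummaryStatsTable,
    ambiguity_window: tuple[float, float] = DEFAULT_AMBIGUITY_WINDOW,
    action: str = "infer",
) -> HarmonizedSet:
    """Align exposure (and mediator) effects with outcome effects.

    For every variant shared by all tables the first exposure's allele
    pair is the reference. Records with the same pair are kept as-is;
    swapped pairs have beta negated and EAF complemented (``flipped``);
    strand-complement pairs are complemented then re-compared. Palindromic
    SNPs are oriented by frequency when ``action="infer"`` and the EAF is
    outside ``ambiguity_window`` on both sides, dropped otherwise;
    ``action="drop"`` drops all palindromic SNPs. Variants whose allele
    pairs cannot be reconciled are dropped as mismatches.
    """
    if isinstance(exposures, SummaryStatsTable):
        exposures = [exposures]
    exposures = list(exposures)
    if not exposures:
        raise HarmonizationError("no exposure tables given")
    if action not in ("infer", "drop"):
        raise ValueError(f"unknown harmonization action {action!r}")

    tables = exposures + [outcome]
    indexed = [t.indexed() for t in tables]
    shared = [
        vid
        for vid in exposures[0].records["variant_id"]
        if all(vid in ix.index for ix in indexed[1:])
    ]
    if not shared:
        raise HarmonizationError(
            f"no overlapping variants between {exposures[0].trait_name} "
            f"and {outcome.trait_name}"
        )

    names = [t.trait_name for t in exposures]
    rows = []
    dropped_pal: list[tuple[str, str]] = []
    dropped_mm: list[str] = []
    n_pos_warn = 0

    ref_ix = indexed[0]
    for vid in shared:
        ref = ref_ix.loc[vid]
        row: dict = {"variant_id": vid}
        row[f"gamma.{names[0]}"] = float(ref["beta"])
        row[f"sigma_gamma.{names[0]}"] = float(ref["se"])
        row[f"eaf.{names[0]}"] = float(ref["eaf"])
        drop_reason = None
        flipped_outcome = False

        for t_i, (tab, ix) in enumerate(zip(tables[1:], indexed[1:]), start=1):
            rec = ix.loc[vid]
            if (
                str(rec["chromosome"]) != str(ref["chromosome"])
                or rec["position"] != ref["position"]
            ):
                n_pos_warn += 1
            decision = _align_to_reference(
                ref["effect_allele"],
                ref["other_allele"],
                float(ref["eaf"]),
                rec["effect_allele"],
                rec["other_allele"],
                float(rec["eaf"]),
                ambiguity_window,
                action,
            )
            if decision in ("ambiguous", "palindromic"):
                drop_reason = decision
                break
            if decision == "mismatch":
                drop_reason = "mismatch"
                break
            beta = float(rec["beta"])
            eaf = float(rec["eaf"])
            if decision == "flip":
                beta = -beta
                eaf = 1.0 - eaf
            is_outcome = t_i == len(tables) - 1
            if is_outcome:
                row["Gamma"] = beta
                row["sigma_Gamma"] = float(rec["se"])
                row["eaf_outcome"] = eaf
                flipped_outcome = decision == "flip"
            else:
                nm = names[t_i]
                row[f"gamma.{nm}"] = beta
                row[f"sigma_gamma.{nm}"] = float(rec["se"])
                row[f"eaf.{nm}"] = eaf

        if drop_reason in ("ambiguous", "palindromic"):
            dropped_pal.append((vid, drop_reason))
        elif drop_reason == "mismatch":
            dropped_mm.append(vid)
        else:
            row["flipped"] = flipped_outcome
            rows.append(row)

    if n_pos_warn:
        log.warning(
            "%d variant(s) matched by id but disagree on chromosome/position "
            "(different genome builds?); kept",
            n_pos_warn,
        )

    cols = ["variant_id"]
    for nm in names:
        cols += [f"gamma.{nm}", f"sigma_gamma.{nm}", f"eaf.{nm}"]
    cols += ["Gamma", "sigma_Gamma", "eaf_outcome", "flipped"]
    table = pd.DataFrame(rows, columns=cols)
    if table.empty:
        raise HarmonizationError(
            f"all {len(shared)} shared variants were dropped during harmonization"
        )
    return HarmonizedSet(names, table, dropped_pal, dropped_mm)
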