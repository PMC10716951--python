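"""GWAS summary-statistics IO, allele harmonization and LD clumping.

The module reads per-trait association tables (one row per variant:
alleles, effect-allele frequency, beta, SE, p, N), aligns an exposure
table and an outcome table onto a shared effect-allele convention, and
selects approximately independent instruments by greedy p-value
clumping against a pairwise r² table.

Positions are 1-based and the clumping window is inclusive at both
endpoints (|pos_i - pos_j| <= window_kb * 1000).  A variant pair absent
from the LD input is treated as r² = 0: absence of evidence of
correlation does not discard instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .exceptions import (
    EmptyInstrumentError,
    FormatError,
    HarmonizationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
#: palindromic allele pairs read the same on both strands
PALINDROMIC_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical field -> default column header in a summary-statistics TSV
DEFAULT_DIALECT: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

DROP_REASONS = ("allele_mismatch", "palindromic_ambiguous", "missing_in_outcome", "duplicate")


class InstrumentCriteria(BaseModel):
    """Thresholds for genome-wide instrument selection.

    Defaults follow standard two-sample MR practice: genome-wide
    significance 5e-8 and LD independence r² < 0.001 within a
    10,000 kb window.
    """

    p_threshold: float = Field(default=5e-8, gt=0, lt=1)
    r2_threshold: float = Field(default=0.001, gt=0, lt=1)
    window_kb: int = Field(default=10_000, gt=0)


@dataclass
class SummaryStats:
    """Validated per-variant association records for one trait.

    ``df`` columns: variant_id, chrom, pos, effect_allele, other_allele,
    eaf (NaN when unknown), beta, se, pval, n.  Rows rejected during
    validation are kept in ``rejected`` with a ``reason`` column rather
    than silently dropped.
    """

    df: pd.DataFrame
    trait_label: str = ""
    trait_type: str = "continuous"  # or "binary"
    unit_note: str = ""
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        dup = self.df["variant_id"][self.df["variant_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate variant_id in {self.trait_label or 'table'}: "
                + ", ".join(sorted(set(dup)))
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.df["variant_id"])

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStats":
        keep = set(variant_ids)
        return SummaryStats(
            df=self.df[self.df["variant_id"].isin(keep)].reset_index(drop=True),
            trait_label=self.trait_label,
            trait_type=self.trait_type,
            unit_note=self.unit_note,
        )

    def rename_variants(self, mapping: Mapping[str, str]) -> "SummaryStats":
        """Apply a proxy map (original id -> proxy id) before harmonization."""
        df = self.df.copy()
        df["variant_id"] = df["variant_id"].map(lambda v: mapping.get(v, v))
        return SummaryStats(df, self.trait_label, self.trait_type, self.unit_note)

    def write(self, path: str | Path, dialect: Mapping[str, str] | None = None) -> None:
        cols = dict(DEFAULT_DIALECT)
        if dialect:
            cols.update(dialect)
        out = self.df.rename(columns=cols)[[cols[k] for k in DEFAULT_DIALECT]]
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw table into (valid, rejected-with-reason)."""
    reasons = pd.Series("", index=df.index)

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    flag(~ea.isin(VALID_BASES) | ~oa.isin(VALID_BASES), "invalid allele")
    flag(ea == oa, "identical alleles")
    flag(~(df["se"] > 0), "nonpositive se")
    flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval outside (0,1]")
    flag(~(df["n"] > 0), "nonpositive n")
    flag(~(df["pos"] >= 1), "nonpositive position")
    eaf_bad = df["eaf"].notna() & ~((df["eaf"] >= 0) & (df["eaf"] <= 1))
    flag(eaf_bad, "eaf outside [0,1]")

    bad = reasons != ""
    rejected = df.loc[bad, ["variant_id"]].copy()
    rejected["reason"] = reasons[bad]
    valid = df[~bad].copy()
    valid["effect_allele"] = ea[~bad]
    valid["other_allele"] = oa[~bad]
    return valid.reset_index(drop=True), rejected.reset_index(drop=True)


def read_gwas_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_label: str = "",
    trait_type: str = "continuous",
    unit_note: str = "",
) -> SummaryStats:
    """Read a tab-separated summary-statistics table.

    ``dialect`` maps canonical field names (keys of
    :data:`DEFAULT_DIALECT`) to the column headers actually present in
    the file.  Missing EAF values are encoded as ``NA``.  Rows failing
    validation are collected on ``SummaryStats.rejected``; a missing
    mandatory column raises :class:`FormatError` naming it, duplicated
    variant ids raise :class:`ValidationError` listing them.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"summary-statistics file not found: {path}")
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    raw = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={cols["chrom"]: str})
    missing = [name for name in cols.values() if name not in raw.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s) in {path.name}: {', '.join(missing)}")
    df = raw.rename(columns={v: k for k, v in cols.items()})[list(DEFAULT_DIALECT)]
    df["variant_id"] = df["variant_id"].astype(str)
    valid, rejected = _validate_rows(df)
    if len(rejected):
        logger.info("%s: rejected %d row(s) during validation", path.name, len(rejected))
    return SummaryStats(valid, trait_label or path.stem, trait_type, unit_note, rejected)


# ---------------------------------------------------------------------------
# LD

class PairwiseLD:
    """Sparse pairwise r² lookup; unlisted pairs are r² = 0."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, float(r2))

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if a != b:
            self._r2[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_pairs(cls, df: pd.DataFrame) -> "PairwiseLD":
        ld = cls()
        for a, b, r2 in zip(df["SNP_A"], df["SNP_B"], df["R2"]):
            ld.set(str(a), str(b), float(r2))
        return ld

    @classmethod
    def from_matrix(cls, df: pd.DataFrame) -> "PairwiseLD":
        ld = cls()
        ids = list(df.index)
        mat = df.to_numpy(dtype=float)
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                if mat[i, j] != 0:
                    ld.set(str(a), str(ids[j]), float(mat[i, j]))
        return ld

    def to_pairs_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"])


def read_ld_table(path: str | Path) -> PairwiseLD:
    """Read LD as either a (SNP_A, SNP_B, R2) pair list or a labelled square matrix."""
    head = pd.read_csv(path, sep="\t", nrows=1)
    if {"SNP_A", "SNP_B", "R2"}.issubset(head.columns):
        return PairwiseLD.from_pairs(pd.read_csv(path, sep="\t"))
    return PairwiseLD.from_matrix(pd.read_csv(path, sep="\t", index_col=0))


# ---------------------------------------------------------------------------
# Harmonization

@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to a shared effect allele.

    ``df`` columns: variant_id, gamma, se_gamma (SNP→exposure effect and
    SE), gamma_out, se_gamma_out (SNP→outcome).  ``dropped`` records one
    (variant_id, reason) row per excluded variant.
    """

    df: pd.DataFrame
    exposure_label: str = ""
    outcome_label: str = ""
    outcome_trait_type: str = "binary"
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gamma(self) -> np.ndarray:
        return self.df["gamma"].to_numpy(float)

    @property
    def se_gamma(self) -> np.ndarray:
        return self.df["se_gamma"].to_numpy(float)

    @property
    def gamma_out(self) -> np.ndarray:
        return self.df["gamma_out"].to_numpy(float)

    @property
    def se_gamma_out(self) -> np.ndarray:
        return self.df["se_gamma_out"].to_numpy(float)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.df["variant_id"])

    def drop_variants(self, variant_ids: Iterable[str], reason: str = "excluded") -> "HarmonizedSet":
        gone = set(variant_ids)
        extra = pd.DataFrame({"variant_id": sorted(gone), "reason": reason})
        return HarmonizedSet(
            df=self.df[~self.df["variant_id"].isin(gone)].reset_index(drop=True),
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            outcome_trait_type=self.outcome_trait_type,
            dropped=pd.concat([self.dropped, extra], ignore_index=True),
        )

    def write(self, path: str | Path) -> None:
        out = self.df.rename(
            columns={
                "variant_id": "SNP",
                "gamma": "GAMMA",
                "se_gamma": "SE_GAMMA",
                "gamma_out": "GAMMA_OUT",
                "se_gamma_out": "SE_GAMMA_OUT",
            }
        )
        out.to_csv(path, sep="\t", index=False)
        drop_path = Path(path).with_suffix(".dropped.tsv")
        self.dropped.rename(columns={"variant_id": "SNP", "reason": "REASON"}).to_csv(
            drop_path, sep="\t", index=False
        )


def _is_palindromic(ea: str, oa: str) -> bool:
    return frozenset((ea, oa)) in PALINDROMIC_PAIRS


def orient_alleles(
    ea_ref: str,
    oa_ref: str,
    eaf_ref: float,
    ea: str,
    oa: str,
    eaf: float,
    palindrome_policy: str = "drop_ambiguous",
    eaf_window: float = 0.08,
) -> tuple[int, str]:
    """Resolve the orientation of one record against reference alleles.

    Returns ``(sign, reason)``: sign +1 (same orientation), -1 (flip
    beta and complement EAF) or 0 with a drop reason.  Non-palindromic
    records are matched directly, after swap, or after strand
    complement; palindromic records are resolved per policy using the
    effect-allele frequencies, with ``eaf_window`` defining the
    ambiguity zone around 0.5.
    """
    if _is_palindromic(ea_ref, oa_ref):
        if frozenset((ea, oa)) != frozenset((ea_ref, oa_ref)):
            return 0, "allele_mismatch"
        if palindrome_policy == "drop_ambiguous":
            if np.isnan(eaf_ref) or abs(eaf_ref - 0.5) <= eaf_window:
                return 0, "palindromic_ambiguous"
            # alleles are taken at face value: reported letters decide
            return (1, "") if ea == ea_ref else (-1, "")
        if palindrome_policy == "infer_by_eaf":
            if (
                np.isnan(eaf_ref)
                or np.isnan(eaf)
                or abs(eaf_ref - 0.5) <= eaf_window
                or abs(eaf - 0.5) <= eaf_window
            ):
                return 0, "palindromic_ambiguous"
            same_side = (eaf_ref < 0.5) == (eaf < 0.5)
            return (1, "") if same_side else (-1, "")
        raise ValidationError(f"unknown palindrome_policy {palindrome_policy!r}")

    if (ea, oa) == (ea_ref, oa_ref):
        return 1, ""
    if (ea, oa) == (oa_ref, ea_ref):
        return -1, ""
    # strand flip: unambiguous for non-palindromic alleles
    ea_c, oa_c = COMPLEMENT[ea], COMPLEMENT[oa]
    if (ea_c, oa_c) == (ea_ref, oa_ref):
        return 1, ""
    if (ea_c, oa_c) == (oa_ref, ea_ref):
        return -1, ""
    return 0, "allele_mismatch"


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_policy: str = "drop_ambiguous",
    eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect-allele convention.

    For each variant present in both tables, the outcome beta sign is
    flipped (and EAF complemented) when the outcome's allele coding is
    reversed relative to the exposure.  Irreconcilable alleles and
    unresolvable palindromic variants are dropped with a reason, never
    raised; an empty intersection raises :class:`HarmonizationError`.
    """
    if not 0 < eaf_window < 0.5:
        raise ValidationError("eaf_window must lie in (0, 0.5)")
    if palindrome_policy not in ("drop_ambiguous", "infer_by_eaf"):
        raise ValidationError(f"unknown palindrome_policy {palindrome_policy!r}")
    merged = exposure.df.merge(
        outcome.df, on="variant_id", how="left", suffixes=("_exp", "_out")
    )
    present = merged["effect_allele_out"].notna()
    if not present.any():
        raise HarmonizationError(
            f"no shared variants between {exposure.trait_label!r} and {outcome.trait_label!r}"
        )
    dropped = [
        (vid, "missing_in_outcome") for vid in merged.loc[~present, "variant_id"]
    ]
    m = merged[present]
    ea_e, oa_e = m["effect_allele_exp"].to_numpy(), m["other_allele_exp"].to_numpy()
    ea_o, oa_o = m["effect_allele_out"].to_numpy(), m["other_allele_out"].to_numpy()
    eaf_e, eaf_o = m["eaf_exp"].to_numpy(float), m["eaf_out"].to_numpy(float)
    comp = np.vectorize(COMPLEMENT.get)
    ea_oc, oa_oc = comp(ea_o), comp(oa_o)

    palin = (ea_e == comp(oa_e))  # A/T or C/G reference pair
    direct = ((ea_o == ea_e) & (oa_o == oa_e)) | ((ea_oc == ea_e) & (oa_oc == oa_e))
    swapped = ((ea_o == oa_e) & (oa_o == ea_e)) | ((ea_oc == oa_e) & (oa_oc == ea_e))

    sign = np.zeros(len(m))
    reason = np.full(len(m), "allele_mismatch", dtype=object)

    # non-palindromic: reported or strand-complemented letters decide
    sign[~palin & direct] = 1.0
    sign[~palin & swapped] = -1.0

    # palindromic: letters always "match" under a strand flip, so the
    # effect-allele frequency has to resolve the orientation
    set_match = palin & (direct | swapped)
    e_informative = ~np.isnan(eaf_e) & (np.abs(eaf_e - 0.5) > eaf_window)
    o_informative = ~np.isnan(eaf_o) & (np.abs(eaf_o - 0.5) > eaf_window)
    if palindrome_policy == "drop_ambiguous":
        ok = set_match & e_informative
        sign[ok] = np.where(ea_o[ok] == ea_e[ok], 1.0, -1.0)
    else:  # infer_by_eaf: minor-allele side agreement across the tables
        ok = set_match & e_informative & o_informative
        sign[ok] = np.where((eaf_e[ok] < 0.5) == (eaf_o[ok] < 0.5), 1.0, -1.0)
    reason[palin & (sign == 0) & (direct | swapped)] = "palindromic_ambiguous"

    kept = sign != 0
    dropped += list(zip(m.loc[~kept, "variant_id"], reason[~kept]))
    if not kept.any():
        raise HarmonizationError(
            f"all {int(present.sum())} shared variants dropped during harmonization"
        )
    df = pd.DataFrame(
        {
            "variant_id": m.loc[kept, "variant_id"].to_numpy(),
            "gamma": m.loc[kept, "beta_exp"].to_numpy(float),
            "se_gamma": m.loc[kept, "se_exp"].to_numpy(float),
            "gamma_out": sign[kept] * m.loc[kept, "beta_out"].to_numpy(float),
            "se_gamma_out": m.loc[kept, "se_out"].to_numpy(float),
        }
    )
    return HarmonizedSet(
        df=df,
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        outcome_trait_type=outcome.trait_type,
        dropped=pd.DataFrame(dropped, columns=["variant_id", "reason"]),
    )


# ---------------------------------------------------------------------------
# Clumping / instrument selection

def clump(
    stats: SummaryStats,
    ld: PairwiseLD | None,
    criteria: InstrumentCriteria | None = None,
) -> list[str]:
    """Greedy LD clumping by ascending p-value.

    A variant is accepted iff its r² with every already-accepted
    variant on the same chromosome within ``window_kb`` is below
    ``r2_threshold``.  Ties on p break lexicographically on variant id
    for determinism.  Empty input returns an empty list.
    """
    criteria = criteria or InstrumentCriteria()
    ld = ld or PairwiseLD()
    df = stats.df
    if df.empty:
        return []
    order = df.sort_values(["pval", "variant_id"], kind="mergesort")
    window = criteria.window_kb * 1000
    accepted: list[tuple[str, str, int]] = []  # (id, chrom, pos)
    for vid, chrom, pos in zip(order["variant_id"], order["chrom"], order["pos"]):
        ok = all(
            not (c == chrom and abs(pos - p) <= window and ld.r2(vid, a) >= criteria.r2_threshold)
            for a, c, p in accepted
        )
        if ok:
            accepted.append((vid, chrom, int(pos)))
    return [a for a, _, _ in accepted]


def select_instruments(
    stats: SummaryStats,
    ld: PairwiseLD | None = None,
    criteria: InstrumentCriteria | None = None,
    restrict_to: Sequence[str] | None = None,
) -> SummaryStats:
    """Significance filter, optional id restriction, then LD clumping.

    Raises :class:`EmptyInstrumentError` naming the trait when no
    variant passes the p-value threshold (after restriction).
    """
    criteria = criteria or InstrumentCriteria()
    df = stats.df[stats.df["pval"] < criteria.p_threshold]
    if restrict_to is not None:
        df = df[df["variant_id"].isin(set(restrict_to))]
    if df.empty:
        raise EmptyInstrumentError(
            f"no instrument passes p < {criteria.p_threshold:g} for trait "
            f"{stats.trait_label!r}"
        )
    filtered = SummaryStats(
        df.reset_index(drop=True), stats.trait_label, stats.trait_type, stats.unit_note
    )
    kept = clump(filtered, ld, criteria)
    return filtered.subset(kept)
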