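"""Reading, filtering and allele-harmonising GWAS summary statistics.

Two per-disease association tables (log-odds beta, its standard error, the
association P value, effect-allele frequency and imputation quality per
variant) are brought onto a single shared effect allele so that downstream
heterogeneity statistics compare like with like.  Coordinates are 1-based
inclusive; chromosome labels are normalised by stripping a leading ``chr``.

Canonical column names used throughout the package::

    variant_id chrom pos effect_allele other_allele eaf beta se p info

Harmonised tables carry per-disease suffixes ``_a`` / ``_b`` on the
statistical columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)

#: canonical field -> default source column name
DEFAULT_DIALECT = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "NEA",
    "eaf": "EAF",
    "or": "OR",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "info": "INFO",
}

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "info",
]

STAT_COLUMNS = ["beta", "se", "p", "eaf", "info"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: GRCh37 MHC bounds (closed interval), chr6
MHC_REGION = ("6", 25_000_000, 34_000_000)


def _revcomp(allele: str) -> str | None:
    """Reverse complement of a SNP allele; None for indels/unknown bases."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele))
    except KeyError:
        return None


def _is_palindromic(ea: str, oa: str) -> bool:
    return (ea, oa) in {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _normalize_chrom(series: pd.Series) -> pd.Series:
    return series.astype(str).str.replace(r"^chr", "", regex=True)


@dataclass
class FilterReport:
    """Counts of variants removed by each filtering criterion."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict[str, int] = field(default_factory=dict)


def read_sumstats(path, dialect: dict | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a summary-statistics table into canonical form.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with a header row.
    dialect
        Mapping from canonical field names (keys of :data:`DEFAULT_DIALECT`)
        to the source file's column names.  Only overrides need be given.
        Either an odds-ratio column (``or``) or a log-odds column (``beta``)
        must resolve; odds ratios are converted with the natural log.
    sep
        Field separator; ``None`` sniffs tab vs comma from the header line.

    Returns
    -------
    DataFrame with :data:`CANONICAL_COLUMNS`.  Rows whose mandatory fields do
    not parse (or violate basic domain constraints such as ``se <= 0``) are
    dropped and counted in the log.

    Raises
    ------
    DataError
        If a mandatory column is absent (the message names it) or no row
        parses.
    """
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)

    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    raw.columns = [c.strip() for c in raw.columns]

    has_beta = dia["beta"] in raw.columns
    has_or = dia["or"] in raw.columns
    if not (has_beta or has_or):
        raise DataError(
            f"missing effect column: neither {dia['beta']!r} nor {dia['or']!r} present"
        )
    mandatory = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "eaf", "se", "p", "info"]
    for field_name in mandatory:
        if dia[field_name] not in raw.columns:
            raise DataError(f"missing mandatory column {dia[field_name]!r} "
                            f"(canonical field {field_name!r})")

    df = pd.DataFrame({
        "variant_id": raw[dia["variant_id"]].astype(str),
        "chrom": _normalize_chrom(raw[dia["chrom"]]),
        "pos": pd.to_numeric(raw[dia["pos"]], errors="coerce"),
        "effect_allele": raw[dia["effect_allele"]].astype(str).str.upper(),
        "other_allele": raw[dia["other_allele"]].astype(str).str.upper(),
        "eaf": pd.to_numeric(raw[dia["eaf"]], errors="coerce"),
        "se": pd.to_numeric(raw[dia["se"]], errors="coerce"),
        "p": pd.to_numeric(raw[dia["p"]], errors="coerce"),
        "info": pd.to_numeric(raw[dia["info"]], errors="coerce"),
    })
    if has_beta:
        df["beta"] = pd.to_numeric(raw[dia["beta"]], errors="coerce")
    else:
        odds = pd.to_numeric(raw[dia["or"]], errors="coerce")
        odds[odds <= 0] = np.nan
        df["beta"] = np.log(odds)

    ok = (
        df[["pos", "eaf", "beta", "se", "p", "info"]].notna().all(axis=1)
        & (df["se"] > 0)
        & (df["p"] > 0) & (df["p"] <= 1)
        & (df["eaf"] >= 0) & (df["eaf"] <= 1)
        & (df["info"] >= 0) & (df["info"] <= 1)
        & (df["effect_allele"] != df["other_allele"])
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("read_sumstats(%s): dropped %d unparseable/invalid rows", path, n_dropped)
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise DataError(f"no parsable rows in {path}")
    df["pos"] = df["pos"].astype(np.int64)
    return df[CANONICAL_COLUMNS]


def write_sumstats(df: pd.DataFrame, path, dialect: dict | None = None) -> None:
    """Write a canonical table back to TSV under a column-name dialect."""
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    out = df[CANONICAL_COLUMNS].copy()
    out.columns = [dia.get(c, c) if c != "beta" else dia["beta"] for c in out.columns]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def filter_variants(df: pd.DataFrame, maf_min: float = 0.005,
                    info_min: float = 0.5) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the MAF and imputation-quality filters.

    Retains rows with ``min(eaf, 1-eaf) >= maf_min`` and ``info >= info_min``
    (both thresholds inclusive, applied uniformly).
    """
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    pass_maf = maf >= maf_min
    pass_info = df["info"] >= info_min
    keep = pass_maf & pass_info
    report = FilterReport(
        n_input=len(df),
        n_retained=int(keep.sum()),
        removed={
            "maf": int((~pass_maf).sum()),
            "info": int((~pass_info).sum()),
            "either": int((~keep).sum()),
        },
    )
    if report.n_retained == 0:
        log.warning("filter_variants: no variants retained "
                    "(maf_min=%g, info_min=%g)", maf_min, info_min)
    return df[keep].reset_index(drop=True), report


def _merge_key(df: pd.DataFrame) -> pd.Series:
    alleles = np.sort(df[["effect_allele", "other_allele"]].to_numpy(), axis=1)
    return (df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + alleles[:, 0] + ":" + alleles[:, 1])


def harmonize(table_a: pd.DataFrame, table_b: pd.DataFrame,
              palindrome_eaf_band: tuple[float, float] = (0.4, 0.6),
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align two diseases' statistics onto disease A's effect allele.

    Matching is on ``variant_id``; if the two tables share no ids at all the
    positional key ``chrom:pos:sorted-alleles`` is used instead.  For each
    shared variant the allele pair of table B is compared with table A's:

    * identical -> statistics kept as-is;
    * effect/other swapped -> B's beta negated, B's eaf complemented;
    * strand flip (reverse complement), same or swapped orientation ->
      resolved the same way;
    * anything else -> dropped (``allele_mismatch``).

    Palindromic variants (A/T or C/G) whose eaf falls inside
    ``palindrome_eaf_band`` in either study are dropped as strand-ambiguous.

    Returns the harmonised table (suffixes ``_a``/``_b`` on beta, se, p, eaf,
    info) and a drop log with columns ``variant_id, reason``.

    Raises
    ------
    DataError
        On duplicate variant ids within a table (the message lists them).
    """
    for name, tab in (("A", table_a), ("B", table_b)):
        dup = tab["variant_id"][tab["variant_id"].duplicated()]
        if len(dup):
            raise DataError(f"duplicate variant ids in table {name}: "
                            + ", ".join(sorted(set(dup))[:10]))

    a = table_a.copy()
    b = table_b.copy()
    if not set(a["variant_id"]) & set(b["variant_id"]):
        a["_key"] = _merge_key(a)
        b["_key"] = _merge_key(b)
        key = "_key"
    else:
        key = "variant_id"
    merged = a.merge(b, on=key, suffixes=("_a", "_b"), how="inner")
    if key == "_key":
        merged = merged.drop(columns="_key").rename(
            columns={"variant_id_a": "variant_id"}).drop(columns="variant_id_b")

    ea_a = merged["effect_allele_a"].to_numpy()
    oa_a = merged["other_allele_a"].to_numpy()
    ea_b = merged["effect_allele_b"].to_numpy()
    oa_b = merged["other_allele_b"].to_numpy()

    rc_ea_b = np.array([_revcomp(x) or "?" for x in ea_b])
    rc_oa_b = np.array([_revcomp(x) or "?" for x in oa_b])

    same = (ea_b == ea_a) & (oa_b == oa_a)
    swapped = (ea_b == oa_a) & (oa_b == ea_a)
    flipped = (rc_ea_b == ea_a) & (rc_oa_b == oa_a) & ~same & ~swapped
    flipped_swapped = (rc_ea_b == oa_a) & (rc_oa_b == ea_a) & ~same & ~swapped

    palin = np.array([_is_palindromic(e, o) for e, o in zip(ea_a, oa_a)])
    lo, hi = palindrome_eaf_band
    ambiguous = palin & (
        ((merged["eaf_a"] >= lo) & (merged["eaf_a"] <= hi))
        | ((merged["eaf_b"] >= lo) & (merged["eaf_b"] <= hi))
    ).to_numpy()
    compatible = same | swapped | flipped | flipped_swapped
    keep = compatible & ~ambiguous

    drops = []
    for mask, reason in ((~compatible, "allele_mismatch"),
                         (compatible & ambiguous, "ambiguous_palindrome")):
        for vid in merged.loc[mask, "variant_id"]:
            drops.append((vid, reason))
    drop_log = pd.DataFrame(drops, columns=["variant_id", "reason"])

    out = merged[keep].copy()
    negate = (swapped | flipped_swapped)[keep]
    out.loc[negate, "beta_b"] = -out.loc[negate, "beta_b"]
    out.loc[negate, "eaf_b"] = 1.0 - out.loc[negate, "eaf_b"]

    out = out.rename(columns={
        "chrom_a": "chrom", "pos_a": "pos",
        "effect_allele_a": "effect_allele", "other_allele_a": "other_allele",
    })
    cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    cols += [f"{c}_a" for c in STAT_COLUMNS] + [f"{c}_b" for c in STAT_COLUMNS]
    out = out[cols].reset_index(drop=True)
    if len(drop_log):
        log.info("harmonize: dropped %d variants (%s)", len(drop_log),
                 drop_log["reason"].value_counts().to_dict())
    return out, drop_log


def split_harmonized(harm: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a harmonised table back into two canonical per-disease tables."""
    out = []
    for suffix in ("_a", "_b"):
        tab = harm[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
        for c in STAT_COLUMNS:
            tab[c] = harm[f"{c}{suffix}"].to_numpy()
        out.append(tab[CANONICAL_COLUMNS])
    return out[0], out[1]


def exclude_mhc(df: pd.DataFrame,
                region: tuple[str, int, int] = MHC_REGION) -> tuple[pd.DataFrame, int]:
    """Remove variants inside the MHC (closed interval; default GRCh37 chr6:25-34 Mb)."""
    chrom, start, end = region
    inside = ((df["chrom"].astype(str) == str(chrom))
              & (df["pos"] >= start) & (df["pos"] <= end))
    n_removed = int(inside.sum())
    if n_removed:
        log.info("exclude_mhc: removed %d variants in %s:%d-%d",
                 n_removed, chrom, start, end)
    return df[~inside].reset_index(drop=True), n_removed
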