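"""The disease-specificity statistic S and top-1% variant prioritisation.

For variant i in disease j,

    S_ij = |beta_ij / se_ij| * Z_i

where Z_i is the one-sided normal transform of the variant's Cochran's Q
P value between the two diseases.  S is large only when the variant is
strongly associated in disease j AND its effects differ between diseases;
a near-zero t-statistic or heterogeneity z keeps S small.  S is a
prioritisation score, not a test statistic: its null distribution depends on
allele frequencies and the two studies' sample sizes, so no parametric P is
ever attached to it.

Each variant gets two S values; it is assigned to the disease with the larger
one, variants are ranked per disease, and the top 1% of the pruned universe
per disease (plus their LD proxies) form the disease-specific SNP sets used
in every downstream enrichment.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import DataError
from .ld import GenotypePanel, ProxySet, expand_proxies, prune

log = logging.getLogger(__name__)


def specificity_s(beta, se, z_het):
    """S = |beta/se| * z_het. Vectorised; raises on non-positive se."""
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DataError("standard errors must be positive")
    return np.abs(np.asarray(beta, dtype=float) / se) * np.asarray(z_het, dtype=float)


def assign_and_rank(table: pd.DataFrame, top_fraction: float = 0.01) -> pd.DataFrame:
    """Score, assign, rank and flag the top disease-specific variants.

    Parameters
    ----------
    table
        One row per LD-pruned, non-MHC variant with columns
        ``variant_id, chrom, pos, beta_a, se_a, p_a, beta_b, se_b, p_b,
        q, p_q, z_het`` (the heterogeneity columns as produced by
        :func:`gwaspec.meta.meta_table`).
    top_fraction
        Per-disease quota as a fraction of the whole pruned universe; the
        quota is ``ceil(top_fraction * len(table))``.

    Returns
    -------
    The input plus ``t_a, t_b, s_a, s_b, assigned, rank, percentile,
    top1pct``.  Assignment is argmax of (s_a, s_b) with ties going to the
    disease with the smaller association P.  Within each assigned-disease
    subset, rank 1 is the most specific (ties: larger |t|, then chrom, pos);
    ``percentile = rank / subset size``.  Records with s <= 0 are never
    promoted into the top list even if a disease falls short of its quota
    (the list is truncated with a warning).
    """
    if table.empty:
        raise DataError("assign_and_rank: empty input table")
    out = table.copy().reset_index(drop=True)
    out["t_a"] = out["beta_a"] / out["se_a"]
    out["t_b"] = out["beta_b"] / out["se_b"]
    out["s_a"] = specificity_s(out["beta_a"], out["se_a"], out["z_het"])
    out["s_b"] = specificity_s(out["beta_b"], out["se_b"], out["z_het"])

    a_wins = (out["s_a"] > out["s_b"]) | (
        (out["s_a"] == out["s_b"]) & (out["p_a"] <= out["p_b"]))
    out["assigned"] = np.where(a_wins, "A", "B")
    out["s_assigned"] = np.where(a_wins, out["s_a"], out["s_b"])
    t_assigned = np.abs(np.where(a_wins, out["t_a"], out["t_b"]))

    if (out["z_het"] <= 0).all():
        log.warning("assign_and_rank: no positive heterogeneity anywhere; "
                    "all S <= 0 — top lists will be empty or truncated")

    quota = math.ceil(top_fraction * len(out))
    out["rank"] = 0
    out["percentile"] = np.nan
    out["top1pct"] = False
    for disease in ("A", "B"):
        mask = out["assigned"] == disease
        sub = out[mask]
        order = np.lexsort((sub["pos"].to_numpy(), sub["chrom"].to_numpy(),
                            -t_assigned[mask.to_numpy()],
                            -sub["s_assigned"].to_numpy()))
        ranks = np.empty(len(sub), dtype=int)
        ranks[order] = np.arange(1, len(sub) + 1)
        out.loc[mask, "rank"] = ranks
        out.loc[mask, "percentile"] = ranks / len(sub)
        top = mask & (out["rank"] <= quota) & (out["s_assigned"] > 0)
        n_top = int(top.sum())
        if n_top < min(quota, int(mask.sum())):
            log.warning("assign_and_rank: disease %s top list truncated to %d "
                        "of quota %d (non-positive S)", disease, n_top, quota)
        out.loc[top, "top1pct"] = True
    return out


def top_variants(ranked: pd.DataFrame, disease: str) -> pd.DataFrame:
    """The top-1% rows assigned to one disease ('A' or 'B'), best first."""
    sub = ranked[(ranked["assigned"] == disease) & ranked["top1pct"]]
    return sub.sort_values("rank").reset_index(drop=True)


def build_disease_specific_sets(ranked: pd.DataFrame, panel: GenotypePanel,
                                r2_min: float = 0.8, window_bp: int = 1_000_000,
                                ) -> dict[str, tuple[set[str], list[ProxySet]]]:
    """Per-disease flat SNP sets: top-1% index variants plus their r2>0.8 proxies.

    Returns ``{"A": (flat_set, proxy_sets), "B": ...}``.  A disease with no
    top variants yields an empty set (with a warning).
    """
    out = {}
    for disease in ("A", "B"):
        idx = list(top_variants(ranked, disease)["variant_id"])
        if not idx:
            log.warning("build_disease_specific_sets: no top variants for "
                        "disease %s", disease)
            out[disease] = (set(), [])
            continue
        sets, flat = expand_proxies(panel, idx, r2_min=r2_min, window_bp=window_bp)
        log.info("disease %s: %d index variants -> %d SNPs with proxies",
                 disease, len(idx), len(flat))
        out[disease] = (flat, sets)
    return out


def export_depict_input(ranked: pd.DataFrame, panel: GenotypePanel,
                        meta: pd.DataFrame, p_meta_max: float = 0.05,
                        r2_max: float = 0.2, window_bp: int = 2_000_000,
                        ) -> dict[str, pd.DataFrame]:
    """Gene-set-analysis input: top variants with meta P < 0.05, pruned at r2 < 0.2.

    Per disease, the top-1% variants are intersected with ``meta`` (needs
    ``variant_id, p_meta``), filtered to ``p_meta < p_meta_max``, pruned
    greedily with priority = S, and emitted as a two-column frame
    ``(variant_id, p)`` where ``p`` is the percentile rank (in (0, 1]) acting
    as a pseudo P value.
    """
    p_meta = meta.set_index("variant_id")["p_meta"]
    out = {}
    for disease in ("A", "B"):
        top = top_variants(ranked, disease)
        top = top[top["variant_id"].map(p_meta).lt(p_meta_max).fillna(False).to_numpy()]
        if top.empty:
            out[disease] = pd.DataFrame(columns=["variant_id", "p"])
            continue
        pruned = prune(panel,
                       top.rename(columns={"s_assigned": "priority"})[
                           ["variant_id", "priority"]],
                       r2_max=r2_max, window_bp=window_bp)
        keep = top[top["variant_id"].isin(pruned)]
        out[disease] = keep[["variant_id", "percentile"]].rename(
            columns={"percentile": "p"}).reset_index(drop=True)
    return out
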