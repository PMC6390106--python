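"""Fixed-effects meta-analysis and Cochran's Q heterogeneity for two studies.

For a variant with per-disease log-odds estimates (beta_a, se_a) and
(beta_b, se_b), the inverse-variance-weighted (IVW) fixed-effects combination
is

    w_j = 1 / se_j**2
    beta_fe = (w_a beta_a + w_b beta_b) / (w_a + w_b)
    se_fe = 1 / sqrt(w_a + w_b)

and Cochran's Q = sum_j w_j (beta_j - beta_fe)**2, which for two studies
collapses to (beta_a - beta_b)**2 / (se_a**2 + se_b**2), chi-square with 1
degree of freedom under homogeneity.  The heterogeneity z-score used by the
disease-specificity statistic is the one-sided normal transform
z_het = Phi^-1(1 - p_q): zero at p_q = 0.5, large and positive for strong
heterogeneity, negative when the two effects agree more than chance expects.

All functions are vectorised over numpy arrays and also accept scalars.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

# p_q clamp bounds: avoid infinite z while preserving ranking
_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


def _check_se(*ses) -> None:
    for se in ses:
        if np.any(np.asarray(se) <= 0):
            raise DataError("standard errors must be positive")


def fixed_effects_meta(beta_a, se_a, beta_b, se_b) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effects combination of two estimates.

    Returns a DataFrame with columns ``beta_fe, se_fe, z_fe, p_meta``
    (two-sided P from the standard-normal deviate z_fe = beta_fe / se_fe).
    """
    _check_se(se_a, se_b)
    beta_a, se_a, beta_b, se_b = np.broadcast_arrays(
        np.atleast_1d(np.asarray(beta_a, dtype=float)),
        np.atleast_1d(np.asarray(se_a, dtype=float)),
        np.atleast_1d(np.asarray(beta_b, dtype=float)),
        np.atleast_1d(np.asarray(se_b, dtype=float)),
    )
    w_a = 1.0 / se_a**2
    w_b = 1.0 / se_b**2
    beta_fe = (w_a * beta_a + w_b * beta_b) / (w_a + w_b)
    se_fe = 1.0 / np.sqrt(w_a + w_b)
    z_fe = beta_fe / se_fe
    p_meta = 2.0 * stats.norm.sf(np.abs(z_fe))
    return pd.DataFrame({"beta_fe": beta_fe, "se_fe": se_fe,
                         "z_fe": z_fe, "p_meta": p_meta})


def het_z(p_q) -> np.ndarray:
    """One-sided normal transform of the Q-test P value.

    z_het = Phi^-1(1 - p_q), computed as ``norm.isf(p_q)`` after clamping
    p_q into [1e-300, 1 - 1e-16] so the result is always finite.  p_q = 0.5
    maps to 0; p_q > 0.5 gives a negative z.
    """
    p = np.clip(np.asarray(p_q, dtype=float), _P_FLOOR, _P_CEIL)
    return stats.norm.isf(p)


def cochran_q(beta_a, se_a, beta_b, se_b) -> pd.DataFrame:
    """Cochran's Q heterogeneity test for two studies.

    Returns a DataFrame with columns ``q`` (the statistic, >= 0), ``df``
    (always 1 for two studies), ``p_q`` (upper-tail chi-square P) and
    ``z_het`` (see :func:`het_z`).
    """
    _check_se(se_a, se_b)
    beta_a, se_a, beta_b, se_b = np.broadcast_arrays(
        np.atleast_1d(np.asarray(beta_a, dtype=float)),
        np.atleast_1d(np.asarray(se_a, dtype=float)),
        np.atleast_1d(np.asarray(beta_b, dtype=float)),
        np.atleast_1d(np.asarray(se_b, dtype=float)),
    )
    q = (beta_a - beta_b) ** 2 / (se_a**2 + se_b**2)
    p_q = stats.chi2.sf(q, df=1)
    return pd.DataFrame({"q": q, "df": np.ones_like(q, dtype=int),
                         "p_q": p_q, "z_het": het_z(p_q)})


def cochran_q_summation(betas: np.ndarray, ses: np.ndarray) -> np.ndarray:
    """General k-study Q via the summation form sum_j w_j (beta_j - beta_fe)^2.

    ``betas`` and ``ses`` have one column per study.  Kept as the reference
    form; for two studies it equals the closed form used by
    :func:`cochran_q`.
    """
    _check_se(ses)
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    b = np.asarray(betas, dtype=float)
    beta_fe = (w * b).sum(axis=-1) / w.sum(axis=-1)
    return (w * (b - beta_fe[..., None]) ** 2).sum(axis=-1)


def meta_table(harm: pd.DataFrame) -> pd.DataFrame:
    """Per-variant meta + heterogeneity table from a harmonised table.

    Output columns: ``variant_id, chrom, pos, beta_fe, se_fe, z_fe, p_meta,
    q, p_q, z_het``.
    """
    fe = fixed_effects_meta(harm["beta_a"], harm["se_a"],
                            harm["beta_b"], harm["se_b"])
    het = cochran_q(harm["beta_a"], harm["se_a"],
                    harm["beta_b"], harm["se_b"])
    out = harm[["variant_id", "chrom", "pos"]].reset_index(drop=True)
    return pd.concat([out, fe, het[["q", "p_q", "z_het"]]], axis=1)


def select_cross_disease_loci(table: pd.DataFrame, gws_p: float = 5e-8,
                              merge_bp: int = 500_000) -> pd.DataFrame:
    """Loci genome-wide significant in the meta-analysis but in neither disease.

    ``table`` needs ``variant_id, chrom, pos, p_a, p_b, p_meta``.  Qualifying
    variants (p_meta < gws_p, p_a >= gws_p, p_b >= gws_p) within ``merge_bp``
    of each other on one chromosome are merged into a single locus, reported
    by its smallest-p_meta variant.

    Returns one row per locus: lead variant's columns plus ``n_variants,
    locus_start, locus_end``.
    """
    hits = table[(table["p_meta"] < gws_p)
                 & (table["p_a"] >= gws_p)
                 & (table["p_b"] >= gws_p)].copy()
    if hits.empty:
        return hits.assign(n_variants=pd.Series(dtype=int),
                           locus_start=pd.Series(dtype=int),
                           locus_end=pd.Series(dtype=int))
    hits = hits.sort_values(["chrom", "pos"]).reset_index(drop=True)
    new_locus = (hits["chrom"] != hits["chrom"].shift()) | \
                (hits["pos"] - hits["pos"].shift() > merge_bp)
    locus_id = new_locus.cumsum()
    rows = []
    for _, grp in hits.groupby(locus_id):
        lead = grp.loc[grp["p_meta"].idxmin()].copy()
        lead["n_variants"] = len(grp)
        lead["locus_start"] = int(grp["pos"].min())
        lead["locus_end"] = int(grp["pos"].max())
        rows.append(lead)
    return pd.DataFrame(rows).reset_index(drop=True)
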