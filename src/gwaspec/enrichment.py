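"""Permutation enrichment of SNP sets in cell-/organ-type regulatory intervals.

An enhancer-by-cell-type binary activity matrix is built from one BED file
per cell type (enhancer identity = the exact coordinate triple).  The
observed statistic for a (SNP set, cell type) pair counts the DISTINCT
enhancers active in that cell type that contain at least one SNP of the set.

The null model shuffles the annotation matrix, never the SNPs, so the LD
among the query SNPs is preserved by construction.  The default shuffle is a
joint row permutation — the mapping from genomic intervals to activity
profiles is permuted — which conserves both the number of enhancers per cell
type (column sums) and the number of cell types per enhancer (row sums).  An
independent per-column shuffle (conserving column sums only) is available as
an option.  The permutation P is add-one, p = (b + 1) / (n_perm + 1), so it
is never zero; with 10,000 replicates the floor is ~1e-4.

Coordinates: intervals are half-open 0-based [start, end); SNP positions are
1-based, so containment is start < pos <= end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)


@dataclass
class AnnotationMatrix:
    """Enhancer intervals plus a binary enhancer-by-cell-type activity matrix."""

    intervals: pd.DataFrame          # chrom, start, end (half-open 0-based)
    cell_types: list[str]
    matrix: np.ndarray               # (n_enhancers, n_cell_types) bool
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.intervals["end"] <= self.intervals["start"]).any():
            raise DataError("degenerate interval (end <= start) in annotation")
        if self.matrix.shape != (len(self.intervals), len(self.cell_types)):
            raise DataError("activity matrix shape mismatch")
        self.matrix = self.matrix.astype(bool)

    @property
    def n_enhancers(self) -> int:
        return len(self.intervals)

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def _read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: malformed BED line "
                                f"(need >= 3 tab-separated fields)")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer BED coordinates")
            if end <= start:
                raise DataError(f"{path}:{lineno}: degenerate interval")
            rows.append((str(parts[0]).removeprefix("chr"), start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def build_annotation_matrix(beds: dict[str, object],
                            categories: dict[str, str] | None = None,
                            ) -> AnnotationMatrix:
    """Build the binary activity matrix from per-cell-type interval sets.

    Parameters
    ----------
    beds
        Mapping cell-type name -> BED file path, or -> in-memory DataFrame
        with columns ``chrom, start, end``.  The union of all distinct
        (chrom, start, end) triples forms the enhancer list; matrix cell
        (e, c) is 1 iff enhancer e appears in cell type c's intervals.
    categories
        Optional cell-type -> category label (e.g. hematopoietic / organ).
    """
    per_type = {}
    for name, src in beds.items():
        df = src if isinstance(src, pd.DataFrame) else _read_bed(src)
        per_type[name] = set(map(tuple, df[["chrom", "start", "end"]]
                                 .itertuples(index=False, name=None)
                                 )) if len(df) else set()
    all_intervals = sorted(set().union(*per_type.values())) if per_type else []
    intervals = pd.DataFrame(all_intervals, columns=["chrom", "start", "end"])
    cell_types = list(beds)
    matrix = np.zeros((len(intervals), len(cell_types)), dtype=bool)
    index = {iv: i for i, iv in enumerate(all_intervals)}
    for c, name in enumerate(cell_types):
        for iv in per_type[name]:
            matrix[index[iv], c] = True
    return AnnotationMatrix(intervals, cell_types, matrix,
                            categories=dict(categories or {}))


def snp_hit_vector(matrix: AnnotationMatrix, snp_positions: pd.DataFrame) -> np.ndarray:
    """Boolean per-enhancer vector: does the interval contain >= 1 set SNP?

    ``snp_positions`` needs columns ``chrom, pos`` (1-based).  Containment is
    start < pos <= end.
    """
    hit = np.zeros(matrix.n_enhancers, dtype=bool)
    if len(snp_positions) == 0:
        return hit
    for chrom, grp in snp_positions.groupby(snp_positions["chrom"].astype(str)):
        sel = matrix.intervals["chrom"].astype(str) == chrom
        if not sel.any():
            continue
        pos = np.sort(grp["pos"].to_numpy())
        starts = matrix.intervals.loc[sel, "start"].to_numpy()
        ends = matrix.intervals.loc[sel, "end"].to_numpy()
        n_inside = (np.searchsorted(pos, ends, side="right")
                    - np.searchsorted(pos, starts, side="right"))
        hit[sel.to_numpy()] = n_inside > 0
    return hit


def overlap_count(matrix: AnnotationMatrix, cell_type: str,
                  snp_positions: pd.DataFrame) -> int:
    """Distinct enhancers active in ``cell_type`` containing >= 1 SNP of the set."""
    c = matrix.cell_types.index(cell_type)
    return int((snp_hit_vector(matrix, snp_positions) & matrix.matrix[:, c]).sum())


def permute_matrix(matrix: AnnotationMatrix, seed, mode: str = "rows",
                   ) -> AnnotationMatrix:
    """One shuffled replicate of the activity matrix.

    ``mode="rows"`` (default) permutes the interval -> activity-profile
    mapping jointly, conserving row and column sums exactly.
    ``mode="columns"`` shuffles each cell type's column independently,
    conserving column sums only.
    """
    rng = np.random.default_rng(seed)
    if mode == "rows":
        perm = rng.permutation(matrix.n_enhancers)
        new = matrix.matrix[perm]
    elif mode == "columns":
        new = np.empty_like(matrix.matrix)
        for c in range(matrix.matrix.shape[1]):
            new[:, c] = matrix.matrix[rng.permutation(matrix.n_enhancers), c]
    else:
        raise DataError(f"unknown permutation mode {mode!r}")
    return AnnotationMatrix(matrix.intervals, matrix.cell_types, new,
                            categories=matrix.categories)


def _null_counts(matrix: AnnotationMatrix, h: np.ndarray, n_perm: int,
                 rng: np.random.Generator, mode: str) -> np.ndarray:
    """(n_perm, n_cell_types) overlap counts under the shuffled null."""
    m = matrix.matrix.astype(np.float32)
    hf = h.astype(np.float32)
    if mode == "rows":
        # count_c = sum_e h[perm(e)] * M[e, c]  ==  (h o perm) . M[:, c]
        counts = np.empty((n_perm, len(matrix.cell_types)), dtype=np.float32)
        chunk = max(1, int(2e7 // max(matrix.n_enhancers, 1)))
        for s in range(0, n_perm, chunk):
            k = min(chunk, n_perm - s)
            perms = np.argsort(rng.random((k, matrix.n_enhancers)), axis=1)
            counts[s:s + k] = hf[perms] @ m
        return counts
    if mode == "columns":
        counts = np.empty((n_perm, len(matrix.cell_types)), dtype=np.float32)
        for c in range(len(matrix.cell_types)):
            col = m[:, c]
            chunk = max(1, int(2e7 // max(matrix.n_enhancers, 1)))
            for s in range(0, n_perm, chunk):
                k = min(chunk, n_perm - s)
                perms = np.argsort(rng.random((k, matrix.n_enhancers)), axis=1)
                counts[s:s + k, c] = hf[perms] @ col
        return counts
    raise DataError(f"unknown permutation mode {mode!r}")


def permutation_enrichment(matrix: AnnotationMatrix,
                           snp_sets: dict[str, pd.DataFrame],
                           n_perm: int = 10_000, seed=0, mode: str = "rows",
                           return_null: bool = False):
    """The margin-preserving permutation enrichment test.

    Parameters
    ----------
    snp_sets
        Mapping set name (e.g. disease) -> DataFrame of SNP positions
        (columns ``chrom, pos``); typically the disease-specific indices plus
        their proxies.  SNPs are never shuffled, so LD among them is intact.
    n_perm, seed, mode
        Number of shuffled replicates, RNG seed, and shuffle mode (see
        :func:`permute_matrix`).

    Returns
    -------
    DataFrame with one row per (set, cell type): ``set, cell_type, category,
    observed, n_perm, b, p, mode`` sorted ascending by p, where b counts
    replicates with count >= observed and p = (b + 1) / (n_perm + 1).
    With ``return_null=True`` also returns ``{set: (n_perm, n_cell_types)
    null count array}``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    nulls = {}
    for name, snps in snp_sets.items():
        if snps is None or len(snps) == 0:
            log.warning("permutation_enrichment: empty SNP set %r; all p = 1", name)
            h = np.zeros(matrix.n_enhancers, dtype=bool)
        else:
            h = snp_hit_vector(matrix, snps)
        observed = (h[:, None] & matrix.matrix).sum(axis=0)
        null = _null_counts(matrix, h, n_perm, rng, mode)
        b = (null >= observed[None, :].astype(np.float32)).sum(axis=0)
        p = (b + 1.0) / (n_perm + 1.0)
        nulls[name] = null
        for c, ct in enumerate(matrix.cell_types):
            rows.append((name, ct, matrix.categories.get(ct, ""),
                         int(observed[c]), n_perm, int(b[c]), float(p[c]), mode))
    out = pd.DataFrame(rows, columns=["set", "cell_type", "category",
                                      "observed", "n_perm", "b", "p", "mode"])
    out = out.sort_values(["set", "p", "cell_type"]).reset_index(drop=True)
    if return_null:
        return out, nulls
    return out
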