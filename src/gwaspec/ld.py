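"""Linkage disequilibrium from a reference genotype panel.

The panel is a samples-by-variants dosage matrix (0/1/2 or fractional).
Pairwise LD is the squared Pearson correlation of dosage vectors, the usual
genotype-correlation definition.  On top of it sit the two workhorses of the
analysis: greedy window-based pruning (keep one representative per clump of
correlated variants) and proxy expansion (collect everything in high LD with
an index variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)


@dataclass
class GenotypePanel:
    """Reference dosages with a (chrom, pos)-sorted variant index.

    Attributes
    ----------
    variants
        DataFrame with columns ``variant_id, chrom, pos``, strictly increasing
        by (chrom, pos).
    dosages
        ``(n_samples, n_variants)`` float array; every column has non-zero
        variance (monomorphic variants are rejected at load).
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    _index: dict = field(init=False, repr=False)
    _z: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self):
        order = np.lexsort((self.variants["pos"].to_numpy(),
                            self.variants["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(order))):
            self.variants = self.variants.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[:, order]
        var = self.dosages.var(axis=0)
        if np.any(var == 0):
            raise DataError("panel contains monomorphic variants")
        self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}
        if len(self._index) != len(self.variants):
            raise DataError("duplicate variant ids in panel")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def loc(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise DataError(f"variant {variant_id!r} not in panel") from None

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    @property
    def zscores(self) -> np.ndarray:
        """Column-standardised dosages, so r(i,j) = z_i . z_j / n."""
        if self._z is None:
            x = self.dosages - self.dosages.mean(axis=0)
            x /= x.std(axis=0)
            self._z = x
        return self._z

    def allele_freq(self) -> np.ndarray:
        """Per-variant dosage allele frequency (mean dosage / 2)."""
        return self.dosages.mean(axis=0) / 2.0


def _load_vcf(path) -> GenotypePanel:
    from cyvcf2 import VCF

    ids, chroms, poss, rows = [], [], [], []
    n_mono = n_multi = 0
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        # cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
        gt = rec.gt_types
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        if np.isnan(dos).any():
            dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        if dos.var() == 0:
            n_mono += 1
            continue
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM).removeprefix("chr"))
        poss.append(rec.POS)
        rows.append(dos)
    if n_multi:
        log.info("load_panel: skipped %d multiallelic records", n_multi)
    if n_mono:
        log.info("load_panel: removed %d monomorphic variants", n_mono)
    if not rows:
        raise DataError(f"no usable biallelic polymorphic variants in {path}")
    variants = pd.DataFrame({"variant_id": ids, "chrom": chroms, "pos": poss})
    return GenotypePanel(variants, np.array(rows).T)


def _load_dosage_matrix(path) -> GenotypePanel:
    df = pd.read_csv(path, sep=r"\s+")
    id_col, chrom_col, pos_col = df.columns[:3]
    dos = df[df.columns[3:]].to_numpy(dtype=float)
    variance = dos.var(axis=1)
    mono = variance == 0
    if mono.any():
        log.info("load_panel: removed %d monomorphic variants", int(mono.sum()))
        df, dos = df[~mono], dos[~mono]
    if dos.size == 0:
        raise DataError(f"no polymorphic variants in {path}")
    variants = pd.DataFrame({
        "variant_id": df[id_col].astype(str).to_numpy(),
        "chrom": df[chrom_col].astype(str).str.removeprefix("chr").to_numpy(),
        "pos": df[pos_col].astype(np.int64).to_numpy(),
    })
    return GenotypePanel(variants, dos.T)


def load_panel(path) -> GenotypePanel:
    """Load a reference panel from a VCF or a whitespace-delimited dosage matrix.

    The dosage-matrix layout is: header row, then one row per variant with
    columns ``id chrom pos`` followed by one dosage column per sample.
    Monomorphic variants are removed (logged); multiallelic VCF records are
    skipped (logged).
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or first.startswith("#CHROM"):
        return _load_vcf(path)
    return _load_dosage_matrix(path)


def r2(panel: GenotypePanel, id1: str, id2: str) -> float:
    """Squared Pearson correlation between two variants' dosage vectors."""
    z = panel.zscores
    i, j = panel.loc(id1), panel.loc(id2)
    r = float(z[:, i] @ z[:, j]) / panel.n_samples
    return r * r


def _r2_block(panel: GenotypePanel, i: int, js: np.ndarray) -> np.ndarray:
    z = panel.zscores
    r = (z[:, js].T @ z[:, i]) / panel.n_samples
    return r * r


def _chrom_slices(chrom: np.ndarray) -> dict[str, tuple[int, int]]:
    """Start/end of each chromosome's contiguous run in a (chrom, pos)-sorted array."""
    slices: dict[str, tuple[int, int]] = {}
    if len(chrom) == 0:
        return slices
    uniq, starts = np.unique(chrom, return_index=True)
    order = np.argsort(starts)
    starts = starts[order]
    ends = np.append(starts[1:], len(chrom))
    for c, s, e in zip(uniq[order], starts, ends):
        slices[c] = (int(s), int(e))
    return slices


def _window_neighbors(slices: dict, chrom: np.ndarray, pos: np.ndarray, i: int,
                      window_bp: int) -> np.ndarray:
    """Indices on variant i's chromosome with |pos - pos_i| <= window_bp (i excluded)."""
    s, e = slices[chrom[i]]
    lo = s + np.searchsorted(pos[s:e], pos[i] - window_bp, side="left")
    hi = s + np.searchsorted(pos[s:e], pos[i] + window_bp, side="right")
    js = np.arange(lo, hi)
    return js[js != i]


def prune(panel: GenotypePanel, variants: pd.DataFrame, r2_max: float = 0.2,
          window_bp: int = 2_000_000, priority_col: str = "priority") -> list[str]:
    """Greedy LD pruning: keep the best tag per clump.

    Repeatedly keeps the highest-priority unprocessed variant and removes all
    unprocessed variants within ``window_bp`` on the same chromosome whose r2
    with it is at least ``r2_max``; consequently no retained pair within the
    window has r2 >= r2_max.  Priority ties break by (chrom, pos) ascending.
    The result is independent of the input row order.

    Parameters
    ----------
    variants
        DataFrame with ``variant_id`` and a ``priority_col`` column (larger =
        kept preferentially, e.g. -log10 meta P or |S|).  All variants must
        exist in the panel.

    Returns
    -------
    Retained variant ids, in (chrom, pos) order.
    """
    idx = np.array([panel.loc(v) for v in variants["variant_id"]])
    sub = np.sort(idx)
    id_arr = panel.variants["variant_id"].to_numpy()[sub]
    chrom = panel.variants["chrom"].to_numpy()[sub]
    pos = panel.variants["pos"].to_numpy()[sub]
    prio = np.empty(len(sub))
    pos_of = {g: k for k, g in enumerate(sub)}
    for v, pr in zip(variants["variant_id"], variants[priority_col]):
        prio[pos_of[panel.loc(v)]] = pr

    # visit order: priority desc, then (chrom, pos) asc; sub is already sorted
    order = np.lexsort((np.arange(len(sub)), -prio))
    slices = _chrom_slices(chrom)
    removed = np.zeros(len(sub), dtype=bool)
    retained = np.zeros(len(sub), dtype=bool)
    for k in order:
        if removed[k]:
            continue
        retained[k] = True
        removed[k] = True
        js = _window_neighbors(slices, chrom, pos, k, window_bp)
        js = js[~removed[js]]
        if len(js):
            rr = _r2_block(panel, sub[k], sub[js])
            removed[js[rr >= r2_max]] = True
    return list(id_arr[retained])


@dataclass
class ProxySet:
    """An index variant and everything in high LD with it (itself included, r2=1)."""

    index_variant_id: str
    members: list[tuple[str, float]]

    @property
    def member_ids(self) -> list[str]:
        return [m for m, _ in self.members]


def expand_proxies(panel: GenotypePanel, index_ids: list[str],
                   r2_min: float = 0.8, window_bp: int = 1_000_000,
                   ) -> tuple[list[ProxySet], set[str]]:
    """Collect proxies (r2 strictly above ``r2_min``) around each index variant.

    Returns one :class:`ProxySet` per index plus the deduplicated flat union
    of all member ids.  An index absent from the panel yields a singleton set
    with a warning (it can still be counted downstream, just without proxies).
    """
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    ids = panel.variants["variant_id"].to_numpy()
    slices = _chrom_slices(chrom)
    sets: list[ProxySet] = []
    flat: set[str] = set()
    for vid in index_ids:
        if vid not in panel:
            log.warning("expand_proxies: index %s absent from panel; kept alone", vid)
            sets.append(ProxySet(vid, [(vid, 1.0)]))
            flat.add(vid)
            continue
        i = panel.loc(vid)
        js = _window_neighbors(slices, chrom, pos, i, window_bp)
        members = [(vid, 1.0)]
        if len(js):
            rr = _r2_block(panel, i, js)
            hit = js[rr > r2_min]
            members += [(ids[j], float(r)) for j, r in zip(hit, rr[rr > r2_min])]
        sets.append(ProxySet(vid, members))
        flat.update(m for m, _ in members)
    return sets, flat


def write_proxy_map(sets: list[ProxySet], path) -> None:
    rows = [(s.index_variant_id, m, r) for s in sets for m, r in s.members]
    pd.DataFrame(rows, columns=["index_id", "proxy_id", "r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")
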