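"""Synthetic paired-disease GWAS data with block LD and known ground truth.

The generator emulates the data a two-disease summary-statistics analysis
consumes: a reference genotype panel with block-wise LD, two case-control
summary-statistic tables with shared and disease-specific causal effects at
realistic cohort sizes, and per-cell-type enhancer tracks in which one
designated cell type is enriched over the disease-specific causal variants.

Genotypes come from a haplotype copying model: within a block the allele
frequency f is shared (tightly linked variants share frequencies in real
data) and each haplotype is a Markov chain along the block — the allele at
the next SNP copies the previous one with probability rho and is drawn
fresh from Bernoulli(f) otherwise.  This makes the haplotype (and dosage)
correlation exactly rho^|i-j| on the observable scale, which a thresholded
latent-Gaussian model cannot achieve at low allele frequencies (tetrachoric
attenuation).  Two haplotypes sum to a dosage; blocks sit > 2 Mb apart, so
they are LD-independent by construction.

Summary statistics are simulated directly at the summary level: within each
block the observed effect vector is

    beta_hat_d ~ Normal(R beta_d, S_d R S_d)

with R the panel dosage correlation of the block, beta_d the class-assigned
true log-odds for disease d, and S_d = diag(se) where
se = 1 / sqrt(2 f (1-f) n_eff,d), n_eff = 4 / (1/n_cases + 1/n_controls).
This matches the distributional assumptions the downstream statistics make
and is orders of magnitude faster than individual-level logistic regression.

Default cohort sizes mirror large published RA and SLE case-control studies
(14,361/43,923 and 4,036/6,959) so the two diseases' standard errors show a
realistic power asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .enrichment import AnnotationMatrix, build_annotation_matrix
from .ld import GenotypePanel
from .sumstats import CANONICAL_COLUMNS

#: allele pairs that can never be strand-ambiguous
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_N_CHROMS = 22
_BLOCK_SPACING_BP = 3_000_000  # > the 2 Mb pruning window
_SNP_SPACING_BP = 1_000


@dataclass
class AnnotationConfig:
    """Enhancer-track generator settings."""

    n_cell_types: int = 20
    enhancers_per_type: int = 300
    enhancer_length: int = 1_000
    target_cell_type: str = "target_cell"
    target_overlap_fraction: float = 0.3  # fraction of target enhancers on truth SNPs


@dataclass
class SimulationConfig:
    """Study conditions for the paired-disease generator.

    Effect classes: ``n_shared`` causal variants with the same log-odds in
    both diseases, ``n_a_specific`` with effect in disease A only,
    ``n_b_specific`` in disease B only; everything else is null.  At most one
    causal variant is placed per LD block.
    """

    n_blocks: int = 2_000
    snps_per_block: int = 10
    rho: float = 0.5
    n_ref_samples: int = 500
    cases_a: int = 14_361
    controls_a: int = 43_923
    cases_b: int = 4_036
    controls_b: int = 6_959
    n_shared: int = 100
    n_a_specific: int = 50
    n_b_specific: int = 50
    beta_shared: float = 0.10
    beta_specific: float = 0.15
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)

    def __post_init__(self):
        if not (0 <= self.rho < 1):
            raise ConfigError("rho must be in [0, 1)")
        for name in ("n_blocks", "snps_per_block", "n_ref_samples",
                     "cases_a", "controls_a", "cases_b", "controls_b"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_causal > self.n_blocks:
            raise ConfigError("causal class counts exceed the number of blocks "
                              "(one causal variant per block)")

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block

    @property
    def n_causal(self) -> int:
        return self.n_shared + self.n_a_specific + self.n_b_specific

    def n_eff(self, disease: str) -> float:
        cases, controls = {"a": (self.cases_a, self.controls_a),
                           "b": (self.cases_b, self.controls_b)}[disease]
        return 4.0 / (1.0 / cases + 1.0 / controls)


def _seed_for(seed, stage: str) -> np.random.Generator:
    """Stage-keyed generator so each product is independently reproducible."""
    import zlib
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(stage.encode())]))


def _variant_map(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic id/chrom/pos layout: blocks round-robin over 22 chromosomes."""
    block = np.repeat(np.arange(config.n_blocks), config.snps_per_block)
    within = np.tile(np.arange(config.snps_per_block), config.n_blocks)
    chrom = (block % _N_CHROMS) + 1
    block_on_chrom = block // _N_CHROMS
    pos = 1_000_000 + block_on_chrom * _BLOCK_SPACING_BP + within * _SNP_SPACING_BP
    ids = [f"rs{b:05d}_{w:02d}" for b, w in zip(block, within)]
    return pd.DataFrame({"variant_id": ids, "chrom": chrom.astype(str),
                         "pos": pos.astype(np.int64), "block": block})


def simulate_panel(config: SimulationConfig, seed) -> GenotypePanel:
    """Simulate the LD reference panel (deterministic in (config, seed))."""
    rng = _seed_for(seed, "panel")
    m = config.snps_per_block
    vmap = _variant_map(config)

    freq_block = rng.uniform(0.05, 0.5, size=config.n_blocks)
    n_hap = 2 * config.n_ref_samples
    fresh = rng.random((config.n_blocks, n_hap, m)) < freq_block[:, None, None]
    copy = rng.random((config.n_blocks, n_hap, m - 1)) < config.rho
    hap = np.empty((config.n_blocks, n_hap, m), dtype=np.int8)
    hap[:, :, 0] = fresh[:, :, 0]
    for k in range(1, m):
        hap[:, :, k] = np.where(copy[:, :, k - 1], hap[:, :, k - 1],
                                fresh[:, :, k])
    dos = (hap.reshape(config.n_blocks, config.n_ref_samples, 2, m)
           .sum(axis=2)
           .transpose(1, 0, 2)
           .reshape(config.n_ref_samples, config.n_snps)
           .astype(float))

    # guard: flip one genotype at any (vanishingly rare) monomorphic column
    mono = dos.var(axis=0) == 0
    if mono.any():
        dos[0, mono] = np.where(dos[0, mono] == 0, 1.0, dos[0, mono] - 1.0)

    return GenotypePanel(vmap[["variant_id", "chrom", "pos"]].copy(), dos)


def assign_effect_classes(config: SimulationConfig, seed) -> pd.DataFrame:
    """Ground-truth class per variant (one causal variant per block, at most).

    Returns the variant map plus a ``class`` column in
    {null, shared, a_specific, b_specific} and signed true log-odds columns
    ``beta_true_a, beta_true_b``.
    """
    rng = _seed_for(seed, "classes")
    vmap = _variant_map(config)
    classes = np.full(config.n_snps, "null", dtype=object)
    beta_a = np.zeros(config.n_snps)
    beta_b = np.zeros(config.n_snps)

    blocks = rng.choice(config.n_blocks, size=config.n_causal, replace=False)
    within = rng.integers(0, config.snps_per_block, size=config.n_causal)
    snp_idx = blocks * config.snps_per_block + within
    signs = rng.choice([-1.0, 1.0], size=config.n_causal)

    k = 0
    for cls, count, b_a, b_b in (
            ("shared", config.n_shared, config.beta_shared, config.beta_shared),
            ("a_specific", config.n_a_specific, config.beta_specific, 0.0),
            ("b_specific", config.n_b_specific, 0.0, config.beta_specific)):
        sel = snp_idx[k:k + count]
        classes[sel] = cls
        beta_a[sel] = signs[k:k + count] * b_a
        beta_b[sel] = signs[k:k + count] * b_b
        k += count
    vmap["class"] = classes
    vmap["beta_true_a"] = beta_a
    vmap["beta_true_b"] = beta_b
    return vmap


def simulate_sumstats(panel: GenotypePanel, config: SimulationConfig, seed,
                      truth: pd.DataFrame | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate both diseases' summary-statistic tables.

    Returns ``(table_a, table_b, truth)`` where the tables are in the
    canonical column layout of :mod:`gwaspec.sumstats` and ``truth`` carries
    the effect-class assignment (generated here unless supplied).
    """
    if truth is None:
        truth = assign_effect_classes(config, seed)
    if len(truth) != panel.n_variants:
        raise ConfigError("truth table does not match panel size")
    rng = _seed_for(seed, "sumstats")
    m = config.snps_per_block
    n_blocks = config.n_blocks
    freq = panel.allele_freq()

    # per-block empirical dosage correlation + its Cholesky factor
    z = panel.dosages - panel.dosages.mean(axis=0)
    z /= z.std(axis=0)
    zb = z.reshape(panel.n_samples, n_blocks, m)
    R = np.einsum("nbi,nbj->bij", zb, zb) / panel.n_samples
    Lr = np.linalg.cholesky(R + 1e-4 * np.eye(m))

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=panel.n_variants)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    tables = []
    for disease in ("a", "b"):
        beta_true = truth[f"beta_true_{disease}"].to_numpy().reshape(n_blocks, m)
        marginal = np.einsum("bij,bj->bi", R, beta_true)
        se = (1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * config.n_eff(disease))
              ).reshape(n_blocks, m)
        noise = np.einsum("bij,bj->bi", Lr, rng.standard_normal((n_blocks, m)))
        beta_hat = (marginal + se * noise).ravel()
        se = se.ravel()
        p = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
        p = np.maximum(p, 5e-324)  # keep p in (0, 1] at extreme z
        tables.append(pd.DataFrame({
            "variant_id": truth["variant_id"],
            "chrom": truth["chrom"],
            "pos": truth["pos"],
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": freq,
            "beta": beta_hat,
            "se": se,
            "p": p,
            "info": rng.uniform(0.7, 1.0, size=panel.n_variants),
        })[CANONICAL_COLUMNS])
    return tables[0], tables[1], truth


def simulate_annotations(panel: GenotypePanel, config: SimulationConfig,
                         truth_positions: pd.DataFrame, seed,
                         ) -> tuple[AnnotationMatrix, dict[str, pd.DataFrame]]:
    """Simulate per-cell-type enhancer tracks with one enriched target cell type.

    Every cell type receives ``enhancers_per_type`` fixed-length intervals
    placed uniformly over the panel's coordinate space, except that the
    target cell type centres a fraction ``target_overlap_fraction`` of its
    intervals on randomly chosen rows of ``truth_positions`` (columns
    ``chrom, pos``) — the disease-specific causal variants it is meant to be
    enriched for.

    Returns the built :class:`AnnotationMatrix` and the raw per-cell-type
    interval frames (writable as BED).
    """
    ann = config.annotation
    rng = _seed_for(seed, "annotations")
    spans = panel.variants.groupby("chrom")["pos"].agg(["min", "max"])
    chrom_names = spans.index.to_numpy()
    lo = spans["min"].to_numpy() - 50_000
    hi = spans["max"].to_numpy() + 50_000
    weights = (hi - lo).astype(float)
    weights /= weights.sum()
    length = ann.enhancer_length

    def uniform_intervals(k: int) -> pd.DataFrame:
        ci = rng.choice(len(chrom_names), size=k, p=weights)
        start = (lo[ci] + rng.random(k) * (hi[ci] - lo[ci] - length)).astype(np.int64)
        start = np.maximum(start, 0)
        return pd.DataFrame({"chrom": chrom_names[ci].astype(str),
                             "start": start, "end": start + length})

    beds: dict[str, pd.DataFrame] = {}
    names = [f"cell_{i:02d}" for i in range(ann.n_cell_types - 1)]
    for name in names:
        beds[name] = uniform_intervals(ann.enhancers_per_type)

    n_on_truth = int(round(ann.target_overlap_fraction * ann.enhancers_per_type))
    n_on_truth = min(n_on_truth, len(truth_positions))
    parts = []
    if n_on_truth > 0:
        picked = truth_positions.iloc[
            rng.choice(len(truth_positions), size=n_on_truth, replace=False)]
        # containment is start < pos <= end; centre the interval on the SNP
        start = np.maximum(picked["pos"].to_numpy() - 1 - length // 2, 0)
        parts.append(pd.DataFrame({"chrom": picked["chrom"].astype(str).to_numpy(),
                                   "start": start.astype(np.int64),
                                   "end": (start + length).astype(np.int64)}))
    rest = ann.enhancers_per_type - n_on_truth
    if rest > 0:
        parts.append(uniform_intervals(rest))
    beds[ann.target_cell_type] = pd.concat(parts, ignore_index=True)

    categories = {name: "background" for name in names}
    categories[ann.target_cell_type] = "target"
    return build_annotation_matrix(beds, categories=categories), beds


def write_panel_dosage(panel: GenotypePanel, path) -> None:
    """Write the panel as the whitespace dosage-matrix format load_panel reads."""
    cols = {"variant_id": panel.variants["variant_id"],
            "chrom": panel.variants["chrom"],
            "pos": panel.variants["pos"]}
    for s in range(panel.n_samples):
        cols[f"S{s:04d}"] = panel.dosages[s].astype(int)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d or {})
    ann = d.pop("annotation", {})
    try:
        return SimulationConfig(annotation=AnnotationConfig(**ann), **d)
    except TypeError as exc:
        raise ConfigError(f"bad simulation config: {exc}") from None
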