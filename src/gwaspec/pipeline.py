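"""End-to-end orchestration of the cross-disease analysis.

``run_pipeline`` sequences the stages — read, filter, harmonise, MHC
exclusion, meta-analysis + Cochran's Q, LD pruning, concordance/conditional
QQ, specificity scoring and top-1% selection, proxy expansion, annotation
enrichment, downstream exports — from a single :class:`RunConfig`, writing
plain-text artifacts plus a machine-readable run report at every stage.

A single master seed deterministically derives one sub-seed per stage (keyed
by stage name), so any stage can be re-run in isolation and reproduce the
pipeline's output bit for bit.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import (DEFAULT_THRESHOLDS, conditional_qq, qq_lambda_table,
                          signed_logp_concordance)
from .enrichment import build_annotation_matrix, permutation_enrichment
from .errors import ConfigError, DataError
from .ld import load_panel, prune, write_proxy_map
from .meta import meta_table, select_cross_disease_loci
from .specificity import (assign_and_rank, build_disease_specific_sets,
                          export_depict_input)
from .sumstats import (exclude_mhc, filter_variants, harmonize, MHC_REGION,
                       read_sumstats)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def stage_seed(master_seed: int, stage: str) -> int:
    """Stage-keyed 31-bit sub-seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed) % 2**31,
                                 zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Paths, thresholds and the master seed for one pipeline run."""

    sumstats_a: str
    sumstats_b: str
    panel: str
    annotation_manifest: str
    out_dir: str
    maf_min: float = 0.005
    info_min: float = 0.5
    r2_prune: float = 0.2
    prune_window_bp: int = 2_000_000
    r2_proxy: float = 0.8
    proxy_window_bp: int = 1_000_000
    top_fraction: float = 0.01
    n_perm: int = 10_000
    gws_p: float = 5e-8
    locus_merge_bp: int = 500_000
    qq_thresholds: tuple = DEFAULT_THRESHOLDS
    mhc: tuple = MHC_REGION
    depict_p_meta_max: float = 0.05
    permutation_mode: str = "rows"
    seed: int = 0
    dialect: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, lo, hi in (("maf_min", 0, 1), ("info_min", 0, 1),
                             ("r2_prune", 0, 1), ("r2_proxy", 0, 1),
                             ("top_fraction", 0, 1), ("gws_p", 0, 1),
                             ("depict_p_meta_max", 0, 1)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.permutation_mode not in ("rows", "columns"):
            raise ConfigError(f"unknown permutation_mode {self.permutation_mode!r}")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"bad run config {path}: {exc}") from None
    if isinstance(cfg.mhc, (list, tuple)):
        cfg.mhc = (str(cfg.mhc[0]), int(cfg.mhc[1]), int(cfg.mhc[2]))
    cfg.qq_thresholds = tuple(float(t) for t in cfg.qq_thresholds)
    return cfg


def read_manifest(path) -> tuple[dict, dict]:
    """Annotation manifest TSV (cell_type, path, category) -> (beds, categories)."""
    df = pd.read_csv(path, sep="\t")
    need = {"cell_type", "path"}
    if not need <= set(df.columns):
        raise DataError(f"annotation manifest {path} needs columns {sorted(need)}")
    base = Path(path).parent
    beds = {}
    for _, row in df.iterrows():
        p = Path(row["path"])
        beds[str(row["cell_type"])] = str(p if p.is_absolute() else base / p)
    cats = ({str(r["cell_type"]): str(r["category"]) for _, r in df.iterrows()}
            if "category" in df.columns else {})
    return beds, cats


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written as JSON).

    Any stage's hard error propagates annotated with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }

    stage = "read"
    try:
        table_a = read_sumstats(config.sumstats_a, dialect=config.dialect or None)
        table_b = read_sumstats(config.sumstats_b, dialect=config.dialect or None)
        report["stages"][stage] = {"n_a": len(table_a), "n_b": len(table_b)}

        stage = "filter"
        table_a, rep_a = filter_variants(table_a, config.maf_min, config.info_min)
        table_b, rep_b = filter_variants(table_b, config.maf_min, config.info_min)
        if table_a.empty or table_b.empty:
            raise DataError("no variants survive the MAF/info filters")
        report["stages"][stage] = {"a": asdict(rep_a), "b": asdict(rep_b)}

        stage = "harmonize"
        harm, drop_log = harmonize(table_a, table_b)
        _write(drop_log, out / "drop_log.tsv")
        report["stages"][stage] = {
            "n_harmonized": len(harm),
            "n_dropped": len(drop_log),
            "drop_reasons": drop_log["reason"].value_counts().to_dict(),
        }

        stage = "exclude_mhc"
        harm, n_mhc = exclude_mhc(harm, config.mhc)
        _write(harm, out / "harmonized.tsv")
        report["stages"][stage] = {"n_removed": n_mhc, "n_remaining": len(harm)}

        stage = "panel"
        panel = load_panel(config.panel)
        in_panel = harm["variant_id"].isin(panel.variants["variant_id"]).to_numpy()
        if not in_panel.any():
            raise DataError("no overlap between harmonised variants and the panel")
        n_off_panel = int((~in_panel).sum())
        harm = harm[in_panel].reset_index(drop=True)
        report["stages"][stage] = {"n_panel_variants": panel.n_variants,
                                   "n_off_panel_dropped": n_off_panel}

        stage = "meta"
        meta = meta_table(harm)
        _write(meta, out / "meta.tsv")
        combined = harm.merge(meta.drop(columns=["chrom", "pos"]), on="variant_id")
        loci = select_cross_disease_loci(combined, config.gws_p, config.locus_merge_bp)
        _write(loci, out / "loci.tsv")
        report["stages"][stage] = {"n_meta": len(meta), "n_cross_disease_loci": len(loci)}

        stage = "prune"
        prio = combined[["variant_id"]].copy()
        prio["priority"] = -np.log10(np.maximum(combined["p_meta"], 5e-324))
        kept = prune(panel, prio, r2_max=config.r2_prune,
                     window_bp=config.prune_window_bp)
        pruned = combined[combined["variant_id"].isin(kept)].reset_index(drop=True)
        _write(pruned[["variant_id", "chrom", "pos", "p_meta"]], out / "pruned.tsv")
        report["stages"][stage] = {"n_pruned_universe": len(pruned)}

        stage = "concordance_qq"
        r, p = signed_logp_concordance(pruned)
        _write(pd.DataFrame({"pearson_r": [r], "p": [p], "n": [len(pruned)]}),
               out / "concordance.tsv")
        qq = conditional_qq(pruned, thresholds=config.qq_thresholds)
        _write(pd.concat([res.to_frame() for res in qq.values()],
                         ignore_index=True), out / "qq_data.tsv")
        _write(qq_lambda_table(qq), out / "qq_lambda.tsv")
        report["stages"][stage] = {
            "concordance_r": r, "concordance_p": p,
            "lambdas": {name: res.lambdas() for name, res in qq.items()},
        }

        stage = "specificity"
        ranked = assign_and_rank(pruned, top_fraction=config.top_fraction)
        _write(ranked[["variant_id", "chrom", "pos", "t_a", "t_b", "q", "p_q",
                       "z_het", "s_a", "s_b", "assigned", "rank", "percentile",
                       "top1pct"]], out / "specificity.tsv")
        report["stages"][stage] = {
            "n_top_a": int(((ranked["assigned"] == "A") & ranked["top1pct"]).sum()),
            "n_top_b": int(((ranked["assigned"] == "B") & ranked["top1pct"]).sum()),
        }

        stage = "proxies"
        sets = build_disease_specific_sets(ranked, panel, r2_min=config.r2_proxy,
                                           window_bp=config.proxy_window_bp)
        positions = panel.variants.set_index("variant_id")
        snp_positions = {}
        for disease in ("A", "B"):
            flat, proxy_sets = sets[disease]
            ids = sorted(flat)
            (out / f"snps_{disease}.txt").write_text("".join(i + "\n" for i in ids))
            write_proxy_map(proxy_sets, out / f"proxy_map_{disease}.tsv")
            pos_df = positions.reindex(ids).dropna().reset_index()
            pos_df["pos"] = pos_df["pos"].astype(np.int64)
            _write(pos_df, out / f"snp_positions_{disease}.tsv")
            snp_positions[disease] = pos_df
        report["stages"][stage] = {d: len(sets[d][0]) for d in ("A", "B")}

        stage = "enrichment"
        beds, cats = read_manifest(config.annotation_manifest)
        matrix = build_annotation_matrix(beds, categories=cats)
        enr = permutation_enrichment(
            matrix, snp_positions, n_perm=config.n_perm,
            seed=stage_seed(config.seed, "enrichment"),
            mode=config.permutation_mode)
        _write(enr, out / "enrichment.tsv")
        report["stages"][stage] = {
            "n_cell_types": len(matrix.cell_types),
            "n_enhancers": matrix.n_enhancers,
            "n_perm": config.n_perm,
            "top_hit": {s: grp.iloc[0]["cell_type"]
                        for s, grp in enr.groupby("set")},
        }

        stage = "exports"
        depict = export_depict_input(ranked, panel, meta,
                                     p_meta_max=config.depict_p_meta_max,
                                     r2_max=config.r2_prune,
                                     window_bp=config.prune_window_bp)
        for disease, df in depict.items():
            _write(df, out / f"depict_input_{disease}.tsv")
        report["stages"][stage] = {d: len(df) for d, df in depict.items()}
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", out / "run_report.json")
    return report
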