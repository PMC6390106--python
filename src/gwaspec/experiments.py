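"""Self-contained validation experiments on synthetic data.

Each function generates its own inputs with the synthetic-data module,
runs the relevant slice of the analysis, and returns the measured
quantities: closed-form oracle agreement, Q-test calibration, ground-truth
recovery of the specificity ranking, permutation-test calibration and power,
and conditional-QQ inflation behaviour.  They are used by the test suite and
by the results-reproduction script; sizes are chosen so the whole battery
runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import conditional_qq, genomic_lambda
from .enrichment import (AnnotationMatrix, permutation_enrichment,
                         snp_hit_vector)
from .ld import expand_proxies, prune
from .meta import cochran_q, cochran_q_summation, fixed_effects_meta, meta_table
from .simulate import (AnnotationConfig, SimulationConfig,
                       assign_effect_classes, simulate_annotations,
                       simulate_panel, simulate_sumstats)
from .specificity import assign_and_rank, build_disease_specific_sets
from .sumstats import harmonize


def oracle_agreement(seed: int = 0, n: int = 1000) -> dict[str, float]:
    """Max |difference| between module outputs and independent closed forms.

    Cochran's Q is recomputed through the k-study summation form, the
    fixed-effects beta/se through explicitly re-derived inverse-variance
    weights, and p_meta through the normal CDF.
    """
    rng = np.random.default_rng(seed)
    beta = rng.normal(scale=0.3, size=(n, 2))
    se = rng.uniform(0.01, 0.5, size=(n, 2))
    fe = fixed_effects_meta(beta[:, 0], se[:, 0], beta[:, 1], se[:, 1])
    het = cochran_q(beta[:, 0], se[:, 0], beta[:, 1], se[:, 1])

    w = 1.0 / se**2
    beta_ref = (w * beta).sum(1) / w.sum(1)
    se_ref = np.sqrt(1.0 / w.sum(1))
    q_ref = cochran_q_summation(beta, se)
    p_ref = 2.0 * (1.0 - stats.norm.cdf(np.abs(beta_ref / se_ref)))
    return {
        "max_beta_fe_diff": float(np.max(np.abs(fe["beta_fe"] - beta_ref))),
        "max_se_fe_diff": float(np.max(np.abs(fe["se_fe"] - se_ref))),
        "max_q_diff": float(np.max(np.abs(het["q"] - q_ref))),
        "max_p_meta_diff": float(np.max(np.abs(fe["p_meta"] - p_ref))),
    }


def het_null_type1(seed: int = 0) -> float:
    """Fraction of Q-test P < 0.05 under equal true effects (20,000 SNPs)."""
    cfg = SimulationConfig(n_shared=100, n_a_specific=0, n_b_specific=0)
    panel = simulate_panel(cfg, seed)
    table_a, table_b, _ = simulate_sumstats(panel, cfg, seed)
    het = cochran_q(table_a["beta"], table_a["se"],
                    table_b["beta"], table_b["se"])
    return float((het["p_q"] < 0.05).mean())


def run_specificity_chain(config: SimulationConfig, seed: int):
    """Panel -> sumstats -> harmonise -> meta -> prune -> rank -> SNP sets."""
    panel = simulate_panel(config, seed)
    table_a, table_b, truth = simulate_sumstats(panel, config, seed)
    harm, _ = harmonize(table_a, table_b)
    meta = meta_table(harm)
    combined = harm.merge(meta.drop(columns=["chrom", "pos"]), on="variant_id")
    prio = combined[["variant_id"]].copy()
    prio["priority"] = -np.log10(np.maximum(combined["p_meta"], 5e-324))
    kept = prune(panel, prio)
    pruned = combined[combined["variant_id"].isin(kept)].reset_index(drop=True)
    ranked = assign_and_rank(pruned)
    sets = build_disease_specific_sets(ranked, panel)
    return panel, truth, pruned, ranked, sets


def specificity_recovery(seed: int = 0,
                         config: SimulationConfig | None = None,
                         ) -> dict[str, float]:
    """Ground-truth recovery of the top-1% disease-specific SNP sets.

    recall_X: fraction of X-specific causal variants captured by disease X's
    set (top-1% indices plus proxies); cross_X: fraction of the OTHER
    disease's causal variants wrongly captured by X's set.
    """
    cfg = config or SimulationConfig()
    _, truth, _, _, sets = run_specificity_chain(cfg, seed)
    truth_a = set(truth.loc[truth["class"] == "a_specific", "variant_id"])
    truth_b = set(truth.loc[truth["class"] == "b_specific", "variant_id"])
    set_a, set_b = sets["A"][0], sets["B"][0]
    return {
        "recall_a": len(truth_a & set_a) / len(truth_a),
        "recall_b": len(truth_b & set_b) / len(truth_b),
        "cross_a": len(truth_b & set_a) / len(truth_b),
        "cross_b": len(truth_a & set_b) / len(truth_a),
    }


def _random_annotation(rng, n_cell_types, enhancers_per_type, length,
                       span) -> AnnotationMatrix:
    frames = {}
    for c in range(n_cell_types):
        start = rng.integers(0, span - length, size=enhancers_per_type)
        frames[f"ct{c:02d}"] = pd.DataFrame(
            {"chrom": "1", "start": start, "end": start + length})
    from .enrichment import build_annotation_matrix
    return build_annotation_matrix(frames)


def enrichment_calibration(seed: int = 0, n_runs: int = 10,
                           n_cell_types: int = 20, enhancers_per_type: int = 300,
                           length: int = 5_000, span: int = 100_000_000,
                           n_snps: int = 1_500, n_perm: int = 500,
                           ) -> dict[str, float]:
    """Null calibration: annotations and SNP sets placed uniformly at random.

    Returns the KS P value of the (n_runs x n_cell_types) permutation P
    values against uniform, the empirical rate of p < 0.05, and the smallest
    p observed (the add-one rule bounds it below by 1/(n_perm+1)).
    """
    rng = np.random.default_rng(seed)
    pvals = []
    for run in range(n_runs):
        matrix = _random_annotation(rng, n_cell_types, enhancers_per_type,
                                    length, span)
        snps = pd.DataFrame({"chrom": "1",
                             "pos": rng.integers(1, span, size=n_snps)})
        res = permutation_enrichment(matrix, {"null": snps}, n_perm=n_perm,
                                     seed=int(rng.integers(2**31)))
        pvals.extend(res["p"].tolist())
    pvals = np.array(pvals)
    return {
        "n_p": len(pvals),
        "ks_p": float(stats.kstest(pvals, "uniform").pvalue),
        "rate_lt_05": float((pvals < 0.05).mean()),
        "min_p": float(pvals.min()),
        "floor": 1.0 / (n_perm + 1),
    }


def enrichment_enumeration_gap(seed: int = 0, n_enhancers: int = 6,
                               n_cell_types: int = 3, n_perm: int = 10_000,
                               ) -> dict[str, float]:
    """Monte-Carlo vs exhaustive-enumeration permutation P on a tiny instance.

    Returns the largest |p_mc - p_exact| across cell types, in units of the
    exact Monte-Carlo standard error (add-one correction included in slack).
    """
    import itertools

    from .enrichment import build_annotation_matrix

    rng = np.random.default_rng(seed)
    iv = pd.DataFrame({"chrom": "1",
                       "start": 1000 * np.arange(n_enhancers),
                       "end": 1000 * np.arange(n_enhancers) + 500})
    mat = rng.random((n_enhancers, n_cell_types)) < 0.5
    matrix = AnnotationMatrix(iv, [f"ct{j}" for j in range(n_cell_types)], mat)
    snps = pd.DataFrame({"chrom": "1", "pos": [200, 1300, 3400]})
    h = snp_hit_vector(matrix, snps)
    observed = (h[:, None] & mat).sum(axis=0)

    total = 0
    b_exact = np.zeros(n_cell_types)
    for perm in itertools.permutations(range(n_enhancers)):
        counts = (h[list(perm), None] & mat).sum(axis=0)
        b_exact += counts >= observed
        total += 1
    p_exact = b_exact / total

    res = permutation_enrichment(matrix, {"d": snps}, n_perm=n_perm, seed=seed)
    p_mc = res.set_index("cell_type").loc[matrix.cell_types, "p"].to_numpy()
    se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
    gap_in_se = np.abs(p_mc - p_exact) / np.maximum(se, 2.0 / n_perm)
    return {"max_gap_se_units": float(gap_in_se.max()),
            "max_abs_gap": float(np.max(np.abs(p_mc - p_exact)))}


POWER_CONFIG = SimulationConfig(
    n_blocks=400, snps_per_block=10, n_ref_samples=300,
    n_shared=20, n_a_specific=30, n_b_specific=30,
    annotation=AnnotationConfig(n_cell_types=15, enhancers_per_type=200,
                                target_overlap_fraction=0.3))


def enrichment_power_once(seed: int, config: SimulationConfig = POWER_CONFIG,
                          n_perm: int = 1_000) -> bool:
    """One replicate: does the enriched target cell type attain the smallest p?

    The query set is the disease-specific causal variants plus their r2>0.8
    proxies; the target cell type overlays fraction f of its enhancers on
    those truth SNPs.
    """
    panel = simulate_panel(config, seed)
    truth = assign_effect_classes(config, seed)
    spec = truth[truth["class"].isin(["a_specific", "b_specific"])]
    matrix, _ = simulate_annotations(panel, config, spec[["chrom", "pos"]], seed)
    _, flat = expand_proxies(panel, list(spec["variant_id"]))
    pos = panel.variants.set_index("variant_id").loc[sorted(flat)]
    res = permutation_enrichment(matrix, {"spec": pos[["chrom", "pos"]]},
                                 n_perm=n_perm, seed=seed + 1)
    best = res["p"].min()
    target_p = res.set_index("cell_type").loc[
        config.annotation.target_cell_type, "p"]
    return bool(target_p <= best)


def enrichment_power(seeds=range(50)) -> float:
    """Fraction of seeds in which the target cell type ranks first."""
    wins = [enrichment_power_once(int(s)) for s in seeds]
    return float(np.mean(wins))


def qq_null_lambda(seed: int = 0, n_blocks: int = 2_000) -> dict[str, float]:
    """Unconditioned genomic inflation of a fully null simulated study.

    Uses independent variants (rho = 0) so the median-based lambda estimate
    carries its full effective sample size; block LD would only add sampling
    noise to a statistic whose expectation is 1 either way.
    """
    cfg = SimulationConfig(n_blocks=n_blocks, snps_per_block=10, rho=0.0,
                           n_shared=0, n_a_specific=0, n_b_specific=0)
    panel = simulate_panel(cfg, seed)
    table_a, table_b, _ = simulate_sumstats(panel, cfg, seed)
    return {"lambda_a": genomic_lambda(table_a["p"]),
            "lambda_b": genomic_lambda(table_b["p"]),
            "n": cfg.n_snps}


SHARED_QQ_CONFIG = SimulationConfig(n_shared=500, n_a_specific=0,
                                    n_b_specific=0, beta_shared=0.05)


def qq_shared_lambdas(seed: int = 0,
                      config: SimulationConfig = SHARED_QQ_CONFIG,
                      ) -> dict[str, list[float]]:
    """Conditional lambdas on a shared-architecture study, loosest threshold first."""
    _, _, pruned, _, _ = run_specificity_chain(config, seed)
    qq = conditional_qq(pruned)
    return {name: [s.lam for s in res.strata] for name, res in qq.items()}
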