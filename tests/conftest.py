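import numpy as np
import pandas as pd
import pytest

import gwaspec as g

SMALL_CONFIG = dict(n_blocks=60, snps_per_block=10, n_ref_samples=200,
                    n_shared=10, n_a_specific=8, n_b_specific=8)


@pytest.fixture(scope="session")
def small_config():
    return g.SimulationConfig(
        **SMALL_CONFIG,
        annotation=g.AnnotationConfig(n_cell_types=8, enhancers_per_type=100))


@pytest.fixture(scope="session")
def small_panel(small_config):
    return g.simulate_panel(small_config, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config, small_panel):
    """(table_a, table_b, truth) from one small deterministic simulation."""
    return g.simulate_sumstats(small_panel, small_config, seed=11)


@pytest.fixture(scope="session")
def small_harmonized(small_study):
    harm, _ = g.harmonize(small_study[0], small_study[1])
    return harm


@pytest.fixture(scope="session")
def small_pruned(small_harmonized, small_panel):
    """Meta-annotated, LD-pruned table — the ranking universe of the small study."""
    harm = small_harmonized
    meta = g.meta_table(harm)
    combined = harm.merge(meta.drop(columns=["chrom", "pos"]), on="variant_id")
    prio = combined[["variant_id"]].copy()
    prio["priority"] = -np.log10(np.maximum(combined["p_meta"], 5e-324))
    kept = g.prune(small_panel, prio)
    return combined[combined["variant_id"].isin(kept)].reset_index(drop=True)


def toy_sumstats(rows, start_id=0):
    """Canonical table from (chrom, pos, ea, oa, eaf, beta, se, p, info) tuples."""
    recs = []
    for i, (chrom, pos, ea, oa, eaf, beta, se, p, info) in enumerate(rows):
        recs.append(dict(variant_id=f"rs{start_id + i}", chrom=str(chrom),
                         pos=pos, effect_allele=ea, other_allele=oa,
                         eaf=eaf, beta=beta, se=se, p=p, info=info))
    return pd.DataFrame(recs)[g.sumstats.CANONICAL_COLUMNS]


def dosage_panel(variants, dosages):
    """Panel from a list of (id, chrom, pos) and a samples-by-variants array."""
    return g.GenotypePanel(
        pd.DataFrame(variants, columns=["variant_id", "chrom", "pos"]),
        np.asarray(dosages, dtype=float))
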