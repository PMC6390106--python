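"""Test disease-specific SNP sets for enrichment in cell-type enhancers.

The null model shuffles the enhancer-by-cell-type activity matrix (a joint
row permutation conserving both the enhancers-per-cell-type and
cell-types-per-enhancer margins), never the SNPs, so LD among the query SNPs
is preserved.  p = (b + 1) / (n_perm + 1) where b counts replicates whose
overlap count reaches the observed one.
"""

import gwaspec as g

config = g.SimulationConfig(
    n_blocks=400, snps_per_block=10, n_ref_samples=300,
    n_shared=20, n_a_specific=30, n_b_specific=30,
    annotation=g.AnnotationConfig(n_cell_types=12, enhancers_per_type=200,
                                  target_overlap_fraction=0.3))
panel = g.simulate_panel(config, seed=2)
truth = g.assign_effect_classes(config, seed=2)
spec = truth[truth["class"].isin(["a_specific", "b_specific"])]
matrix, _ = g.simulate_annotations(panel, config, spec[["chrom", "pos"]], seed=2)

_, flat = g.expand_proxies(panel, list(spec["variant_id"]))
positions = panel.variants.set_index("variant_id").loc[sorted(flat)]

res = g.permutation_enrichment(matrix, {"disease_specific": positions},
                               n_perm=10_000, seed=3)
print(f"{matrix.n_enhancers} distinct enhancers, "
      f"{len(matrix.cell_types)} cell types, 10,000 shuffles")
print("\ntop five cell types by permutation P:")
print(res.head(5)[["cell_type", "observed", "b", "p"]].to_string(index=False))

print("\nThe target cell type (whose enhancers were placed over the")
print("disease-specific variants) floors the permutation P at ~1e-4 while")
print("background cell types stay near uniform.")
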