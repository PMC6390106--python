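"""Reference-panel loading, r2, greedy pruning and proxy expansion."""

import numpy as np
import pandas as pd
import pytest

import gwaspec as g
from gwaspec.errors import DataError

from conftest import dosage_panel


def write_vcf(path, records, n_samples):
    """Minimal uncompressed VCFv4.2 with GT-only genotype columns."""
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(f"S{i}" for i in range(n_samples))]
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    for chrom, pos, vid, ref, alt, dosages in records:
        lines.append("\t".join([str(chrom), str(pos), vid, ref, alt, ".", "PASS",
                                ".", "GT"] + [gt[d] for d in dosages]))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def five_variant_records():
    return [
        ("1", 100, "v1", "A", "G", [0, 0, 1, 1, 2, 2, 0, 1, 2, 1]),
        ("1", 200, "v2", "A", "G", [0, 1, 2, 0, 1, 2, 0, 1, 2, 0]),
        ("1", 300, "v3", "A", "G", [1, 1, 1, 1, 1, 1, 1, 1, 1, 1]),  # monomorphic
        ("1", 400, "v4", "A", "G", [2, 2, 1, 1, 0, 0, 2, 1, 0, 1]),
        ("2", 100, "v5", "A", "G", [0, 2, 0, 2, 0, 2, 1, 1, 0, 2]),
    ]


class TestLoadPanel:
    def test_vcf_monomorphic_removed(self, tmp_path, five_variant_records):
        panel = g.load_panel(write_vcf(tmp_path / "p.vcf", five_variant_records, 10))
        assert panel.n_variants == 4
        assert "v3" not in panel

    def test_multiallelic_skipped(self, tmp_path, five_variant_records):
        recs = five_variant_records[:2] + [("1", 250, "vm", "A", "G,T",
                                            [0, 1, 2, 0, 1, 2, 0, 1, 2, 0])]
        panel = g.load_panel(write_vcf(tmp_path / "p.vcf", recs, 10))
        assert "vm" not in panel and panel.n_variants == 2

    def test_dosage_matrix_equals_vcf(self, tmp_path, five_variant_records):
        vcf_panel = g.load_panel(write_vcf(tmp_path / "p.vcf",
                                           five_variant_records, 10))
        g.simulate.write_panel_dosage(vcf_panel, tmp_path / "p.tsv")
        txt_panel = g.load_panel(tmp_path / "p.tsv")
        pd.testing.assert_frame_equal(txt_panel.variants, vcf_panel.variants)
        np.testing.assert_array_equal(txt_panel.dosages, vcf_panel.dosages)


class TestR2:
    def test_self_is_one(self):
        panel = dosage_panel([("a", "1", 1), ("b", "1", 2)],
                             [[0, 0], [1, 1], [2, 2], [0, 1], [1, 2], [2, 0]])
        assert g.r2(panel, "a", "a") == pytest.approx(1.0)

    def test_perfect_negative_correlation_squares_to_one(self):
        panel = dosage_panel([("a", "1", 1), ("b", "1", 2)],
                             np.array([[0, 2], [0, 2], [1, 1],
                                       [1, 1], [2, 0], [2, 0]]))
        assert g.r2(panel, "a", "b") == pytest.approx(1.0)

    def test_hand_computed_quarter(self):
        # Pearson r = 0.5 by hand -> r2 = 0.25
        panel = dosage_panel([("a", "1", 1), ("b", "1", 2)],
                             np.array([[0, 0], [1, 0], [2, 1],
                                       [0, 1], [1, 2], [2, 2]]))
        assert g.r2(panel, "a", "b") == pytest.approx(0.25, abs=1e-12)

    def test_unknown_id_fatal(self):
        panel = dosage_panel([("a", "1", 1)], [[0], [1], [2]])
        with pytest.raises(DataError, match="nope"):
            g.r2(panel, "a", "nope")

    def test_matches_bruteforce_on_random_panel(self, small_panel):
        rng = np.random.default_rng(5)
        ids = small_panel.variants["variant_id"].to_numpy()
        for i, j in rng.integers(0, len(ids), size=(25, 2)):
            expected = np.corrcoef(small_panel.dosages[:, i],
                                   small_panel.dosages[:, j])[0, 1] ** 2
            assert g.r2(small_panel, ids[i], ids[j]) == pytest.approx(
                expected, abs=1e-12)


def _corr_panel(positions, corr_pairs, n=400, seed=0):
    """Panel with approximately requested dosage correlations via shared latents."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=n)
    cols = []
    for rho in corr_pairs:
        z = rho * base + np.sqrt(1 - rho**2) * rng.normal(size=n)
        cols.append(np.digitize(z, [-0.5, 0.5]).astype(float))
    variants = [(f"v{k}", "1", p) for k, p in enumerate(positions)]
    return dosage_panel(variants, np.column_stack(cols))


class TestPrune:
    def test_greedy_keeps_priority_winner_and_distant(self):
        # B within A's window, correlated; C outside the window entirely
        panel = _corr_panel([100, 200, 2_100_000], [1.0, 0.95, 0.1], seed=3)
        variants = pd.DataFrame({"variant_id": ["v0", "v1", "v2"],
                                 "priority": [8.0, 4.0, 1.0]})
        assert g.r2(panel, "v0", "v1") > 0.2
        kept = g.prune(panel, variants, r2_max=0.2, window_bp=2_000_000)
        assert kept == ["v0", "v2"]

    def test_nothing_to_prune(self, small_panel):
        ids = small_panel.variants["variant_id"].iloc[::10]
        variants = pd.DataFrame({"variant_id": ids,
                                 "priority": np.arange(len(ids), dtype=float)})
        # one variant per block -> all pairwise r2 tiny, everything retained
        assert len(g.prune(small_panel, variants)) == len(ids)

    def test_duplicate_variants_tie_keeps_earlier_position(self):
        x = np.array([0., 0, 1, 1, 2, 2, 0, 1, 2, 1])
        panel = dosage_panel([("dup1", "1", 100), ("dup2", "1", 200)],
                             np.column_stack([x, x]))
        variants = pd.DataFrame({"variant_id": ["dup2", "dup1"],
                                 "priority": [5.0, 5.0]})
        assert g.prune(panel, variants) == ["dup1"]

    def test_order_independence(self, small_pruned, small_panel, small_harmonized):
        rng = np.random.default_rng(1)
        meta = g.meta_table(small_harmonized)
        prio = meta[["variant_id"]].copy()
        prio["priority"] = -np.log10(np.maximum(meta["p_meta"], 5e-324))
        shuffled = prio.sample(frac=1.0, random_state=7)
        assert g.prune(small_panel, prio) == g.prune(small_panel, shuffled)

    def test_no_retained_pair_correlated(self, small_panel, small_harmonized):
        """Exhaustive post-condition on a panel of a few hundred variants."""
        meta = g.meta_table(small_harmonized)
        prio = meta[["variant_id"]].copy()
        prio["priority"] = -np.log10(np.maximum(meta["p_meta"], 5e-324))
        kept = g.prune(small_panel, prio, r2_max=0.2, window_bp=2_000_000)
        sub = small_panel.variants.set_index("variant_id").loc[kept]
        for c, grp in sub.groupby("chrom"):
            ids = grp.index.to_numpy()
            pos = grp["pos"].to_numpy()
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    if abs(pos[i] - pos[j]) <= 2_000_000:
                        assert g.r2(small_panel, ids[i], ids[j]) < 0.2


class TestExpandProxies:
    def test_isolated_index_is_singleton(self, small_panel):
        vid = small_panel.variants["variant_id"].iloc[0]
        sets, flat = g.expand_proxies(small_panel, [vid], r2_min=0.999999)
        assert sets[0].member_ids == [vid] and flat == {vid}

    def test_strict_threshold(self):
        panel = _corr_panel([100, 200, 300], [1.0, 0.999, 0.2], n=4000, seed=8)
        r01 = g.r2(panel, "v0", "v1")
        r02 = g.r2(panel, "v0", "v2")
        sets, _ = g.expand_proxies(panel, ["v0"], r2_min=(r01 + r02) / 2)
        assert "v1" in sets[0].member_ids and "v2" not in sets[0].member_ids
        # threshold is strict (>): just below r2(v0,v1) keeps v1, just above drops it
        below, _ = g.expand_proxies(panel, ["v0"], r2_min=r01 - 1e-9)
        above, _ = g.expand_proxies(panel, ["v0"], r2_min=r01 + 1e-9)
        assert "v1" in below[0].member_ids and "v1" not in above[0].member_ids

    def test_shared_proxy_union(self):
        panel = _corr_panel([100, 200, 300], [0.95, 1.0, 0.95], n=4000, seed=9)
        # v0 and v2 each tag v1 strongly; v0-v2 correlation is weaker by
        # construction, so a threshold between the two isolates the sharing
        r_near = min(g.r2(panel, "v0", "v1"), g.r2(panel, "v1", "v2"))
        r_far = g.r2(panel, "v0", "v2")
        assert r_far < r_near
        sets, flat = g.expand_proxies(panel, ["v0", "v2"],
                                      r2_min=(r_far + r_near) / 2)
        assert sets[0].member_ids == ["v0", "v1"]
        assert sets[1].member_ids == ["v2", "v1"]
        assert len(flat) == 3  # v1 shared once: 2 + 2 - 1

    def test_absent_index_kept_alone(self, small_panel):
        sets, flat = g.expand_proxies(small_panel, ["rs_missing"])
        assert sets[0].member_ids == ["rs_missing"] and "rs_missing" in flat

    def test_index_always_member_with_r2_one(self, small_panel):
        ids = list(small_panel.variants["variant_id"].iloc[:5])
        sets, _ = g.expand_proxies(small_panel, ids)
        for s in sets:
            assert s.members[0] == (s.index_variant_id, 1.0)
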