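"""Annotation matrix construction and the margin-preserving permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest

import gwaspec as g
from gwaspec.errors import DataError
from gwaspec.enrichment import snp_hit_vector


def bed_frame(intervals):
    return pd.DataFrame(intervals, columns=["chrom", "start", "end"])


def snps(positions, chrom="1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions})


class TestBuildAnnotationMatrix:
    def test_union_and_sums(self):
        shared = ("1", 100, 200)
        m = g.build_annotation_matrix({
            "ct1": bed_frame([shared, ("1", 300, 400)]),
            "ct2": bed_frame([shared, ("1", 500, 600)]),
        })
        assert m.n_enhancers == 3
        np.testing.assert_array_equal(m.column_sums(), [2, 2])
        assert sorted(m.row_sums()) == [1, 1, 2]

    def test_identical_beds_give_all_ones(self):
        bed = bed_frame([("1", 0, 10), ("2", 5, 15)])
        m = g.build_annotation_matrix({"a": bed, "b": bed, "c": bed})
        assert m.matrix.all()

    def test_empty_bed_gives_zero_column(self):
        m = g.build_annotation_matrix({"a": bed_frame([("1", 0, 10)]),
                                       "b": bed_frame([])})
        np.testing.assert_array_equal(m.column_sums(), [1, 0])

    def test_malformed_bed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("1\t100\t200\n1\t300\n")
        with pytest.raises(DataError, match=":2"):
            g.build_annotation_matrix({"a": str(p)})

    def test_bed_file_and_frame_agree(self, tmp_path):
        df = bed_frame([("1", 100, 200), ("2", 50, 80)])
        p = tmp_path / "a.bed"
        g.simulate.write_bed(df, p)
        m_file = g.build_annotation_matrix({"a": str(p)})
        m_frame = g.build_annotation_matrix({"a": df})
        pd.testing.assert_frame_equal(m_file.intervals, m_frame.intervals)


class TestOverlapCount:
    def matrix(self):
        return g.build_annotation_matrix({
            "active": bed_frame([("1", 100, 200), ("1", 300, 400)]),
            "empty": bed_frame([]),
        })

    def test_zero_active_enhancers(self):
        assert g.overlap_count(self.matrix(), "empty", snps([150])) == 0

    def test_distinct_enhancer_counting(self):
        # three SNPs in one enhancer count once
        assert g.overlap_count(self.matrix(), "active",
                               snps([150, 160, 170])) == 1

    def test_multiple_enhancers_plus_outside_snp(self):
        assert g.overlap_count(self.matrix(), "active",
                               snps([150, 350, 900])) == 2

    def test_half_open_containment_convention(self):
        # interval [100, 200): contains 1-based pos 101..200, not 100 or 201
        m = g.build_annotation_matrix({"a": bed_frame([("1", 100, 200)])})
        assert g.overlap_count(m, "a", snps([100])) == 0
        assert g.overlap_count(m, "a", snps([101])) == 1
        assert g.overlap_count(m, "a", snps([200])) == 1
        assert g.overlap_count(m, "a", snps([201])) == 0


class TestPermuteMatrix:
    def random_matrix(self, seed=0, n=40, c=6):
        rng = np.random.default_rng(seed)
        iv = bed_frame([("1", 10 * i, 10 * i + 5) for i in range(n)])
        return g.AnnotationMatrix(iv, [f"ct{j}" for j in range(c)],
                                  rng.random((n, c)) < 0.3)

    def test_row_mode_conserves_both_margins(self):
        m = self.random_matrix()
        for seed in range(10):
            p = g.permute_matrix(m, seed)
            np.testing.assert_array_equal(p.column_sums(), m.column_sums())
            assert sorted(p.row_sums()) == sorted(m.row_sums())

    def test_column_mode_conserves_column_sums(self):
        m = self.random_matrix(1)
        p = g.permute_matrix(m, 3, mode="columns")
        np.testing.assert_array_equal(p.column_sums(), m.column_sums())

    def test_fixed_seed_reproducible(self):
        m = self.random_matrix(2)
        p1 = g.permute_matrix(m, 42)
        p2 = g.permute_matrix(m, 42)
        np.testing.assert_array_equal(p1.matrix, p2.matrix)
        assert not np.array_equal(g.permute_matrix(m, 43).matrix, p1.matrix)


class TestPermutationEnrichment:
    def test_zero_active_enhancers_p_one(self):
        m = g.build_annotation_matrix({"on": bed_frame([("1", 100, 200)]),
                                       "off": bed_frame([])})
        res = g.permutation_enrichment(m, {"d": snps([150])}, n_perm=200, seed=0)
        off = res[res["cell_type"] == "off"].iloc[0]
        assert off["observed"] == 0 and off["p"] == 1.0

    def test_empty_snp_set_all_p_one(self):
        m = g.build_annotation_matrix({"on": bed_frame([("1", 100, 200)])})
        res = g.permutation_enrichment(m, {"d": snps([])}, n_perm=100, seed=0)
        assert (res["p"] == 1.0).all()

    def test_exact_three_way_null(self):
        """3 equal enhancers, column sum 1, SNPs inside one: p converges to 1/3."""
        m = g.build_annotation_matrix({
            "hit": bed_frame([("1", 100, 200)]),
            "other1": bed_frame([("1", 300, 400)]),
            "other2": bed_frame([("1", 500, 600)]),
        })
        one_active = g.AnnotationMatrix(
            m.intervals, ["ct"], np.array([[True], [False], [False]]))
        res = g.permutation_enrichment(one_active, {"d": snps([150])},
                                       n_perm=9999, seed=1)
        se = np.sqrt((1 / 3) * (2 / 3) / 9999)
        assert res.loc[0, "p"] == pytest.approx(1 / 3, abs=3 * se + 1e-4)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """On <= 7 enhancers every row permutation can be enumerated exactly."""
        rng = np.random.default_rng(7)
        n, c = 6, 3
        iv = bed_frame([("1", 100 * i, 100 * i + 50) for i in range(n)])
        mat = rng.random((n, c)) < 0.5
        m = g.AnnotationMatrix(iv, [f"ct{j}" for j in range(c)], mat)
        positions = snps([120, 125, 310, 505])
        h = snp_hit_vector(m, positions)
        observed = (h[:, None] & mat).sum(axis=0)

        exact_b = np.zeros(c)
        n_perms = 0
        for perm in itertools.permutations(range(n)):
            counts = (h[list(perm), None] & mat).sum(axis=0)
            exact_b += counts >= observed
            n_perms += 1
        exact_p = (exact_b / n_perms)

        n_mc = 10_000
        res = g.permutation_enrichment(m, {"d": positions}, n_perm=n_mc, seed=3)
        for j, ct in enumerate(m.cell_types):
            p_mc = res.set_index("cell_type").loc[ct, "p"]
            se = np.sqrt(exact_p[j] * (1 - exact_p[j]) / n_mc)
            assert p_mc == pytest.approx(exact_p[j], abs=3 * se + 2 / n_mc)

    def test_p_never_zero_add_one_floor(self):
        m = g.build_annotation_matrix(
            {"ct": bed_frame([("1", 100, 200), ("1", 300, 400)])})
        res = g.permutation_enrichment(m, {"d": snps([150, 350])},
                                       n_perm=500, seed=0)
        assert (res["p"] >= 1 / 501).all()

    def test_determinism_same_seed(self):
        m = TestPermuteMatrix().random_matrix(5)
        s = snps([15, 105, 255])
        r1 = g.permutation_enrichment(m, {"d": s}, n_perm=300, seed=9)
        r2 = g.permutation_enrichment(m, {"d": s}, n_perm=300, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_column_mode_marginals_match_row_mode(self):
        """Per-cell-type null distributions coincide between shuffle modes."""
        m = TestPermuteMatrix().random_matrix(6, n=30, c=2)
        s = snps([15, 45, 75, 105, 215])
        _, null_rows = g.permutation_enrichment(m, {"d": s}, n_perm=4000,
                                                seed=1, return_null=True)
        _, null_cols = g.permutation_enrichment(m, {"d": s}, n_perm=4000,
                                                seed=2, mode="columns",
                                                return_null=True)
        for j in range(2):
            a, b = null_rows["d"][:, j], null_cols["d"][:, j]
            assert abs(a.mean() - b.mean()) < 0.15
            assert abs(a.std() - b.std()) < 0.15
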