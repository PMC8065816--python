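"""Fst_RMS combination, candidate selection, gene mapping, overlap tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sweepconv.convergence import (
    CandidateSet,
    annotate_candidates,
    build_convergence,
    fst_rms,
    overlap_significance,
    select_candidates,
)
from sweepconv.io import GeneModel


def _site_frame(thetas, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, len(thetas) + 1) * 100, "theta": thetas}
    )


class TestFstRms:
    def test_equal_inputs_identity(self):
        out, _ = fst_rms(_site_frame([0.2]), _site_frame([0.2]))
        assert out["fst_rms"].iloc[0] == pytest.approx(0.2)

    def test_worked_value(self):
        out, _ = fst_rms(_site_frame([0.3]), _site_frame([0.4]))
        assert out["fst_rms"].iloc[0] == pytest.approx(math.sqrt(0.125))

    def test_negative_site_dropped_and_tallied(self):
        out, info = fst_rms(_site_frame([-0.01, 0.2]), _site_frame([0.4, 0.3]))
        assert len(out) == 1
        assert info["n_negative_dropped"] == 1
        assert info["n_used"] == 1

    def test_undefined_site_dropped_and_tallied(self):
        out, info = fst_rms(_site_frame([np.nan, 0.2]), _site_frame([0.4, 0.3]))
        assert info["n_undefined_dropped"] == 1
        assert len(out) == 1

    def test_only_shared_positions_used(self):
        a = _site_frame([0.1, 0.2])
        b = _site_frame([0.3, 0.4]).assign(pos=[100, 999])
        out, info = fst_rms(a, b)
        assert info["n_shared"] == 1
        assert list(out["pos"]) == [100]

    def test_empty_intersection_is_error(self):
        b = _site_frame([0.3]).assign(chrom="chr9")
        with pytest.raises(ValueError, match="shared"):
            fst_rms(_site_frame([0.1]), b)

    @settings(derandomize=True, max_examples=200)
    @given(
        x=st.floats(0, 1, allow_nan=False),
        y=st.floats(0, 1, allow_nan=False),
    )
    def test_bounds_symmetry_and_identity(self, x, y):
        out, _ = fst_rms(_site_frame([x]), _site_frame([y]))
        rms = out["fst_rms"].iloc[0]
        hi = max(x, y)
        assert hi / math.sqrt(2) - 1e-12 <= rms <= hi + 1e-12
        out2, _ = fst_rms(_site_frame([y]), _site_frame([x]))
        assert rms == pytest.approx(out2["fst_rms"].iloc[0])


class TestSelectCandidates:
    def _frame(self, values):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, len(values) + 1), "v": values}
        )

    def test_top_fraction_keeps_maximum(self):
        cs = select_candidates(self._frame([0.9, 0.5, 0.1]), "v", "fraction", 1 / 3)
        assert list(cs.table["v"]) == [0.9]

    def test_boundary_ties_all_kept(self):
        cs = select_candidates(self._frame([0.5, 0.5, 0.1]), "v", "fraction", 1 / 3)
        assert list(cs.table["v"]) == [0.5, 0.5]

    def test_cutoff_mode(self):
        cs = select_candidates(self._frame([0.9, 0.5, 0.1]), "v", "cutoff", 0.5)
        assert sorted(cs.table["v"]) == [0.5, 0.9]
        assert cs.implied_cutoff == 0.5

    def test_fraction_matches_order_statistic_on_uniform_values(self, rng):
        vals = rng.uniform(size=1000)
        cs = select_candidates(self._frame(vals), "v", "fraction", 0.007)
        assert len(cs.table) == 7  # continuous values: no boundary ties
        assert cs.implied_cutoff == pytest.approx(np.sort(vals)[::-1][6])

    def test_fraction_superset_of_higher_cutoff(self, rng):
        vals = rng.uniform(size=500)
        frac = select_candidates(self._frame(vals), "v", "fraction", 0.05)
        cut = select_candidates(self._frame(vals), "v", "cutoff", 0.99)
        if frac.implied_cutoff <= 0.99:
            assert set(cut.table["pos"]) <= set(frac.table["pos"])


class TestAnnotateCandidates:
    def _windows(self, rows):
        return CandidateSet(
            "window",
            pd.DataFrame(rows, columns=["chrom", "start", "end"]),
            0.0, 0.0,
        )

    def test_partial_overlap_is_enough(self):
        genes = [GeneModel("g", "g", "chr1", 1000, 2000)]
        hits = annotate_candidates(self._windows([("chr1", 1, 1500)]), genes)
        assert hits == {"g"}

    def test_snp_on_gene_boundary_included(self):
        genes = [GeneModel("g", "g", "chr1", 1000, 2000)]
        cs = CandidateSet("snp", pd.DataFrame({"chrom": ["chr1"], "pos": [2000]}), 0, 0)
        assert annotate_candidates(cs, genes) == {"g"}

    def test_random_fixture_matches_all_pairs_oracle(self, rng):
        genes = []
        for i in range(50):
            start = int(rng.integers(1, 100_000))
            genes.append(
                GeneModel(f"g{i}", f"g{i}", f"chr{rng.integers(1, 3)}",
                          start, start + int(rng.integers(1, 5000)))
            )
        rows = []
        for _ in range(20):
            s = int(rng.integers(1, 100_000))
            rows.append((f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(1, 8000))))
        hits = annotate_candidates(self._windows(rows), genes)
        oracle = {
            g.gene_id
            for g in genes
            for (c, s, e) in rows
            if g.chrom == c and g.start <= e and g.end >= s
        }
        assert hits == oracle

    def test_chromosome_mismatch_warns(self, caplog):
        genes = [GeneModel("g", "g", "chr9", 1, 10)]
        with caplog.at_level("WARNING"):
            annotate_candidates(self._windows([("chr1", 1, 100)]), genes)
        assert any("chromosome" in r.message for r in caplog.records)


class TestBuildConvergence:
    def test_reference_gene_sets_intersect_to_two_genes(self):
        goat_shared = {"CHST11", "SDCCAG8", "ATF6", "FAM13A",
                       "HSP90B1", "IBSP", "IFNLR1", "STAB2"}
        sheep = {"CHST11", "SDCCAG8", "TGFB2", "NRG4", "PIK3CA"}
        rep = build_convergence(goat_shared, goat_shared, sheep)
        assert rep.convergent_genes == {"CHST11", "SDCCAG8"}

    def test_case_insensitive_matching(self):
        rep = build_convergence({"chst11"}, {"Chst11"}, {"CHST11"})
        assert rep.convergent_genes == {"CHST11"}

    def test_disjoint_sets_empty_report(self):
        rep = build_convergence({"A"}, {"B"}, {"C"})
        assert rep.goat_shared_genes == set()
        assert rep.convergent_genes == set()

    def test_ortholog_map_bridges_symbols(self):
        rep = build_convergence({"LOC1"}, {"LOC1"}, {"CHST11"},
                                ortholog_map={"LOC1": "CHST11"})
        assert rep.convergent_genes == {"CHST11"}


class TestOverlapSignificance:
    def test_zero_overlap_is_one(self):
        assert overlap_significance(0, 10, 10, 100) == 1.0

    def test_closed_form_full_overlap(self):
        p = overlap_significance(5, 5, 5, 20)
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_permutation_agrees_with_hypergeometric(self):
        N, K, n, k = 200, 20, 10, 3
        exact = overlap_significance(k, n, K, N, method="hypergeometric")
        B = 100_000
        perm = overlap_significance(k, n, K, N, method="permutation", n_perm=B, seed=5)
        se = math.sqrt(exact * (1 - exact) / B)
        assert abs(perm - exact) < 3 * se + 2 / B

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValueError):
            overlap_significance(6, 5, 10, 100)
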