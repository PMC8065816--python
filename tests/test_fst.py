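"""Weir-Cockerham estimator, windowed scan, LD pruning and PCA."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sweepconv.fst import (
    ScanParams,
    fst_scan,
    fst_windowed,
    ld_prune,
    pca,
    ratio_of_averages,
    wc_fst_site,
    window_starts,
)
from sweepconv.io import GenotypeMatrix
from sweepconv.simulate import SimParams, simulate_population_pair


def wc_oracle(n1, p1, h1, n2, p2, h2):
    """Independent step-by-step evaluation of the two-population variance
    components, written directly from the estimator's definitions."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 / 2 - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


class TestWcFstSite:
    def test_fixed_difference(self):
        a, b, c, theta = wc_fst_site(10, 1.0, 0.0, 10, 0.0, 0.0)
        assert (a, b, c, theta) == (0.5, 0.0, 0.0, 1.0)

    def test_all_heterozygote_no_differentiation(self):
        a, b, c, theta = wc_fst_site(10, 0.5, 1.0, 10, 0.5, 1.0)
        assert a == pytest.approx(0.0, abs=1e-15)
        assert b == pytest.approx(-0.25)
        assert c == pytest.approx(0.5)
        assert theta == pytest.approx(0.0, abs=1e-15)

    def test_mixed_case(self):
        a, b, c, theta = wc_fst_site(10, 0.9, 0.2, 10, 0.5, 0.6)
        assert a == pytest.approx(0.072222222, abs=1e-9)
        assert b == pytest.approx(-0.022222222, abs=1e-9)
        assert c == pytest.approx(0.2, abs=1e-12)
        assert theta == pytest.approx(0.288888889, abs=1e-9)

    def test_matches_independent_oracle_on_random_draws(self, rng):
        for _ in range(1000):
            n1, n2 = rng.integers(2, 101, size=2)
            p1, p2 = rng.uniform(0, 1, size=2)
            h1, h2 = rng.uniform(0, 1, size=2)
            a, b, c, _ = wc_fst_site(n1, p1, h1, n2, p2, h2)
            ao, bo, co = wc_oracle(n1, p1, h1, n2, p2, h2)
            assert abs(a - ao) < 1e-10
            assert abs(b - bo) < 1e-10
            assert abs(c - co) < 1e-10

    def test_monomorphic_site_theta_undefined(self):
        *_, theta = wc_fst_site(10, 0.0, 0.0, 10, 0.0, 0.0)
        assert np.isnan(theta)

    def test_single_individual_per_pop_undefined(self):
        a, *_ = wc_fst_site(1, 1.0, 0.0, 1, 0.0, 0.0)
        assert np.isnan(a)


class TestFstScan:
    def test_null_groups_have_near_zero_weighted_fst(self):
        gm, _ = simulate_population_pair(
            SimParams(n_chrom=1, chrom_len=2_000_000, n_snps=1000,
                      n_samples_per_group=30, baseline_F=0.01, seed=21)
        )
        sites = fst_scan(gm)
        assert -0.05 < ratio_of_averages(sites) < 0.05

    def test_balding_nichols_recovery(self):
        gm, _ = simulate_population_pair(
            SimParams(n_chrom=4, chrom_len=10_000_000, n_snps=20_000,
                      n_samples_per_group=50, baseline_F=0.15, seed=4)
        )
        assert ratio_of_averages(fst_scan(gm)) == pytest.approx(0.15, abs=0.02)

    def test_fixed_difference_site_theta_one(self):
        geno = np.zeros((4, 1, 2), dtype=np.int8)
        geno[2:] = 1
        gm = GenotypeMatrix(
            ["a", "b", "c", "d"],
            {"a": "LG", "b": "LG", "c": "HG", "d": "HG"},
            np.array(["chr1"], dtype=object), np.array([100]),
            np.array(["A"], dtype=object), np.array(["G"], dtype=object),
            geno, np.array([True]),
        )
        assert fst_scan(gm)["theta"].iloc[0] == pytest.approx(1.0)


class TestFstWindowed:
    def test_tiling_of_250kb_chromosome(self):
        starts = window_starts(250_000, ScanParams())
        np.testing.assert_array_equal(starts, [1, 50_001, 100_001, 150_001])

    def test_trailing_truncated_window_added_when_needed(self):
        starts = window_starts(120_000, ScanParams())
        np.testing.assert_array_equal(starts, [1, 50_001])

    def test_boundary_site_window_membership(self):
        sites = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [100_000, 100_001],
                "a": [0.1, 0.1], "b": [0.0, 0.0], "c": [0.1, 0.1],
                "theta": [0.5, 0.5],
            }
        )
        win = fst_windowed(sites, ScanParams(), {"chr1": 250_000})
        counts = win.set_index("start")["n_snps"]
        # pos 100,000 -> windows starting 1 and 50,001; pos 100,001 -> 50,001 and 100,001
        assert counts[1] == 1
        assert counts[50_001] == 2
        assert counts[100_001] == 1
        assert counts[150_001] == 0

    def test_all_fixed_differences_give_window_fst_one(self):
        sites = pd.DataFrame(
            {
                "chrom": ["chr1"] * 5,
                "pos": [10, 20_000, 40_000, 60_000, 80_000],
                "a": [0.5] * 5, "b": [0.0] * 5, "c": [0.0] * 5,
                "theta": [1.0] * 5,
            }
        )
        win = fst_windowed(sites, ScanParams(), {"chr1": 100_000})
        nonempty = win[win["n_snps"] > 0]
        assert np.allclose(nonempty["weighted_fst"], 1.0)

    def test_ratio_of_averages_invariant_to_splitting(self, rng):
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, 101),
                "a": rng.normal(0.05, 0.02, 100),
                "b": rng.normal(0.0, 0.02, 100),
                "c": rng.uniform(0.1, 0.5, 100),
            }
        )
        sites["theta"] = sites["a"] / (sites[["a", "b", "c"]].sum(axis=1))
        whole = ratio_of_averages(sites)
        part1, part2 = sites.iloc[:37], sites.iloc[37:]
        num = part1["a"].sum() + part2["a"].sum()
        den = part1[["a", "b", "c"]].to_numpy().sum() + part2[["a", "b", "c"]].to_numpy().sum()
        assert whole == pytest.approx(num / den, rel=1e-12)


def _matrix_from_dosages(dos):
    dos = np.asarray(dos)
    n_samples, n_var = dos.shape
    geno = np.zeros((n_samples, n_var, 2), dtype=np.int8)
    geno[..., 0] = (dos >= 1).astype(np.int8)
    geno[..., 1] = (dos == 2).astype(np.int8)
    return GenotypeMatrix(
        [f"s{i}" for i in range(n_samples)],
        {},
        np.array(["chr1"] * n_var, dtype=object),
        np.arange(1, n_var + 1) * 100,
        np.array(["A"] * n_var, dtype=object),
        np.array(["G"] * n_var, dtype=object),
        geno,
        np.ones(n_var, dtype=bool),
    )


class TestLdPrune:
    def test_duplicated_variant_removed(self, rng):
        col = rng.integers(0, 3, size=30)
        other = rng.integers(0, 3, size=30)
        gm = _matrix_from_dosages(np.stack([col, col, other], axis=1))
        kept = ld_prune(gm)
        assert len(kept) == 2
        assert 2 in kept

    def test_independent_variants_untouched(self, rng):
        dos = rng.integers(0, 3, size=(200, 10))  # large n -> tiny r2
        gm = _matrix_from_dosages(dos)
        kept = ld_prune(gm)
        assert len(kept) == 10

    def test_kept_set_satisfies_r2_bound_in_every_window(self, rng):
        base = rng.integers(0, 3, size=(60, 200))
        # plant correlated blocks
        for j in range(0, 200, 7):
            noise = rng.integers(0, 3, size=60)
            base[:, j] = np.clip(base[:, (j + 3) % 200] + (noise == 0), 0, 2)
        gm = _matrix_from_dosages(base)
        kept = ld_prune(gm, window_snps=50, step_snps=5, r2_max=0.2)
        dos = gm.dosages()[:, kept]
        kept_pos = np.asarray(kept)
        for w0 in range(0, 200, 5):
            inw = np.flatnonzero((kept_pos >= w0) & (kept_pos < w0 + 50))
            for ii in range(len(inw)):
                for jj in range(ii + 1, len(inw)):
                    x, y = dos[:, inw[ii]], dos[:, inw[jj]]
                    if x.std() == 0 or y.std() == 0:
                        continue
                    r2 = np.corrcoef(x, y)[0, 1] ** 2
                    assert r2 <= 0.2 + 1e-12


class TestPca:
    def test_strong_structure_separates_groups(self):
        gm, _ = simulate_population_pair(
            SimParams(n_chrom=1, chrom_len=1_000_000, n_snps=500,
                      n_samples_per_group=30, baseline_F=0.5, seed=13)
        )
        coords = pca(gm, k=2)
        from sklearn.metrics import silhouette_score

        labels = [gm.group_labels[s] for s in gm.sample_ids]
        assert silhouette_score(coords, labels) > 0.5

    def test_identical_samples_give_zero_coordinates(self):
        dos = np.tile(np.array([0, 1, 2, 1, 0]), (8, 1))
        gm = _matrix_from_dosages(dos)
        coords = pca(gm, k=2)
        assert np.allclose(coords, 0.0, atol=1e-10)

    def test_k_larger_than_rank_is_error(self):
        gm = _matrix_from_dosages(np.zeros((3, 5)))
        with pytest.raises(ValueError):
            pca(gm, k=4)
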