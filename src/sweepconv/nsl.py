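"""The nSL haplotype statistic ("number of segregating sites by length").

For a focal biallelic site, haplotypes are split into ancestral- and
derived-allele carriers.  For each within-pool pair, the identity run is the
maximal contiguous interval of segregating sites around the focal site on
which the two haplotypes agree, measured in number of SNPs (the focal site
itself always counts, so the minimum run is 1; runs hitting a chromosome
edge are kept as-is).  SL_A and SL_D are the pool-mean pairwise run lengths
and nsl_raw = ln(SL_A / SL_D): long shared haplotypes among derived carriers
(a sweep) drive nsl_raw negative and large in magnitude.  Raw scores are
z-standardized within derived-allele-frequency bins, where extreme values
flag candidate sweeps.

Ancestral allele is the VCF REF by default; an explicit ancestral-state
array can override it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from sweepconv.io import GenotypeMatrix


@dataclass
class NslParams:
    """Standardization and thresholding knobs.

    n_bins: equal-width derived-allele-frequency bins over (0, 1).
    min_pool: minimum haplotypes per allele pool for a defined score.
    abs_threshold: |standardized nSL| at or above which a site is a candidate.
    """

    n_bins: int = 20
    min_pool: int = 2
    abs_threshold: float = 6.0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


def sl_pair(hap_i: np.ndarray, hap_j: np.ndarray, s: int) -> int:
    """Identity-run length (in SNPs) around focal site ``s`` for one pair.

    Both haplotypes must agree at ``s``.  Runs truncated by a chromosome
    edge are returned as-is.
    """
    hap_i = np.asarray(hap_i)
    hap_j = np.asarray(hap_j)
    if hap_i.shape != hap_j.shape:
        raise ValueError("haplotypes differ in length")
    if hap_i[s] != hap_j[s]:
        raise ValueError(f"haplotypes disagree at focal site {s}")
    match = hap_i == hap_j
    left = s
    while left > 0 and match[left - 1]:
        left -= 1
    right = s
    while right < len(match) - 1 and match[right + 1]:
        right += 1
    return right - left + 1


def _run_lengths(match: np.ndarray) -> np.ndarray:
    """For each position, length of the maximal identity run containing it
    (0 at mismatch positions)."""
    run_id = np.cumsum(~match)
    out = np.zeros(match.size, dtype=np.int64)
    if match.any():
        lens = np.bincount(run_id[match])
        out[match] = lens[run_id[match]]
    return out


def nsl_site(H: np.ndarray, s: int, min_pool: int = 2) -> dict | None:
    """Unstandardized nSL at site ``s`` of haplotype matrix ``H`` (rows =
    haplotypes, 0 = ancestral / 1 = derived).

    Returns a dict with daf, sl_a, sl_d, nsl_raw, or None when either allele
    pool has fewer than ``min_pool`` haplotypes (including monomorphic sites).
    """
    H = np.asarray(H)
    col = H[:, s]
    d_idx = np.flatnonzero(col == 1)
    a_idx = np.flatnonzero(col == 0)
    if d_idx.size < min_pool or a_idx.size < min_pool:
        return None
    sl_d = _pool_mean_sl(H, d_idx, s)
    sl_a = _pool_mean_sl(H, a_idx, s)
    return {
        "daf": d_idx.size / (d_idx.size + a_idx.size),
        "sl_a": sl_a,
        "sl_d": sl_d,
        "nsl_raw": float(np.log(sl_a / sl_d)),
    }


def _pool_mean_sl(H: np.ndarray, pool: np.ndarray, s: int) -> float:
    total = 0
    n_pairs = 0
    for i, j in combinations(pool, 2):
        match = H[i] == H[j]
        left = s
        while left > 0 and match[left - 1]:
            left -= 1
        right = s
        while right < match.size - 1 and match[right + 1]:
            right += 1
        total += right - left + 1
        n_pairs += 1
    return total / n_pairs


def nsl_chromosome(H: np.ndarray, min_pool: int = 2) -> pd.DataFrame:
    """Raw nSL for every site of one chromosome's haplotype matrix.

    Shares each pair's identity-run profile across all focal sites, so the
    cost is O(n_pairs * n_sites) rather than per-site pairwise rescans.
    Returns columns site, daf, sl_a, sl_d, nsl_raw (NaN where undefined).
    """
    H = np.asarray(H, dtype=np.int8)
    m, S = H.shape
    sum_d = np.zeros(S)
    cnt_d = np.zeros(S, dtype=np.int64)
    sum_a = np.zeros(S)
    cnt_a = np.zeros(S, dtype=np.int64)
    for i in range(m - 1):
        hi = H[i]
        for j in range(i + 1, m):
            hj = H[j]
            match = hi == hj
            L = _run_lengths(match)
            both_d = (hi == 1) & (hj == 1)
            both_a = (hi == 0) & (hj == 0)
            sum_d[both_d] += L[both_d]
            cnt_d[both_d] += 1
            sum_a[both_a] += L[both_a]
            cnt_a[both_a] += 1
    n_derived = (H == 1).sum(axis=0)
    n_ancestral = (H == 0).sum(axis=0)
    defined = (n_derived >= min_pool) & (n_ancestral >= min_pool)
    with np.errstate(invalid="ignore", divide="ignore"):
        sl_d = np.where(cnt_d > 0, sum_d / np.maximum(cnt_d, 1), np.nan)
        sl_a = np.where(cnt_a > 0, sum_a / np.maximum(cnt_a, 1), np.nan)
        raw = np.log(sl_a / sl_d)
    sl_d[~defined] = np.nan
    sl_a[~defined] = np.nan
    raw[~defined] = np.nan
    return pd.DataFrame(
        {
            "site": np.arange(S),
            "daf": n_derived / np.maximum(n_derived + n_ancestral, 1),
            "sl_a": sl_a,
            "sl_d": sl_d,
            "nsl_raw": raw,
        }
    )


def nsl_standardize(scores: pd.DataFrame, params: NslParams) -> pd.DataFrame:
    """Z-standardize raw nSL within equal-width DAF bins over (0, 1).

    Adds ``bin_index`` and ``nsl_std``; bins with fewer than two defined
    scores or zero spread leave nsl_std NaN.  Uses the population SD.
    """
    out = scores.copy()
    daf = out["daf"].to_numpy(dtype=float)
    bins = np.clip((daf * params.n_bins).astype(int), 0, params.n_bins - 1)
    out["bin_index"] = bins
    std = np.full(len(out), np.nan)
    raw = out["nsl_raw"].to_numpy(dtype=float)
    for b in np.unique(bins):
        sel = (bins == b) & ~np.isnan(raw)
        if sel.sum() < 2:
            continue
        mu = raw[sel].mean()
        sd = raw[sel].std()  # ddof=0
        if sd <= 1e-12 * max(1.0, abs(mu)):  # degenerate (zero-spread) bin
            continue
        std[sel] = (raw[sel] - mu) / sd
    out["nsl_std"] = std
    return out


def nsl_scan(
    gm: GenotypeMatrix,
    group: str = "HG",
    params: NslParams | None = None,
    ancestral: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome-wide standardized nSL within one labelled group.

    Requires phased genotypes.  ``ancestral``, if given, is a per-variant
    0/1 array naming the ancestral allele code (default: REF ancestral).
    Returns (all scores with chrom/pos, candidate subset with
    |nsl_std| >= params.abs_threshold).
    """
    params = params or NslParams()
    if not bool(np.all(gm.phased)):
        raise ValueError("nSL requires phased haplotypes")
    idx = gm.samples_in_group(group)
    if idx.size == 0:
        raise ValueError(f"no samples labelled {group!r}")
    H_all = gm.haplotypes(idx)
    if ancestral is not None:
        flip = np.asarray(ancestral) == 1
        H_all = np.where(flip[None, :], 1 - H_all, H_all)
    frames = []
    for chrom in pd.unique(gm.chrom):
        mask = gm.chrom == chrom
        sub = nsl_chromosome(H_all[:, mask], min_pool=params.min_pool)
        sub.insert(0, "chrom", chrom)
        sub.insert(1, "pos", gm.pos[mask])
        frames.append(sub.drop(columns="site"))
    scores = pd.concat(frames, ignore_index=True)
    scores = nsl_standardize(scores, params)
    cand = scores[scores["nsl_std"].abs() >= params.abs_threshold].reset_index(drop=True)
    return scores, cand
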