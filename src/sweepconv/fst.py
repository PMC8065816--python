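"""Weir & Cockerham (1984) Fst estimation, windowed scans, LD pruning, PCA.

The per-site estimator decomposes allele-frequency variance into the
among-population (a), among-individual-within-population (b) and
within-individual (c) components; theta = a/(a+b+c).  Multi-SNP summaries
use the ratio-of-averages form sum(a)/sum(a+b+c) ("weighted" Fst), which is
the convention of the VCF toolchain the scan mirrors.  Components may be
negative at the site level and are deliberately not clipped here; clipping
to nonnegative values happens only where the cross-breed combination
statistic requires it (:mod:`sweepconv.convergence`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sweepconv.io import MISSING, GenotypeMatrix


@dataclass
class ScanParams:
    """Sliding-window parameters for the windowed Fst scan (bp units)."""

    window_bp: int = 100_000
    step_bp: int = 50_000

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window_bp and step_bp must be positive")
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")


def wc_fst_site(
    n1: float, p1: float, h1: float, n2: float, p2: float, h2: float
) -> tuple[float, float, float, float]:
    """Two-population Weir-Cockerham variance components for one SNP.

    Parameters are per-population sample size (diploid individuals with
    non-missing genotypes), allele frequency and observed heterozygote
    proportion.  Returns ``(a, b, c, theta)``; theta is NaN when the site is
    monomorphic across both populations (a+b+c == 0) or when nbar == 1.
    """
    a, b, c = _wc_components(
        np.asarray([n1]), np.asarray([p1]), np.asarray([h1]),
        np.asarray([n2]), np.asarray([p2]), np.asarray([h2]),
    )
    denom = a + b + c
    theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    return float(a[0]), float(b[0]), float(c[0]), float(theta[0])


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Vectorized a, b, c components (r = 2 populations).

    Sites with nbar == 1 come back as NaN components (the 1/(nbar-1) terms
    are undefined there).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
        c = hbar / 2.0
    bad = (nbar <= 1.0) | (nc <= 0.0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def group_site_stats(gm: GenotypeMatrix, group: str):
    """Per-site (n, p, h) for one labelled group: non-missing diploid count,
    ALT frequency and observed heterozygote proportion."""
    idx = gm.samples_in_group(group)
    if idx.size == 0:
        raise ValueError(f"no samples labelled {group!r}")
    g = gm.genotypes[idx]
    called = (g != MISSING).all(axis=2)
    n = called.sum(axis=0).astype(float)
    dos = g.sum(axis=2).astype(float)
    dos[~called] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dos, axis=0) / (2.0 * n)
        h = np.nansum(dos == 1, axis=0) / n
    return n, p, h


def fst_scan(gm: GenotypeMatrix, groups: tuple[str, str] = ("LG", "HG")) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham components between two labelled groups.

    Returns a frame with columns chrom, pos, n1, p1, h1, n2, p2, h2, a, b,
    c, theta.  theta is NaN at sites monomorphic in the pooled sample or
    where either group has no non-missing calls.
    """
    n1, p1, h1 = group_site_stats(gm, groups[0])
    n2, p2, h2 = group_site_stats(gm, groups[1])
    a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    undef = (n1 == 0) | (n2 == 0)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    theta[undef] = np.nan
    for arr in (a, b, c):
        arr[undef] = np.nan
    return pd.DataFrame(
        {
            "chrom": gm.chrom,
            "pos": gm.pos,
            "n1": n1,
            "p1": p1,
            "h1": h1,
            "n2": n2,
            "p2": p2,
            "h2": h2,
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
        }
    )


def ratio_of_averages(sites: pd.DataFrame) -> float:
    """Multi-SNP weighted Fst: sum(a)/sum(a+b+c) over sites with defined components."""
    ok = sites[["a", "b", "c"]].notna().all(axis=1)
    num = sites.loc[ok, "a"].sum()
    den = (sites.loc[ok, ["a", "b", "c"]].sum(axis=1)).sum()
    return float(num / den) if den != 0 else float("nan")


def window_starts(chrom_len: int, params: ScanParams) -> np.ndarray:
    """Window start positions tiling [1, chrom_len].

    Full windows start at 1 with stride ``step_bp`` while they fit; if the
    last full window ends short of the chromosome end one trailing truncated
    window is added so coverage is complete.
    """
    w, s = params.window_bp, params.step_bp
    last_full = max(1, chrom_len - w + 1)
    starts = list(range(1, last_full + 1, s))
    if starts[-1] + w - 1 < chrom_len:
        starts.append(starts[-1] + s)
    return np.asarray(starts, dtype=np.int64)


def fst_windowed(
    sites: pd.DataFrame, params: ScanParams, chrom_lens: dict[str, int]
) -> pd.DataFrame:
    """Windowed ratio-of-averages Fst over per-site components.

    Windows tile each chromosome from bp 1 with stride ``step_bp``; a site
    at position p belongs to window [start, start+window-1] when
    start <= p <= end.  Returns chrom, start, end, n_snps, weighted_fst
    (sum a / sum a+b+c) and mean_fst (mean of defined per-site theta); empty
    windows carry NaN statistics.
    """
    rows = []
    for chrom, clen in chrom_lens.items():
        sub = sites[sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        a = sub["a"].to_numpy(dtype=float)
        abc = a + sub["b"].to_numpy(dtype=float) + sub["c"].to_numpy(dtype=float)
        theta = sub["theta"].to_numpy(dtype=float)
        for start in window_starts(int(clen), params):
            end = min(start + params.window_bp - 1, int(clen))
            inw = (pos >= start) & (pos <= end)
            n_snps = int(inw.sum())
            ok = inw & ~np.isnan(abc)
            den = abc[ok].sum()
            weighted = a[ok].sum() / den if ok.any() and den != 0 else np.nan
            th = theta[inw]
            th = th[~np.isnan(th)]
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "n_snps": n_snps,
                    "weighted_fst": weighted,
                    "mean_fst": th.mean() if th.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy pairwise LD pruning (plink ``--indep-pairwise`` style).

    A window of ``window_snps`` variants slides by ``step_snps``; within each
    window, while any kept pair has squared dosage correlation > ``r2_max``,
    the pair member with lower MAF is dropped (ties: the later variant).
    Returns sorted indices of kept variants.
    """
    if gm.n_variants < 1:
        raise ValueError("need at least one variant")
    dos = gm.dosages()
    col_mean = np.nanmean(dos, axis=0)
    col_mean = np.nan_to_num(col_mean)
    filled = np.where(np.isnan(dos), col_mean[None, :], dos)
    p = col_mean / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = np.ones(gm.n_variants, dtype=bool)
    for w0 in range(0, max(1, gm.n_variants - 1), step_snps):
        idx = np.flatnonzero(keep[w0 : w0 + window_snps]) + w0
        if idx.size < 2:
            if w0 + window_snps >= gm.n_variants:
                break
            continue
        sub = filled[:, idx]
        sd = sub.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(sub, rowvar=False)
        r2 = np.nan_to_num(r**2)
        np.fill_diagonal(r2, 0.0)
        r2[sd == 0, :] = 0.0
        r2[:, sd == 0] = 0.0
        alive = np.ones(idx.size, dtype=bool)
        while True:
            m = np.where(np.outer(alive, alive), r2, 0.0)
            i, j = np.unravel_index(np.argmax(m), m.shape)
            if m[i, j] <= r2_max:
                break
            gi, gj = idx[i], idx[j]
            if maf[gi] < maf[gj]:
                drop = i
            elif maf[gj] < maf[gi]:
                drop = j
            else:
                drop = max(i, j)  # tie: later variant
            alive[drop] = False
            keep[idx[drop]] = False
        if w0 + window_snps >= gm.n_variants:
            break
    return np.flatnonzero(keep)


def pca(gm: GenotypeMatrix, k: int, standardize: bool = True) -> np.ndarray:
    """Sample coordinates on the first k principal components of the dosage
    matrix (missing dosages mean-imputed; optional 1/sqrt(p(1-p)) scaling).

    Coordinates are deterministic up to the sign of each axis.
    """
    if k > min(gm.n_samples, gm.n_variants):
        raise ValueError(
            f"k={k} exceeds min(n_samples, n_variants)="
            f"{min(gm.n_samples, gm.n_variants)}"
        )
    from sklearn.decomposition import PCA

    dos = gm.dosages()
    col_mean = np.nan_to_num(np.nanmean(dos, axis=0))
    filled = np.where(np.isnan(dos), col_mean[None, :], dos)
    centered = filled - col_mean[None, :]
    if standardize:
        p = col_mean / 2.0
        scale = np.sqrt(np.clip(p * (1.0 - p), 0.0, None))
        nz = scale > 0
        centered[:, nz] = centered[:, nz] / scale[nz]
        centered[:, ~nz] = 0.0
    return PCA(n_components=k, svd_solver="full").fit_transform(centered)
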