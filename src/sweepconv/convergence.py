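"""Cross-breed Fst combination, candidate selection, gene mapping and
cross-species convergence testing.

The sheep arm combines two breeds' per-SNP case/control Fst values on their
shared SNPs via the root mean square Fst_RMS = sqrt((F1^2 + F2^2)/2)
(negative or undefined per-site estimates are excluded and tallied).  Top
windows/SNPs become candidates, genes overlapping them (wholly or
partially) become positively-selected-gene (PSG) candidates, and the
convergent set is the intersection of one species' Fst+nSL-shared genes
with the other species' Fst_RMS genes, with a hypergeometric (or
permutation) overlap significance against a gene background.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sweepconv.io import GeneModel

logger = logging.getLogger(__name__)


@dataclass
class ThresholdConfig:
    """Candidate-selection conventions for the two species' scans.

    Each arm may select by top fraction of the ranked statistic or by a
    fixed cutoff; the defaults are the printed genome-scale conventions
    (goat windows: cutoff 0.05 / top 0.8%; sheep SNPs: cutoff 0.3 /
    top 0.7%; |nSL| >= 6).
    """

    goat_mode: str = "fraction"
    goat_value: float = 0.008
    sheep_mode: str = "fraction"
    sheep_value: float = 0.007
    nsl_threshold: float = 6.0

    def __post_init__(self) -> None:
        for mode, value in ((self.goat_mode, self.goat_value), (self.sheep_mode, self.sheep_value)):
            if mode not in ("fraction", "cutoff"):
                raise ValueError(f"mode must be 'fraction' or 'cutoff', got {mode!r}")
            if mode == "fraction" and not (0 < value <= 1):
                raise ValueError(f"fraction must lie in (0, 1], got {value}")


@dataclass
class CandidateSet:
    """Threshold-passing windows or SNPs with selection provenance."""

    kind: str  # "window" | "snp"
    table: pd.DataFrame  # window: chrom,start,end,value; snp: chrom,pos,value
    implied_cutoff: float
    implied_fraction: float
    provenance: str = ""


@dataclass
class ConvergenceReport:
    """Gene-level convergence between the two species' selection scans."""

    goat_fst_genes: set[str]
    goat_nsl_genes: set[str]
    goat_shared_genes: set[str]
    sheep_genes: set[str]
    convergent_genes: set[str]
    overlap_p: float | None = None
    extra: dict = field(default_factory=dict)


def fst_rms(df1: pd.DataFrame, df2: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-SNP root-mean-square of two breeds' Fst on their shared sites.

    ``df1``/``df2`` need columns chrom, pos, theta.  Sites absent from
    either breed, or with a negative or undefined theta in either, are
    excluded; the returned info dict tallies the exclusions.
    """
    merged = df1[["chrom", "pos", "theta"]].merge(
        df2[["chrom", "pos", "theta"]], on=["chrom", "pos"], suffixes=("_1", "_2")
    )
    if merged.empty:
        raise ValueError("no SNPs shared between the two breeds")
    t1 = merged["theta_1"].to_numpy(dtype=float)
    t2 = merged["theta_2"].to_numpy(dtype=float)
    undefined = np.isnan(t1) | np.isnan(t2)
    negative = (~undefined) & ((t1 < 0) | (t2 < 0))
    ok = ~(undefined | negative)
    out = merged.loc[ok, ["chrom", "pos"]].copy()
    out["fst_1"] = t1[ok]
    out["fst_2"] = t2[ok]
    out["fst_rms"] = np.sqrt((t1[ok] ** 2 + t2[ok] ** 2) / 2.0)
    info = {
        "n_shared": int(len(merged)),
        "n_undefined_dropped": int(undefined.sum()),
        "n_negative_dropped": int(negative.sum()),
        "n_used": int(ok.sum()),
    }
    return out.reset_index(drop=True), info


def select_candidates(
    table: pd.DataFrame, value_col: str, mode: str, value: float, kind: str = "snp"
) -> CandidateSet:
    """Select extreme-statistic candidates by top fraction or fixed cutoff.

    Fraction mode keeps the top ceil(fraction * N) values after a
    descending sort, extending to all boundary ties; cutoff mode keeps
    values >= cutoff.  Both the implied cutoff and the implied fraction are
    recorded so either convention can be audited.
    """
    vals = table[value_col].to_numpy(dtype=float)
    defined = ~np.isnan(vals)
    if not defined.any():
        raise ValueError("no defined statistic values to select from")
    sub = table.loc[defined].reset_index(drop=True)
    v = vals[defined]
    n = v.size
    if mode == "fraction":
        k = math.ceil(value * n)
        order = np.sort(v)[::-1]
        cutoff = order[k - 1]
        keep = v >= cutoff
    elif mode == "cutoff":
        cutoff = value
        keep = v >= cutoff
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    out = sub.loc[keep].copy()
    sort_cols = ["chrom", "start"] if "start" in out.columns else ["chrom", "pos"]
    out = out.sort_values(sort_cols).reset_index(drop=True)
    return CandidateSet(
        kind=kind,
        table=out,
        implied_cutoff=float(cutoff),
        implied_fraction=float(keep.sum() / n),
        provenance=f"{mode}={value}",
    )


def annotate_candidates(cands: CandidateSet, genes: list[GeneModel]) -> set[str]:
    """Genes wholly or partially overlapping candidate windows / covering
    candidate SNPs (1-based inclusive on both sides)."""
    table = cands.table
    cand_chroms = set(map(str, table["chrom"].unique()))
    gene_chroms = {g.chrom for g in genes}
    if cand_chroms and not (cand_chroms & gene_chroms):
        logger.warning(
            "no shared chromosome names between candidates (%s) and genes (%s)",
            sorted(cand_chroms),
            sorted(gene_chroms),
        )
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    hits: set[str] = set()
    for _, row in table.iterrows():
        chrom = str(row["chrom"])
        if cands.kind == "window":
            lo, hi = int(row["start"]), int(row["end"])
        else:
            lo = hi = int(row["pos"])
        for g in by_chrom.get(chrom, []):
            if g.start <= hi and g.end >= lo:
                hits.add(g.gene_id)
    return hits


def _normalize(genes: set[str], ortholog_map: dict[str, str] | None) -> set[str]:
    if ortholog_map:
        lut = {k.upper(): v.upper() for k, v in ortholog_map.items()}
        return {lut.get(g.upper(), g.upper()) for g in genes}
    return {g.upper() for g in genes}


def build_convergence(
    goat_fst_genes: set[str],
    goat_nsl_genes: set[str],
    sheep_genes: set[str],
    ortholog_map: dict[str, str] | None = None,
) -> ConvergenceReport:
    """Intersect gene sets across scans and species by case-normalized
    symbol (or through an explicit ortholog map)."""
    gf = _normalize(goat_fst_genes, ortholog_map)
    gn = _normalize(goat_nsl_genes, ortholog_map)
    sh = _normalize(sheep_genes, ortholog_map)
    shared = gf & gn
    return ConvergenceReport(
        goat_fst_genes=gf,
        goat_nsl_genes=gn,
        goat_shared_genes=shared,
        sheep_genes=sh,
        convergent_genes=shared & sh,
    )


def overlap_significance(
    k: int,
    n: int,
    K: int,
    N: int,
    method: str = "hypergeometric",
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """P(overlap >= k) between a size-n and a size-K gene set drawn from a
    background of N genes.

    Hypergeometric: exact upper tail.  Permutation: seeded draws of the
    overlap under the null with the +1/(B+1) finite-sample correction.
    """
    if not (0 <= k <= min(n, K) <= N):
        raise ValueError(f"require 0 <= k <= min(n, K) <= N, got k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    if method == "hypergeometric":
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    if method == "permutation":
        rng = np.random.default_rng(seed)
        draws = rng.hypergeometric(K, N - K, n, size=n_perm)
        return float((1 + (draws >= k).sum()) / (n_perm + 1))
    raise ValueError(f"unknown method {method!r}")
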