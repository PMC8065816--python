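"""Hypergeometric gene-set enrichment, cross-species term convergence, and
the cohort association tests (Mann-Whitney U, chi-squared / Fisher).

Term maps are user-supplied GMT-like TSV files (term_id, name, then member
gene symbols); no live GO/KEGG retrieval and no GO-graph propagation.
Enrichment is a plain one-sided hypergeometric over-representation test
with a per-term significance threshold (default p < 0.01) and no
term-level multiple-testing correction by default, with BH available
behind a flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TermAnnotation:
    """One GO/KEGG-style term with its member gene symbols."""

    term_id: str
    name: str
    members: set[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id} has no members")


def read_term_map(path) -> list[TermAnnotation]:
    """Read a GMT-like TSV: term_id <tab> name <tab> gene1 <tab> gene2 ..."""
    terms = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed term line: {line!r}")
            terms.append(TermAnnotation(parts[0], parts[1], set(parts[2:])))
    return terms


def write_term_map(terms: list[TermAnnotation], path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.name] + sorted(t.members)) + "\n")


def hypergeom_enrich(
    query: set[str],
    terms: list[TermAnnotation],
    background: set[str],
    alpha: float = 0.01,
    ontology: dict[str, str] | None = None,
    ontology_filter: str | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each term.

    Term members are intersected with the background before testing; the
    upper tail P(X >= k) is reported per term with X ~ Hypergeom(N, K, n).
    ``ontology``/``ontology_filter`` optionally restrict GO terms to one
    namespace (e.g. biological process).  Results are sorted by ascending
    p (ties by term_id); ``significant`` flags p < alpha (on BH q-values
    instead when ``bh_correct``).
    """
    if not query:
        raise ValueError("empty query gene set")
    if not background:
        raise ValueError("empty background gene set")
    query = {g.upper() for g in query}
    background = {g.upper() for g in background}
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N = len(background)
    n = len(query)
    rows = []
    for t in terms:
        if ontology_filter and ontology is not None:
            if ontology.get(t.term_id) != ontology_filter:
                continue
        members = {m.upper() for m in t.members} & background
        if not members:
            continue
        K = len(members)
        hit = sorted(query & members)
        k = len(hit)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": t.term_id,
                "name": t.name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "pvalue": p,
                "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
                "hits": ",".join(hit),
            }
        )
    res = pd.DataFrame(rows).sort_values(["pvalue", "term_id"]).reset_index(drop=True)
    if res.empty:
        res["significant"] = pd.Series(dtype=bool)
        return res
    if bh_correct:
        from sweepconv.expression import bh_adjust

        res["qvalue"] = bh_adjust(res["pvalue"].to_numpy())
        res["significant"] = res["qvalue"] < alpha
    else:
        res["significant"] = res["pvalue"] < alpha
    return res


_KEGG_RE = re.compile(r"^(?:ko|hsa|map)(\d+)$", re.IGNORECASE)


def normalize_term_key(term_id: str) -> str:
    """Normalize a term id for cross-species matching.

    KEGG-style ids drop their organism/ontology prefix (ko04380 and
    hsa04380 are the same pathway); GO ids and anything else match
    verbatim (case-insensitively).
    """
    m = _KEGG_RE.match(term_id.strip())
    if m:
        return m.group(1)
    return term_id.strip().upper()


def convergent_terms(
    results_a: pd.DataFrame, results_b: pd.DataFrame, normalize_kegg: bool = True
) -> pd.DataFrame:
    """Significant terms shared by two species' enrichment results.

    Inputs are :func:`hypergeom_enrich` frames already filtered (or
    flagged) at their alpha; only rows with ``significant`` True are
    intersected, by normalized term key.
    """
    def sig_keys(df: pd.DataFrame) -> dict[str, pd.Series]:
        sub = df[df["significant"]] if "significant" in df.columns else df
        out = {}
        for _, row in sub.iterrows():
            key = normalize_term_key(row["term_id"]) if normalize_kegg else row["term_id"]
            out.setdefault(key, row)
        return out

    a = sig_keys(results_a)
    b = sig_keys(results_b)
    rows = []
    for key in sorted(set(a) & set(b)):
        rows.append(
            {
                "term_key": key,
                "term_id_a": a[key]["term_id"],
                "term_id_b": b[key]["term_id"],
                "name": a[key]["name"],
                "pvalue_a": a[key]["pvalue"],
                "pvalue_b": b[key]["pvalue"],
            }
        )
    return pd.DataFrame(
        rows, columns=["term_key", "term_id_a", "term_id_b", "name", "pvalue_a", "pvalue_b"]
    )


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    ``exact`` enumerates the permutation distribution (no ties, n1+n2 <=
    20); ``normal`` uses the tie-corrected normal approximation with 0.5
    continuity correction; ``auto`` picks exact when admissible.  Returns
    (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (not has_ties and x.size + y.size <= 20) else "normal"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode is invalid with ties; use mode='normal'")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif mode == "normal":
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


def genotype_association(table, n_mc: int = 100_000, seed: int = 0) -> tuple[str, float, float]:
    """Genotype x phenotype-class association test.

    Pearson chi-squared (no continuity correction) when every expected
    count is >= 5, otherwise Fisher's exact test (2x2: exact two-sided by
    summing tables as or less probable; larger tables: seeded Monte-Carlo
    permutation of the chi-squared statistic conditional on the margins).
    Returns (test_name, statistic, p).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a contingency table with >= 2 rows and columns")
    if np.any(obs < 0) or np.any(obs != np.round(obs)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("contingency table has an all-zero row or column")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if np.all(expected >= 5):
        chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
        return "chi2", float(chi2), float(p)
    if obs.shape == (2, 2):
        res = stats.fisher_exact(obs.astype(int), alternative="two-sided")
        return "fisher", float(res[0]), float(res[1])
    # r x c Fisher fallback: conditional Monte-Carlo on the chi-squared statistic
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(obs.shape[0]), obs.sum(axis=1).astype(int))
    col_labels = np.repeat(np.arange(obs.shape[1]), obs.sum(axis=0).astype(int))
    stat_obs = _chi2_stat(obs, expected)
    count = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        sim = np.zeros_like(obs)
        np.add.at(sim, (row_labels, perm), 1.0)
        if _chi2_stat(sim, expected) >= stat_obs - 1e-12:
            count += 1
    return "fisher_mc", float(stat_obs), float((count + 1) / (n_mc + 1))


def _chi2_stat(obs: np.ndarray, expected: np.ndarray) -> float:
    return float(((obs - expected) ** 2 / expected).sum())
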