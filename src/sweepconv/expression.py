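"""Differential-expression calling from DE summary tables and cross-species
DEG convergence.

The pipeline consumes per-gene DE summaries (gene, log2 fold change HG vs
LG, p-value) for each species x estrous phase (FP follicular, LP luteal).
P-values are Benjamini-Hochberg adjusted within each table; a gene is a DEG
when q < q_max and |log2FC| >= lfc_min.  Convergent DEGs are the per-phase
cross-species intersections; expression direction is reported but not
required to agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DEGThresholds:
    """DEG acceptance thresholds: q-value strictly below ``q_max`` and
    |log2FC| at least ``lfc_min``.

    NOTE: the defaults (q < 0.5, |lfc| >= 0.24) are deliberately permissive
    — they reproduce the source study's printed criteria.  Use
    :meth:`strict` (q < 0.05, |lfc| >= 1) for a conventional analysis.
    """

    q_max: float = 0.5
    lfc_min: float = 0.24

    def __post_init__(self) -> None:
        if not (0 < self.q_max <= 1):
            raise ValueError("q_max must lie in (0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")

    @classmethod
    def strict(cls) -> "DEGThresholds":
        return cls(q_max=0.05, lfc_min=1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the input
    order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_degs(records: pd.DataFrame, thr: DEGThresholds | None = None) -> pd.DataFrame:
    """Call DEGs from a DE summary table.

    ``records`` needs columns gene, log2fc, pvalue and optionally species
    and phase; q-values are computed by BH within each (species, phase)
    table independently.  Returns the table with qvalue, is_deg and
    direction ('up' = higher in HG) columns.  A duplicated gene within one
    table is an error.
    """
    thr = thr or DEGThresholds()
    df = records.copy()
    group_cols = [c for c in ("species", "phase") if c in df.columns]
    parts = [(None, df)] if not group_cols else list(df.groupby(group_cols, sort=False))
    out = []
    for key, part in parts:
        dup = part["gene"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate gene(s) in table {key}: {sorted(part.loc[dup, 'gene'].unique())}"
            )
        part = part.copy()
        part["qvalue"] = bh_adjust(part["pvalue"].to_numpy())
        out.append(part)
    df = pd.concat(out, ignore_index=True)
    lfc = df["log2fc"].to_numpy(dtype=float)
    df["is_deg"] = (df["qvalue"] < thr.q_max) & (np.abs(lfc) >= thr.lfc_min)
    df["direction"] = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    return df


def deg_sets(called: pd.DataFrame) -> dict[tuple[str, str], set[str]]:
    """DEG symbol sets keyed by (species, phase) from a called table."""
    sets: dict[tuple[str, str], set[str]] = {}
    for (sp, ph), part in called.groupby(["species", "phase"], sort=False):
        sets[(sp, ph)] = set(part.loc[part["is_deg"], "gene"].str.upper())
    return sets


def convergent_degs(
    goat: dict[str, set[str]],
    sheep: dict[str, set[str]],
    goat_directions: dict[str, dict[str, str]] | None = None,
    sheep_directions: dict[str, dict[str, str]] | None = None,
    ortholog_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-phase cross-species DEG intersection by case-normalized symbol.

    Direction concordance is reported (when direction maps are supplied)
    but never required for membership.  Returns columns phase, gene,
    concordant.
    """
    lut = {k.upper(): v.upper() for k, v in (ortholog_map or {}).items()}

    def norm(genes: set[str]) -> set[str]:
        return {lut.get(g.upper(), g.upper()) for g in genes}

    rows = []
    for phase in sorted(set(goat) | set(sheep)):
        shared = norm(goat.get(phase, set())) & norm(sheep.get(phase, set()))
        for gene in sorted(shared):
            concordant = None
            if goat_directions and sheep_directions:
                dg = {k.upper(): v for k, v in goat_directions.get(phase, {}).items()}.get(gene)
                ds = {k.upper(): v for k, v in sheep_directions.get(phase, {}).items()}.get(gene)
                if dg is not None and ds is not None:
                    concordant = dg == ds
            rows.append({"phase": phase, "gene": gene, "concordant": concordant})
    return pd.DataFrame(rows, columns=["phase", "gene", "concordant"])


def read_de_table(path, species: str | None = None, phase: str | None = None) -> pd.DataFrame:
    """Read a DE summary TSV (gene, log2fc, pvalue[, qvalue]) and tag it."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "log2fc", "pvalue"}
    if not required <= set(df.columns):
        raise ValueError(f"DE table {path} must have columns {sorted(required)}")
    if species is not None:
        df["species"] = species
    if phase is not None:
        df["phase"] = phase
    return df
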