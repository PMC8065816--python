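"""Synthetic inputs with known truth for every pipeline stage.

Genotypes follow the Balding-Nichols model: each SNP has an ancestral
frequency p ~ Uniform(0.05, 0.95) and each group (LG/HG) draws its own
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so the expected Weir-Cockerham
Fst between the groups is approximately the differentiation parameter F.
This directly parameterizes the quantity the scan estimates, which keeps
estimator-recovery checks analytic; no recombination model is simulated
beyond the sweep construction.

Selective sweeps are injected per locus by (1) raising the HG derived-allele
frequency by delta_freq (capped at 0.98) and (2) copying a single core
haplotype into every HG derived carrier across the core window, with a
per-site copy-error rate growing linearly from 0 at the focal SNP to 0.2 at
the window edge.  This is a deliberate stand-in for a hard sweep: it
guarantees both elevated differentiation (Fst) and the extended shared
haplotypes the nSL statistic detects, without a forward simulator.

Gene annotations, DE summary tables and GMT-like term maps are generated
with planted positives, all recorded in a :class:`TruthTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from sweepconv.io import GeneModel, GenotypeMatrix


@dataclass(frozen=True)
class SweepLocus:
    """One injected sweep: position, HG frequency shift, core width in bp."""

    chrom: str
    pos: int
    delta_freq: float
    core_width: int

    def __post_init__(self) -> None:
        if not (0 < self.delta_freq <= 1):
            raise ValueError("delta_freq must lie in (0, 1]")


@dataclass
class SimParams:
    """Balding-Nichols population-pair simulation parameters."""

    n_chrom: int = 4
    chrom_len: int = 10_000_000
    n_snps: int = 8_000
    n_samples_per_group: int = 50
    baseline_F: float = 0.05
    sweep_loci: list[SweepLocus] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0
    position_seed: int | None = None  # share SNP positions across cohorts (chip-style)

    def __post_init__(self) -> None:
        if not (0 < self.baseline_F < 1):
            raise ValueError("baseline_F must lie in (0, 1)")
        for sw in self.sweep_loci:
            if not (1 <= sw.pos <= self.chrom_len):
                raise ValueError(f"sweep position {sw.pos} outside chromosome bounds")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @classmethod
    def demo(cls, seed: int = 0) -> "SimParams":
        """The desk-scale three-sweep scenario used by the end-to-end demo:
        weak background differentiation (F=0.05) and three strong sweeps
        (delta_freq=0.8, ~50-SNP cores) on chromosomes 1-3.

        Sizes are chosen for estimability rather than realism: 100
        diploids/group keeps the minor allele pool >= 4 haplotypes at the
        capped sweep frequency (0.98), so SL_A stays estimable at the focal
        SNP, and 24,000 background SNPs keep every derived-allele-frequency
        bin background-dominated (the ~300 sweep-core sites are < 2% of the
        genome) so bin standardization is not inflated by the sweeps
        themselves.
        """
        p = cls(seed=seed, n_samples_per_group=100, n_snps=24_000)
        snps_per_chrom = p.n_snps // p.n_chrom
        core_bp = int(round(50 * p.chrom_len / snps_per_chrom))  # ~50 SNPs wide
        sweeps = [
            SweepLocus(f"chr{i + 1}", p.chrom_len // 2, 0.8, core_bp) for i in range(3)
        ]
        return replace(p, sweep_loci=sweeps)


@dataclass
class TruthTable:
    """Ground truth for planted signals across all generated inputs."""

    selected_loci: list[tuple[str, int]] = field(default_factory=list)
    true_psg_ids: set[str] = field(default_factory=set)
    true_deg_ids: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    true_convergent_genes: dict[str, set[str]] = field(default_factory=dict)
    true_enriched_terms: set[str] = field(default_factory=set)


def simulate_population_pair(params: SimParams) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate one breed's LG/HG contrast with optional injected sweeps.

    Deterministic for a fixed ``params.seed``; phased haplotypes; sweep
    loci are snapped to the nearest simulated SNP (recorded in the truth
    table at the snapped position).
    """
    rng = np.random.default_rng(params.seed)
    pos_rng = (
        rng if params.position_seed is None else np.random.default_rng(params.position_seed)
    )
    chroms = params.chrom_names()
    per_chrom = _split_counts(params.n_snps, params.n_chrom)
    chrom_arr: list[str] = []
    pos_list: list[np.ndarray] = []
    for c, k in zip(chroms, per_chrom):
        pos = np.sort(pos_rng.choice(np.arange(1, params.chrom_len + 1), size=k, replace=False))
        pos_list.append(pos)
        chrom_arr.extend([c] * k)
    pos_all = np.concatenate(pos_list)
    chrom_all = np.array(chrom_arr, dtype=object)
    n_var = pos_all.size

    F = params.baseline_F
    p_anc = rng.uniform(0.05, 0.95, size=n_var)
    alpha = p_anc * (1 - F) / F
    beta = (1 - p_anc) * (1 - F) / F
    n = params.n_samples_per_group
    hap_groups = {}
    group_freqs = {}
    for grp in ("LG", "HG"):
        p_g = rng.beta(alpha, beta)
        group_freqs[grp] = p_g
        hap_groups[grp] = (rng.random((2 * n, n_var)) < p_g[None, :]).astype(np.int8)

    truth = TruthTable()
    for sw in params.sweep_loci:
        on_chrom = np.flatnonzero(chrom_all == sw.chrom)
        if on_chrom.size == 0:
            raise ValueError(f"sweep chromosome {sw.chrom} not simulated")
        s = on_chrom[np.argmin(np.abs(pos_all[on_chrom] - sw.pos))]
        q_new = group_freqs["HG"][s] + sw.delta_freq
        if q_new > 0.98:
            q_new = 0.98
        # set (not resample) the HG derived frequency: a deterministic carrier
        # count keeps both allele pools non-degenerate at the capped frequency
        H = hap_groups["HG"]
        n_der = int(round(q_new * 2 * n))
        carriers = rng.permutation(2 * n)[:n_der]
        H[:, s] = 0
        H[carriers, s] = 1
        if carriers.size >= 2:
            region = on_chrom[np.abs(pos_all[on_chrom] - pos_all[s]) <= sw.core_width]
            dist = np.abs(pos_all[region] - pos_all[s]) / max(sw.core_width, 1)
            err = 0.2 * dist  # copy fidelity decays with distance from the core
            template = H[carriers[0], region].copy()
            for r in carriers[1:]:
                keep_own = rng.random(region.size) < err
                H[r, region] = np.where(keep_own, H[r, region], template)
        truth.selected_loci.append((sw.chrom, int(pos_all[s])))

    sample_ids = [f"LG_{i:03d}" for i in range(n)] + [f"HG_{i:03d}" for i in range(n)]
    labels = {sid: sid[:2] for sid in sample_ids}
    haps = np.vstack([hap_groups["LG"], hap_groups["HG"]])  # (4n, n_var)
    geno = haps.reshape(2 * n, 2, n_var).transpose(0, 2, 1)  # (2n samples, n_var, 2)
    geno = np.ascontiguousarray(geno)
    if params.missing_rate > 0:
        miss = rng.random((2 * n, n_var)) < params.missing_rate
        geno = geno.copy()
        geno[miss] = -1
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        group_labels=labels,
        chrom=chrom_all,
        pos=pos_all,
        ref=np.array(["A"] * n_var, dtype=object),
        alt=np.array(["G"] * n_var, dtype=object),
        genotypes=geno,
        phased=np.ones(n_var, dtype=bool),
    )
    gm.validate()
    return gm, truth


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    rem = total % parts
    return [base + (1 if i < rem else 0) for i in range(parts)]


def simulate_gene_annotation(
    params: SimParams,
    truth: TruthTable,
    n_genes: int,
    gene_len: int,
    seed: int | None = None,
) -> tuple[list[GeneModel], TruthTable]:
    """Non-overlapping genes at uniform positions, one covering each sweep.

    Every locus in ``truth.selected_loci`` is covered by exactly one gene
    (centered on it); those gene ids become ``true_psg_ids``.
    """
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    chroms = params.chrom_names()
    if n_genes * gene_len > 0.5 * params.n_chrom * params.chrom_len:
        raise ValueError("gene packing infeasible: genes would cover >50% of the genome")
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    gid = 0

    def overlaps(chrom: str, start: int, end: int) -> bool:
        return any(start <= e and end >= s for s, e in placed[chrom])

    for chrom, pos in truth.selected_loci:
        start = max(1, pos - gene_len // 2)
        end = min(params.chrom_len, start + gene_len - 1)
        if overlaps(chrom, start, end):
            raise ValueError(f"sweep gene at {chrom}:{pos} overlaps a previous sweep gene")
        gid += 1
        g = GeneModel(f"G{gid:04d}", f"G{gid:04d}", chrom, start, end)
        genes.append(g)
        placed[chrom].append((start, end))
        truth.true_psg_ids.add(g.gene_id)

    attempts = 0
    while gid < n_genes:
        attempts += 1
        if attempts > 200 * n_genes:
            raise ValueError("gene packing infeasible: too many placement rejections")
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, params.chrom_len - gene_len + 2))
        end = start + gene_len - 1
        if overlaps(chrom, start, end):
            continue
        gid += 1
        genes.append(GeneModel(f"G{gid:04d}", f"G{gid:04d}", chrom, start, end))
        placed[chrom].append((start, end))
    return sorted(genes, key=lambda g: (g.chrom, g.start)), truth


def simulate_de_tables(
    genes: list[str],
    deg_fraction: float,
    lfc_mean: float,
    convergent_ids: dict[str, set[str]] | None,
    seed: int,
    truth: TruthTable | None = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """DE summary tables for 2 species x 2 phases with planted DEGs.

    Null genes: p ~ Uniform(0,1), log2FC ~ Normal(0, 0.1).  True DEGs: p ~
    Beta(0.2, 8), |log2FC| ~ Normal(lfc_mean, 0.2) with random sign.
    ``convergent_ids`` maps phase -> genes planted as true DEGs in BOTH
    species at that phase.  Returns one long frame with columns gene,
    log2fc, pvalue, species, phase, plus the updated truth table.
    """
    if not (0 <= deg_fraction < 1):
        raise ValueError("deg_fraction must lie in [0, 1)")
    truth = truth or TruthTable()
    convergent_ids = convergent_ids or {}
    universe = set(genes)
    for phase, ids in convergent_ids.items():
        if not ids <= universe:
            raise ValueError(f"convergent ids for {phase} not all in the gene universe")
        truth.true_convergent_genes[phase] = {g.upper() for g in ids}
    rng = np.random.default_rng(seed)
    n = len(genes)
    gene_arr = np.array(sorted(genes))
    frames = []
    for species in ("goat", "sheep"):
        for phase in ("FP", "LP"):
            n_deg = int(round(deg_fraction * n))
            chosen = set(rng.choice(gene_arr, size=n_deg, replace=False)) if n_deg else set()
            chosen |= convergent_ids.get(phase, set())
            is_deg = np.isin(gene_arr, sorted(chosen))
            p = rng.uniform(0, 1, size=n)
            lfc = rng.normal(0, 0.1, size=n)
            k = int(is_deg.sum())
            if k:
                p[is_deg] = rng.beta(0.2, 8, size=k)
                mag = rng.normal(lfc_mean, 0.2, size=k)
                sign = rng.choice([-1.0, 1.0], size=k)
                lfc[is_deg] = sign * np.abs(mag)
            truth.true_deg_ids[(species, phase)] = {g.upper() for g in chosen}
            frames.append(
                pd.DataFrame(
                    {
                        "gene": gene_arr,
                        "log2fc": lfc,
                        "pvalue": p,
                        "species": species,
                        "phase": phase,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True), truth


def simulate_term_map(
    genes: set[str],
    n_terms: int,
    enriched_terms: list[tuple[str, set[str]]],
    seed: int,
    truth: TruthTable | None = None,
):
    """GMT-like term map: background terms with uniform members plus
    planted enriched terms (their subset + a few random members)."""
    from sweepconv.enrich import TermAnnotation

    truth = truth or TruthTable()
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(genes))
    terms: list[TermAnnotation] = []
    for term_id, subset in enriched_terms:
        if not set(subset) <= genes:
            raise ValueError(f"planted genes for {term_id} not in the gene universe")
        extra_n = int(rng.integers(3, 10))
        extra = set(rng.choice(universe, size=min(extra_n, universe.size), replace=False))
        terms.append(TermAnnotation(term_id, term_id, set(subset) | extra))
        truth.true_enriched_terms.add(term_id)
    for i in range(n_terms):
        size = int(rng.integers(10, 31))
        members = set(rng.choice(universe, size=min(size, universe.size), replace=False))
        terms.append(TermAnnotation(f"T{i + 1:04d}", f"background term {i + 1}", members))
    return terms, truth
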