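"""Genotype container, VCF/GFF3/BED input-output and SNP/sample quality control.

The pipeline starts from genotypes in VCF 4.x (biallelic SNPs only; the GT
field is required).  Internally genotypes live in a :class:`GenotypeMatrix`:
a samples x variants array of allele-code pairs with chromosome/position
metadata and case/control group labels ("LG" low-yield, "HG" high-yield).
Coordinates are 1-based inclusive throughout; BED input is converted on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


class VcfFormatError(ValueError):
    """Raised when a VCF lacks required structure (GT field, sorted positions)."""


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for a cohort of samples at biallelic SNPs.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, in column order of ``genotypes``.
    group_labels : dict
        Maps sample id -> group label (``"LG"`` / ``"HG"``).  May be empty
        for unlabelled cohorts (e.g. straight after reading an external VCF).
    chrom : ndarray of str, shape (n_variants,)
    pos : ndarray of int, shape (n_variants,)
        1-based positions, strictly increasing within each chromosome.
    ref, alt : ndarray of str, shape (n_variants,)
    genotypes : ndarray of int8, shape (n_samples, n_variants, 2)
        Allele codes 0 (REF), 1 (ALT) or -1 (missing).
    phased : ndarray of bool, shape (n_variants,)
        True iff every sample's genotype at the site used the ``|`` separator.
    """

    sample_ids: list[str]
    group_labels: dict[str, str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    phased: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        """Check container invariants; raise ValueError on violation."""
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if self.group_labels:
            missing = [s for s in self.sample_ids if s not in self.group_labels]
            if missing:
                raise ValueError(f"group_labels missing for samples: {missing}")
        if self.genotypes.shape != (self.n_samples, self.n_variants, 2):
            raise ValueError("genotypes shape inconsistent with metadata")
        codes = np.unique(self.genotypes)
        if not np.all(np.isin(codes, [MISSING, 0, 1])):
            raise ValueError("genotype allele codes must be 0, 1 or missing (-1)")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def samples_in_group(self, group: str) -> np.ndarray:
        """Indices of samples carrying ``group`` label."""
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group_labels.get(s) == group],
            dtype=int,
        )

    def dosages(self) -> np.ndarray:
        """ALT-allele dosage per sample per variant (float; NaN when any allele missing)."""
        g = self.genotypes
        d = g.sum(axis=2).astype(float)
        d[(g == MISSING).any(axis=2)] = np.nan
        return d

    def haplotypes(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Haplotype matrix (2*n_samples, n_variants) of 0/1/-1 allele codes.

        Only meaningful at phased sites; callers enforce phasing.
        """
        g = self.genotypes if sample_idx is None else self.genotypes[sample_idx]
        return g.transpose(0, 2, 1).reshape(-1, self.n_variants)

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            genotypes=self.genotypes[:, idx, :],
            phased=self.phased[idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        ids = [self.sample_ids[i] for i in idx]
        return replace(
            self,
            sample_ids=ids,
            group_labels={s: g for s, g in self.group_labels.items() if s in set(ids)},
            genotypes=self.genotypes[idx],
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 1-based inclusive coordinates."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class QCParams:
    """SNP/sample quality-control thresholds.

    Any threshold may be ``None`` to disable that criterion entirely
    (the "permissive" mode used on clean synthetic data).
    """

    min_sample_call_rate: float | None = 0.90
    autosomes: set[str] | None = None  # None = keep all chromosomes
    min_maf: float | None = 0.01
    max_snp_missing: float | None = 0.10
    min_hwe_p: float | None = 1e-6

    def __post_init__(self) -> None:
        for name in ("min_sample_call_rate", "min_maf", "max_snp_missing", "min_hwe_p"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def permissive(cls, autosomes: set[str] | None = None) -> "QCParams":
        return cls(None, autosomes, None, None, None)


@dataclass
class QCReport:
    """Counts removed per quality-control criterion."""

    n_samples_removed: int = 0
    n_non_autosomal: int = 0
    n_low_maf: int = 0
    n_high_missing: int = 0
    n_hwe_fail: int = 0
    removed_samples: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["sample_call_rate", "non_autosomal", "maf", "missingness", "hwe"],
                "n_removed": [
                    self.n_samples_removed,
                    self.n_non_autosomal,
                    self.n_low_maf,
                    self.n_high_missing,
                    self.n_hwe_fail,
                ],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, group_labels: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Multi-allelic records are skipped with a logged warning; a site is
    flagged phased iff every sample genotype at the site is phased.

    Raises
    ------
    VcfFormatError
        If the file has no GT field or positions are unsorted within a
        chromosome (the first offending record is named).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    phased: list[bool] = []
    gts: list[np.ndarray] = []
    n_multi = 0
    last: dict[str, int] = {}
    for v in vcf:
        if "GT" not in (v.FORMAT or []):
            raise VcfFormatError(f"record {v.CHROM}:{v.POS} has no GT field")
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise VcfFormatError(
                f"unsorted VCF: {v.CHROM}:{v.POS} follows {v.CHROM}:{last[v.CHROM]}"
            )
        last[v.CHROM] = v.POS
        rows = v.genotypes  # per sample: [allele0, allele1, phased]
        arr = np.full((len(samples), 2), MISSING, dtype=np.int8)
        ph = True
        for i, row in enumerate(rows):
            *alleles, is_ph = row
            ph = ph and bool(is_ph)
            for j, a in enumerate(alleles[:2]):
                arr[i, j] = MISSING if a < 0 else a
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        phased.append(ph)
        gts.append(arr)
    if n_multi:
        logger.warning("skipped %d multi-allelic record(s) in %s", n_multi, path)
    geno = (
        np.stack(gts, axis=1)
        if gts
        else np.empty((len(samples), 0, 2), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        sample_ids=samples,
        group_labels=dict(group_labels or {}),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=geno,
        phased=np.array(phased, dtype=bool),
    )
    gm.validate()
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT only; ``|`` separator iff the site is phased)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + gm.sample_ids) + "\n")
        for j in range(gm.n_variants):
            sep = "|" if gm.phased[j] else "/"
            toks = []
            for i in range(gm.n_samples):
                a, b = gm.genotypes[i, j]
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                toks.append(f"{sa}{sep}{sb}")
            row = [
                str(gm.chrom[j]),
                str(int(gm.pos[j])),
                ".",
                str(gm.ref[j]),
                str(gm.alt[j]),
                ".",
                ".",
                ".",
                "GT",
            ]
            fh.write("\t".join(row + toks) + "\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path, fmt: str = "gff3", feature_type: str = "gene") -> list[GeneModel]:
    """Read gene intervals from GFF3 or BED4.

    GFF3: only records of ``feature_type`` are kept; gene_id comes from the
    ``ID`` attribute and symbol from ``Name`` (falling back to the id).
    BED: 0-based half-open converted to 1-based inclusive.  Output is sorted
    by (chrom, start).
    """
    fmt = fmt.lower()
    genes: list[GeneModel] = []
    if fmt == "bed":
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name"],
            usecols=[0, 1, 2, 3],
            dtype={0: str, 3: str},
        )
        for i, row in df.iterrows():
            if row["start"] >= row["end"]:
                raise ValueError(f"BED line {i + 1}: start {row['start']} >= end {row['end']}")
            genes.append(
                GeneModel(
                    gene_id=str(row["name"]),
                    symbol=str(row["name"]),
                    chrom=str(row["chrom"]),
                    start=int(row["start"]) + 1,
                    end=int(row["end"]),
                )
            )
    elif fmt == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        for n, feat in enumerate(db.all_features(), start=1):
            if feat.featuretype != feature_type:
                continue
            ids = feat.attributes.get("ID")
            if not ids:
                raise ValueError(f"GFF3 feature #{n} ({feat.seqid}:{feat.start}) lacks ID attribute")
            name = feat.attributes.get("Name", ids)
            genes.append(
                GeneModel(
                    gene_id=ids[0],
                    symbol=name[0],
                    chrom=str(feat.seqid),
                    start=int(feat.start),
                    end=int(feat.end),
                    strand=feat.strand or ".",
                )
            )
    else:
        raise ValueError(f"unknown gene-model format: {fmt!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def write_gene_models_bed(genes: list[GeneModel], path) -> None:
    """Write gene models as BED4 (0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditions on the total sample size and minor-allele count and sums the
    probabilities of every heterozygote count whose conditional probability
    is at most that of the observed count.  Monomorphic sites return 1.0.
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0 or v != int(v):
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0
    # log P(n_het | n, n_minor) up to a shared constant
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    n_hom_minor = (n_minor - hets) // 2
    n_hom_major = n - hets - n_hom_minor
    logp = (
        hets * math.log(2.0)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(n_hom_minor + 1)
        - _lgamma_arr(n_hom_major + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = np.flatnonzero(hets == n_Aa)
    if obs.size == 0:
        raise ValueError(
            f"heterozygote count {n_Aa} impossible given {n_minor} minor alleles"
        )
    p_obs = p[obs[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def qc_filter(gm: GenotypeMatrix, params: QCParams) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample then variant quality control.

    Order: (1) samples with call rate <= ``min_sample_call_rate`` removed;
    then variants removed for (2) non-autosomal chromosome, (3) MAF <=
    ``min_maf``, (4) missingness >= ``max_snp_missing``, (5) HWE exact p <=
    ``min_hwe_p``.  Each variant is counted under the first criterion that
    removes it.  MAF/missingness/HWE use post-sample-removal genotypes.
    """
    report = QCReport()
    ok = (gm.genotypes != MISSING).all(axis=2)  # sample x variant called
    if params.min_sample_call_rate is not None and gm.n_variants > 0:
        call_rate = ok.mean(axis=1)
        keep = call_rate > params.min_sample_call_rate
        report.n_samples_removed = int((~keep).sum())
        report.removed_samples = [s for s, k in zip(gm.sample_ids, keep) if not k]
        if not keep.any():
            raise ValueError("empty cohort: all samples removed by call-rate filter")
        if report.n_samples_removed:
            gm = gm.take_samples(np.flatnonzero(keep))
            ok = (gm.genotypes != MISSING).all(axis=2)

    n_var = gm.n_variants
    keep_var = np.ones(n_var, dtype=bool)

    if params.autosomes is not None:
        bad = ~np.isin(gm.chrom.astype(str), list(params.autosomes))
        report.n_non_autosomal = int(bad.sum())
        keep_var &= ~bad

    dos = gm.dosages()
    n_called = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.nansum(dos, axis=0) / (2.0 * n_called)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    maf[n_called == 0] = 0.0

    if params.min_maf is not None:
        bad = keep_var & (maf <= params.min_maf)
        report.n_low_maf = int(bad.sum())
        keep_var &= ~bad

    if params.max_snp_missing is not None:
        missing_frac = 1.0 - ok.mean(axis=0) if gm.n_samples else np.zeros(n_var)
        bad = keep_var & (missing_frac >= params.max_snp_missing)
        report.n_high_missing = int(bad.sum())
        keep_var &= ~bad

    if params.min_hwe_p is not None:
        for j in np.flatnonzero(keep_var):
            d = dos[:, j]
            d = d[~np.isnan(d)].astype(int)
            counts = np.bincount(d, minlength=3)
            if hwe_exact_test(counts[0], counts[1], counts[2]) <= params.min_hwe_p:
                keep_var[j] = False
                report.n_hwe_fail += 1

    return gm.take_variants(np.flatnonzero(keep_var)), report
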