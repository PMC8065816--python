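# Methods

## The estimation problem

Two species each carry a within-breed case/control contrast for a
quantitative reproductive trait (litter size): a low-yield group (LG,
control) and a high-yield group (HG, case).  The pipeline looks for
*convergent* signals — genes and pathways that surface independently in
both species — from three evidence streams: allele-frequency
differentiation (F<sub>ST</sub>), haplotype structure in the case group
(nSL), and differential ovarian expression.

## Per-SNP F<sub>ST</sub>: Weir & Cockerham variance components

For two populations (r = 2) with per-site diploid sample sizes n₁, n₂,
allele frequencies p₁, p₂ and observed heterozygote proportions h₁, h₂,
the method-of-moments components are

    n̄  = (n₁+n₂)/2                    n_c = (2n̄ − Σnᵢ²/(2n̄)) / 1
    p̄  = Σnᵢpᵢ / (2n̄)               s²  = Σnᵢ(pᵢ−p̄)² / n̄
    h̄  = Σnᵢhᵢ / (2n̄)

    a = (n̄/n_c) [ s² − (p̄(1−p̄) − s²/2 − h̄/4) / (n̄−1) ]
    b = (n̄/(n̄−1)) [ p̄(1−p̄) − s²/2 − h̄(2n̄−1)/(4n̄) ]
    c = h̄/2

with θ = a/(a+b+c).  Components may legitimately be negative and are *not*
clipped at the site level; the nonnegativity filter exists only where the
cross-breed combination statistic requires it (below).  θ is undefined at
pooled-monomorphic sites (a+b+c = 0) and when n̄ = 1.  Multi-SNP summaries
use the ratio of averages Σa/Σ(a+b+c), which is consistent (unlike the
mean of ratios) and is the default window statistic.

Windows tile each chromosome from bp 1 with a 100-kb width and 50-kb step
(defaults); membership is inclusive on both ends.  Full windows start
while they fit; one trailing truncated window is appended when needed so
coverage reaches the chromosome end.

## Cross-breed combination: F<sub>ST,RMS</sub>

Two breeds' per-SNP θ values are combined on the intersection of their
sites as √((θ₁² + θ₂²)/2).  Sites where either estimate is negative or
undefined are excluded (and counted).  The RMS lies between max(θ₁,θ₂)/√2
and max(θ₁,θ₂), so a site must be elevated in at least one breed — and is
rewarded for being elevated in both.

## nSL in the case group

For a focal biallelic site, haplotypes split into ancestral (A) and
derived (D) carriers.  For one within-pool pair, the identity run is the
maximal contiguous interval of SNPs around the focal site on which the two
haplotypes agree, counted in segregating sites, focal site included
(minimum 1); runs reaching a chromosome edge are kept as-is (discarding
them is available behind a flag but off by default).  SL_A and SL_D are
pool-mean pairwise run lengths; nsl_raw = ln(SL_A/SL_D).  A sweep makes
derived carriers share long haplotypes, driving nsl_raw strongly negative.

Raw scores are z-standardized within 20 equal-width derived-allele-
frequency bins over (0,1) (population SD; bins with < 2 defined scores or
zero spread stay undefined).  Both the bin count and the candidate
threshold are configurable: at genome scale the conventional cutoff is
|nSL| ≥ 6, while desk-scale runs select a top fraction instead (see
below).  Ancestral allele defaults to the VCF REF; an explicit ancestral
array may override.  The scan requires phased genotypes and refuses
unphased input.

Implementation note: the genome scan shares each haplotype pair's
identity-run profile across all focal sites (one O(S) pass per pair),
giving O(m²S) per chromosome instead of O(m²S²); it is tested to agree
exactly with the brute-force pairwise definition.

## Candidate selection, gene mapping, convergence

Ranked statistics are thresholded either by a fixed cutoff or by a top
fraction (keep ⌈fN⌉ after a descending sort, extending to boundary ties);
the report always records both the implied cutoff and the implied
fraction so either convention can be audited.  Genes wholly *or partially*
overlapping a candidate window, or covering a candidate SNP, are
candidates (1-based inclusive intervals on both sides).  Cross-species
gene identity is by case-normalized symbol, optionally through a
two-column ortholog map.

Convergent selection candidates = (species-1 window-F<sub>ST</sub> genes ∩
species-1 nSL genes) ∩ species-2 F<sub>ST,RMS</sub> genes.  Overlap
significance is the hypergeometric upper tail P(X ≥ k) for X ~
Hypergeom(N, K, n) with configurable background N, or a seeded permutation
with the +1/(B+1) correction.  The null treats genes as exchangeable; a
gene-length- or LD-aware null is out of scope and noted as an extension.

## Expression and gene sets

DE summary tables (gene, log2FC of HG vs LG, p-value) per species × phase
(follicular FP / luteal LP) are BH-adjusted within each table
(q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j).  The default DEG thresholds are q < 0.5 and
|log2FC| ≥ 0.24 — deliberately permissive, reproducing the source
analysis's printed criteria; a `strict` preset (q < 0.05, |log2FC| ≥ 1) is
one flag away.  Convergent DEGs are the per-phase cross-species
intersections; direction concordance is reported, never required.

Enrichment is a plain one-sided hypergeometric over-representation test
over user-supplied GMT-like term maps, significant at p < 0.01 per term
with no term-level multiple-testing correction by default (BH behind a
flag); GO terms can be restricted to one namespace when an ontology map is
supplied.  Cross-species term convergence matches GO ids verbatim and
strips KEGG `ko`/`hsa`/`map` prefixes so ko04380 ≡ hsa04380.

## Cohort statistics

Group phenotype contrasts use a two-sided Mann–Whitney U (exact
enumeration when tie-free and n₁+n₂ ≤ 20, otherwise tie-corrected normal
approximation with 0.5 continuity correction).  Genotype × phenotype
tables use Pearson chi-squared without continuity correction when all
expected counts are ≥ 5, otherwise Fisher's exact test (2×2 exact;
larger tables via seeded conditional Monte-Carlo on the chi-squared
statistic).

## Quality control

Sample call rate > 0.90 (strict), then variants filtered in order:
non-autosomal, MAF ≤ 0.01, missingness ≥ 0.10, Hardy–Weinberg exact
p ≤ 10⁻⁶; each variant is counted under the first criterion that removes
it, and MAF uses non-missing alleles after sample removal.  The HWE test
is the standard conditional enumeration over heterozygote counts (no
mid-p).  Any threshold may be set to `None` to disable that criterion —
the "permissive" preset used on clean synthetic data.

## Synthetic data: what it emulates and what it does not

Genotypes follow the Balding–Nichols model: per SNP, ancestral frequency
p ~ U(0.05, 0.95) and group frequency p_g ~ Beta(p(1−F)/F, (1−p)(1−F)/F),
so the expected Weir–Cockerham F<sub>ST</sub> between the groups is ≈ F.
This directly parameterizes the quantity the scan estimates, keeping
recovery checks analytic.  Haplotype alleles are drawn independently per
site: there is **no background linkage disequilibrium, recombination map,
demography or chip ascertainment**.  Sweeps are injected per locus by
(1) setting the case-group derived-allele frequency to
min(p_HG + delta_freq, 0.98) as a deterministic carrier count, and
(2) copying one core haplotype into every derived carrier across the core
window with a per-site copy-error probability rising linearly from 0 at
the focal SNP to 0.2 at the core edge.  This is a deliberate stand-in for
a hard sweep — it guarantees elevated differentiation plus the extended
haplotype identity nSL detects, without a forward simulator.  Passing
tests therefore demonstrate estimator correctness and detection power
under this idealized model, not performance on real LD structure.

Gene annotations are non-overlapping uniform placements with one gene
centred on each sweep locus; DE tables draw null genes p ~ U(0,1),
log2FC ~ N(0, 0.1) and true DEGs p ~ Beta(0.2, 8), |log2FC| ~
N(lfc_mean, 0.2); term maps contain planted enriched terms plus uniform
background terms.  All outputs are bit-reproducible from (params, seed).

Under the Beta(0.2, 8) alternative the attainable sensitivity of DEG
calling at q < 0.05 (m = 2000, 5% true) is ≈ 0.41 — the p-value
distribution has a heavy right tail — and the recovery test asserts the
band computed from that distribution, with observed FDR ≈ 0.

## The demo scenario and its sizes

`sweepconv demo` simulates three cohorts — one "goat" LG/HG pair scanned
by windowed F<sub>ST</sub> + nSL, and two "sheep" breed pairs (sharing one
chip-like SNP position set) combined by F<sub>ST,RMS</sub> — on 4 × 10 Mb
chromosomes with background F = 0.05 and three sweeps (delta_freq = 0.8,
50-SNP cores) at the midpoints of chromosomes 1–3, plus 400 genes of
50 kb, DE tables (5% true DEGs, planted cross-species convergent DEGs)
and a term map with one planted term.

The scenario's sizes are chosen for estimability, not realism:

* **100 diploids per group** keeps the minor allele pool ≥ 4 haplotypes at
  the capped sweep frequency 0.98, so SL_A remains estimable at the focal
  SNP (with fewer haplotypes the focal-site nSL is undefined or rests on a
  single haplotype pair).
* **24,000 background SNPs** keep each derived-allele-frequency bin
  dominated by background sites: the three sweep cores contribute ~300
  elevated sites, and in a smaller genome they inflate their own bins'
  standard deviation, deflating every z-score.
* Selection uses the printed top fraction for windows (0.8% of ~800
  windows) and SNP fractions of 0.5% (nSL) and 0.2% (RMS), which keep the
  candidate *gene* sets at a few percent of the 400-gene universe —
  comparable selectivity to the genome-scale analysis, where the printed
  SNP fractions correspond to far sparser gene hits than they would in
  this dense toy genome.  The overlap background is N = 400 (the full toy
  gene universe).

With these sizes the demo completes in under a minute on one CPU and, on
every seed tried, places all three sweep sites in the top 1% of both
window F<sub>ST</sub> and |nSL| and recovers all three planted genes as
convergent with overlap p ≪ 0.01.

## Numerical and degenerate-input choices

* LD pruning (sliding 50-SNP window, 5-SNP step, r² > 0.2) removes the
  lower-MAF member of an offending pair, ties broken toward the later
  variant — fixed so output is deterministic.
* PCA mean-imputes missing dosages, optionally scales by 1/√(p(1−p)), and
  is deterministic up to axis sign.
* Zero-spread standardization bins, pooled-monomorphic sites, empty
  allele pools and empty windows yield undefined (NaN) statistics, never
  exceptions; contract violations (unphased input to nSL, unsorted VCFs,
  duplicate genes in a DE table, all-zero contingency margins) raise with
  the offending record named.
* HWE p-value comparisons use a 1+10⁻¹² relative guard when summing
  as-or-less-probable outcomes.

## Known limitations

* No background LD in the generator: LD pruning and PCA are exercised on
  essentially independent sites plus planted duplicates.
* The overlap null ignores gene length and clustering; long genes are
  likelier candidates under any null.
* The permutation alternative for overlap significance samples the
  hypergeometric null directly (uniform gene draws); it does not permute
  genomic positions.
* nSL is computed without a genetic map (by construction of the
  statistic) and assumes correct ancestral polarity; with REF-as-ancestral
  misspecification the sign, but not the magnitude ranking within bins,
  can flip.
* Enrichment does not propagate the GO graph; term maps are taken as
  given.
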