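# Methods

`sexlinkit` re-implements, as a tested pipeline over synthetic cohorts, the
analysis chain used to characterise sex-determination (SD) loci in Atlantic
salmon (*Salmo salar*): variant QC, population divergence, case-control GWAS
with homeolog-aware leakage filtering, delineation of the male-specific
region (MSR) from read depth and mate-pair architecture, hemizygosity
testing via B-allele frequency (BAF), and MSR haplotype phylogenetics.
Because the original study's read data live in external archives, every
stage here runs on data from the package's own generator, whose defaults
encode the study conditions; the generator is first-class, tested code, and
its ground-truth record is what the recovery tests score against.

## The biological model

Salmonid sex determination is male-heterogametic (XX/XY-like): males carry a
single copy of a chromosomal segment containing the master gene *sdY*. In
Atlantic salmon the *sdY* cassette segregates at three separate genomic
locations — the sex lineages SL-02, SL-03 and SL-06, named for the
chromosome (Ssa02/03/06) hosting the cassette. The female-derived reference
assembly lacks the MSR, so analyses append a 20 kb male BAC contig spanning
*sdY*; on that contig the MSR (single-copy in males, absent in females)
abuts the male–female common region (MFCR) at a junction point detectable
as the base where female read depth resumes.

A salmonid-specific whole-genome duplication left ~25% of the genome with
delayed rediploidization: homeologous (duplicated, non-syntenic) blocks on
different chromosomes retain correlated allele frequencies. A strong GWAS
signal inside such a block therefore reappears ("leaks") on the partner
block and can masquerade as an additional locus.

## The synthetic cohort generator

The generator (`synthetic_data`) draws everything from one seed through
fixed per-stage substreams, so identical configurations give byte-identical
FASTA/VCF/SAM/TSV/JSON outputs. Its components, with defaults and
rationale:

**Genome geometry.** Six 500 kb chromosome proxies (stand-ins for Ssa02,
03, 05, 06, 12, 25) plus a 20 kb sdY contig whose MSR spans bases
2,001–13,333; 13,333 is the junction the depth analysis must recover.
Desk-scale chromosome lengths keep a full run in seconds; none of the
tested statistics depend on absolute chromosome length.

**Populations.** Three populations (TAS 20, NA 7, EU 13 — the
whole-genome-sequencing panel scale) drift from a common ancestor under the
Balding–Nichols model: ancestral frequencies ~ Uniform(0.05, 0.95),
per-population frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with
F = {TAS 0.04, NA 0.04, EU 0.17}. Pairwise Weir–Cockerham θ between two
such populations is approximately the mean of their Fs, so TAS–NA lands
near 0.04 (the magnitude reported for that comparison) and the vs-EU pairs
near 0.10 — the correct ordering, though shallower than the real EU split,
which would require F_EU ≈ 0.3. GWAS-scale analyses use the same generator
with a single large population (e.g. TAS 800), mirroring the study's
two-cohort design (thousands of array-genotyped fish; a small sequenced
panel).

**Markers.** 2,200 background SNPs per chromosome. This density is chosen
so that a chromosome's top-0.5% association threshold always selects more
SNPs (≥ 11) than lie on either side of an SD anchor block (10 + 10),
guaranteeing that a detected critical interval straddles its anchor — a
structural property the leakage geometry relies on.

**Sex and lineages.** Sex is balanced within population; each male draws a
lineage (SL-02 0.50, SL-03 0.25, SL-06 0.25 — SL-02 dominant, as the Ssa02
signal dominates the real GWAS). The cassette is "anchored" as a 20-SNP
haplotype block (±10 kb) around the lineage's SD locus: carrier males have
dosage 1 + Bernoulli(p) at every block site, making marker presence
perfectly linked to maleness within lineage. The Ssa02 anchor sits at
250,000 bp — the boundary between that chromosome's two homeolog blocks —
so its association block straddles both and leaks to Ssa05 *and* Ssa12,
reproducing the observed geometry. The Ssa03/Ssa06 anchors sit outside any
retained-tetrasomy block, so their partners show no leaked signal (their
real homeolog partners were not implicated either).

**Homeologs.** Three duplicated block pairs (Ssa02↔Ssa05, Ssa02↔Ssa12,
Ssa03↔Ssa06; each 250 kb). Half of the background sites inside an A-side
block (and every SD-block site, since the anchored haplotype is placed in a
retained-tetrasomy region by construction) get a partner site at the
mirrored coordinate whose genotype is copied per individual with
probability ρ = 0.9, otherwise drawn fresh — producing non-syntenic LD of
r² ≈ 0.8 between partners.

**Double haploids and artifacts.** Four DH females are homozygous at every
site except 50 planted artifact sites where *everyone* is heterozygous —
the signature of a collapsed paralog. Artifact sites draw their mapping
quality from the high-quality component: confidently mapped artifacts are
precisely the errors the DH screen exists to catch (an MQ filter would
remove the others anyway).

**Sequencing model.** Depth ~ Poisson(40) per site (half across male MSR
sites, zero for females there); allele depths are Binomial with het
fraction 0.5 and cross-allele error rate `seq_error_rate`/3 (a sequencing
error reads as the other *called* allele only when the substituted base
matches it — one of three substitutions); site MQ ~ Normal(58, 3) with a 2%
low-MQ component ~ Normal(35, 4). Array genotypes flip to a different
dosage class with probability 0.01, giving the ~99% WGS-vs-array
concordance scale; GSEX derives from three sdY presence assays, and PSEX
flips from GSEX at 2%, the reported phenotyping discordance scale.

**Alignment architecture.** Reads are emitted as already-mapped SAM records
(the inference consumes mapped architecture; no aligner in the loop). Each
MSR-less chromosome copy is simulated as the *joined* MFCR — the two flanks
fused, with reads mapped back to reference coordinates and reads straddling
the joint split into clipped pieces — so female depth resumes at full
height immediately after the junction, as clipped alignments anchor in real
data. Females carry two such copies; SL-02 males carry one plus a full
contiguous contig copy (whose fragments naturally span the junction in FR
orientation at the configured insert, 400 ± 50 bp); SL-03/SL-06 males carry
two joined copies plus a translocated cassette template covering only the
MSR, whose fragments crossing the junction put the mate on the host
chromosome (one third on the host's homeolog partner, echoing the mixed
orphan tallies seen in translocated males). Every chromosome also receives
a fully covered 20 kb background window used for genome-wide depth
normalisation.

**MSR haplotypes.** 22 polymorphic MSR sites; the HG-2 haplogroup carries
the ancestral (reference/BAC) allele everywhere, HG-1 the alternate allele
at 80% of sites; each male's haplotype then flips per site with probability
0.03 (within-haplogroup diversity). Expected between-haplogroup p-distance
is 0.8·((1−w)² + w²) + 0.2·2w(1−w) ≈ 0.77 — the same scale as the reported
0.78 — with within-group distance 2w(1−w) ≈ 0.06. SL-02 males carry HG-2;
SL-03/SL-06 males carry HG-1 (nearly indistinguishable from each other, as
observed). An outgroup table assigns the ancestral allele at 8 sites, 4 of
them divergent and hence phylogenetically informative.

**What the generator does not emulate.** Base-level sequence realism
(no indels, no quality strings), recombination and linkage beyond the
planted blocks, selection, pedigree structure (animals are founders; the
pedigree checks are exercised on purpose-built families in tests), the
ascertainment bias of a real SNP array, and real mismapping of female reads
into the MSR (optional uniform noise, default 0). Passing tests therefore
demonstrate the *operations* are correct under the stated statistical
structure, not that real sequencing data would yield the same magnitudes
(genome-wide π in particular reflects the generator's uniform frequency
spectrum, an order of magnitude above the ~2×10⁻⁴ per-bp diversity typical
of farmed Atlantic salmon genomes).

## Analysis methods

**Variant QC** (`variant_qc`). Sites with MQ < 50 are removed, genotypes
with DP < 5 set missing (sites with no surviving call dropped), non-biallelic
or non-SNP records removed; filters are idempotent. The DH screen removes
every position heterozygous in any DH sample — "presence in a DH genome" is
read as heterozygosity, since a hom-alt DH call is a legitimate allele.
Concordance matches loci on position and identical ref/alt (allele-swapped
loci are excluded rather than recoded — no reconciliation rule is defined),
compares 0/1/2 dosages over jointly called genotypes, and is symmetric.
Depth downsampling thins each allele depth binomially and re-calls
genotypes (missing below DP 5; hom if the alt fraction leaves [0.2, 0.8]) —
thresholds chosen to mimic caller behaviour at low depth.

**Population statistics** (`popgen`). Per-site diversity is
c(n−c)/(n(n−1)/2) over called alleles; window values divide by the full
window length (20 kb, 10 kb step), matching the convention of the standard
windowed-π tool. Weir & Cockerham (1984) two-population θ̂ is computed from
the a/b/c variance components per site; the headline number is the
unweighted mean of per-site estimates (the "average value" convention) with
the ratio-of-sums estimator exposed as an option — at these sample sizes
the per-site mean runs ~25% below the ratio form, so both are reported.
LD is the squared Pearson correlation of dosages (composite LD, matching
unphased input); pruning is greedy within 500-SNP windows stepping by 5,
removing the later site of the worst pair above r² = 0.3. "PCA of genetic
distance" is classical MDS (double-centering, eigendecomposition) of the
allele-sharing distance mean|dᵢ−dⱼ|/2.

**GWAS** (`gwas`). GSEX: male iff all three sdY assays positive, female iff
all negative, missing otherwise. Matrix QC order: samples (> 5% missing),
then SNP call rate (< 90%), then MAF (< 1%). The genomic relationship
matrix is VanRaden method 1; the pedigree A matrix comes from the tabular
method, and an animal is flagged when ≥ 2 pairs disagree with G by more
than 0.25 (midway between unrelated, 0, and parent–offspring, 0.5).
Association is OLS of the 0/1 phenotype on dosage (the study's prose
specifies linear regression; logistic is an option), p from the slope's t
statistic with per-SNP complete cases, Bonferroni and Benjamini–Hochberg
adjustments attached. Critical intervals take, per chromosome, the
ceil(0.5%) best SNPs; the interval is their positional span and the
chromosome is reported only when its peak passes genome-wide Bonferroni at
α = 0.05 (the gate operationalises the visual distinction between
association peaks and isolated SNPs).

**Leakage** (`leakage`). Intervals are processed strongest-first, ordered
by the summed score of the interval's threshold-passing SNPs and then by
peak score. The aggregate leads because it concentrates over many SNPs: a
true locus carries independently strong supporting SNPs while a mirror's
are damped copies, so the aggregate orders source before mirror even when
single-site noise lets one mirrored SNP out-peak the source peak (which
happens in a few percent of moderate-cohort replicates), and even when a
mirror copies the source's peak dosage exactly. Only when both components
tie exactly are partnered intervals left mutually unresolved.
An interval is *leakage* when it overlaps the homeolog partner projection
(≥ 1 bp) of an already-retained interval and ≥ 10 SNP pairs between the two
intervals reach r² ≥ 0.2 (the thresholds the LD analysis itself reports);
*unresolved* when the overlap holds but the LD support fails.

**MSR** (`msr`). The junction detector forms the per-base ratio of mean
female to mean male depth (capped at 2 so near-zero male depth at contig
edges cannot dominate), smooths it with a 201 bp centered moving average,
and fits a two-segment piecewise-constant model: among split points whose
left segment mean is < 0.25, right segment mean > 0.5 and both segments
span ≥ 500 bp, the split minimising total squared error is the junction
(last base of the low, male-specific segment). The algorithm is this
package's own — the original boundary was read off visually — and the
thresholds are exposed parameters. On default cohorts the detector lands
15–25 bp right of truth (the smoothed ramp crosses the optimal split level
slightly past the boundary); well within the ±100 bp recovery band.
Spanning pairs require FR orientation, insert within ±3σ, MAPQ ≥ 20 and the
implied fragment to cross the junction by at least half a read length on
each side — the margin keeps a small junction-estimate error from turning
one-sided pairs into spanning evidence, while ≥ 3 pairs guard against
chimeras. Orphans are MSR reads within 2 kb of the junction whose mates map
elsewhere; chromosomes with ≥ 2 orphan mates become lineage candidates
(2 matches the minority-chromosome count accepted in the original read
inspection). BAF is ad_alt/dp (undefined at dp 0); MSR sites are those
called in no female and ≥ 95% of sequenced males; hemizygosity counts BAF
values *exactly* 0 or 1 (a single stray read demotes a genotype, mirroring
how a 14/15 = 0.933 genotype was treated as a deviation), and the depth
ratio divides mean MSR depth by the genome-wide mean over the background
windows, excluding the sdY contig itself so the tiny proxy genome does not
bias the normaliser.

**Haplotypes** (`haplotree`). Haplotype extraction renders hom calls as the
single carried allele; a heterozygous MSR call violates hemizygosity and is
warned about and set missing. Site filter first (call rate ≥ 75% across
males), then male filter (≤ 50% missing over surviving sites). p-distance
uses pairwise deletion with the jointly-called polymorphic sites as
denominator. Neighbor joining is the Saitou–Nei algorithm with ties broken
toward the lowest taxon-index pair and negative branch lengths clamped to
zero; bootstrap resamples sites with replacement (1000 replicates) and
scores each internal bipartition of the full-data tree. Haplogroups split
at the longest internal edge — which presumes each haplogroup contributes
≥ 2 haplotypes (a singleton group sits on a leaf edge, and NJ may cherry it
with a noisy neighbour); analyses therefore sequence ≥ 10 males for the
tree stage. Ancestral assignment requires sites where both haplogroups are
fixed for different alleles and an outgroup allele exists; strict majority
wins, ties are undetermined (the real case was a unanimous 4-of-4; with
within-haplogroup diversity, informative-site counts vary between runs).

## Numerical and scale choices

Problem sizes are chosen for desk-scale runs: the default cohort simulates
in ~0.5 s, a full end-to-end pass (simulate → QC → GWAS → leakage → MSR →
tree with 1000 bootstraps) in well under a minute, and the complete test
suite in a few minutes. Leakage recovery uses 100 replicates of an
n = 300 single-population GWAS; junction recovery uses 20 seeded cohorts;
lineage recovery classifies 100 males. All tests and scripts are seeded and
deterministic. Degenerate inputs raise rather than guess: no low/high
segment contract → "no junction found"; monomorphic sites make r²
undefined; undefined p-distance entries block tree building; a star tree
cannot be split.
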