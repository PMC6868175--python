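# Methods

scarscape reconstructs, as a tested library, the genomic-scar analyses used
to stratify metastatic castration-resistant prostate cancer (mCRPC)
whole genomes: small-variant burden, microsatellite instability (MSI),
kataegis, chromothripsis, mutational signatures, a per-sample scar feature
vector, unsupervised genotype clustering with enrichment testing, and
enhancer-versus-gene copy-ratio classification. The cohort that motivated
these methods is controlled-access, so the package ships a synthetic cohort
generator that plants the eight published genotype profiles with full truth
labels; every claim the test suite makes is a claim about planted structure
being recovered.

## Variant model and filtering

Small somatic variants are SNVs, MNVs (equal-length multi-base
substitutions, no length cap), and InDels up to 50 bp. The heuristic
post-filters remove a variant when any of: supporting reads ≤ 3, gnomAD
exome allele frequency ≥ 0.001, gnomAD genome frequency ≥ 0.005 (all
boundaries inclusive on the removal side, all configurable). A missing
population frequency never removes a call. Structural variants require
B-allele frequency ≥ 0.1; unannotated BAF is kept. Per gene, coding
variants collapse to the most deleterious consequence under the order
nonsense/frameshift > splice > missense/inframe > synonymous > non-coding.

## Burden and MSI

Tumor mutational burden divides the summed SNV+MNV+InDel count by callable
megabases: 2,858,674,662 callable bases genome-wide and 28,711,682 coding
bases by default (GRCh37; both overridable on `GenomeSpec`). A sample is
MSI when more than 11,436 genomic InDels sit in microsatellites — repeat
unit 2–4 bp repeated ≥ 4 times, or a homopolymer repeated ≥ 5 times. When
repeat annotations are absent they are derived from a reference sequence by
maximal exact tandem extension of the inserted/deleted unit around the
event. The threshold is applied after heuristic filtering by default
(configurable), since the filters define the callable variant set.

## Kataegis

Per chromosome, SNV positions (ties collapsed) are reduced to log10
inter-mutation distances and segmented by an exact dynamic program that
minimizes the within-segment sum of squared deviations at a fixed segment
count S = min(5000, max(1, ⌊m/5⌋)) for m distances — one segment allowed
per five consecutive SNVs. The DP is the O(S·m²) layered recursion with
prefix-sum costs; a divide-and-conquer speedup is *not* valid here because
the SSE segment cost is not Monge on unsorted sequences (we verified this
numerically before settling on the exact recursion). The inner loops are
numba-compiled; only hypermutated samples (MSI-like, thousands of SNVs per
chromosome) make the quadratic term noticeable (~45 s for ~7000 SNVs on
one chromosome).

A segment is a kataegis focus when its raw-scale mean inter-mutation
distance is ≤ 2000 bp and it spans ≥ 5 SNVs (member distances + 1, shared
boundary SNVs assigned left). Adjacent qualifying segments merge into one
event (flag to disable). A sample with > 200 genome-wide events is reset
to zero events with a hypermutator flag: such genomes are hypermutated
everywhere rather than locally.

Because the segment count is fixed at its maximum rather than selected by
model criticism, boundary effects are possible: a focus adjacent to a long
quiet stretch can lose its outermost SNVs to a mixed segment. The calling
criteria, not the segmentation, define events, so this costs sensitivity
only at focus edges.

## Mutational signatures

Spectra use the standard 96 pyrimidine-normalized trinucleotide classes in
fixed alphabetical order (substitution, then 5′, then 3′ flank);
purine-reference calls are reverse-complemented on entry. Refitting
against a catalog is non-negative least squares (active-set, deterministic);
relative contributions are weights normalized to one.

De novo extraction is KL-divergence NMF with multiplicative updates,
implemented directly so the per-iteration objective is exposed (the test
suite asserts it never increases). For each rank in the survey range the
factorization is restarted from seeded random initializations; samples are
assigned to their dominant exposure per run, the across-run consensus
matrix is clustered (average linkage), and rank quality is scored by the
cophenetic correlation of that consensus, the best-run residual sum of
squares, and the mean silhouette. Defaults: 50 restarts, 200 iterations,
relative tolerance 1e-6 (the survey used for rank selection in the original
analysis ran 1000 restarts; the default here keeps test runtimes in seconds
and is configurable).

The packaged signature catalog is **synthetic**: five low-mutual-cosine
columns (aging-like CpG C>T, MSI-like, flat HRD-like, APOBEC-like TpC,
and a generic C>A column) stored as editable TSV data, as is the
signature-to-etiology grouping. No external catalog is fetched.

## Chromothripsis

Candidate region per chromosome (Y excluded) is the footprint of its
intrachromosomal SVs — deliberately simpler than interleaving-graph
clustering; the five criteria then are: (a) ≥ 25 intrachromosomal SVs;
(b) a run of ≥ 7 copy-number segments oscillating between two rounded
states, or ≥ 14 among three (longest-run scans verified against a
quadratic oracle); (c) footprint ≥ 20 Mbp; (d) equal representation of
DEL/DUP/INV-HH/INV-TT by chi-square goodness of fit, p > 0.05, switching
to a seeded 10⁵-draw Monte-Carlo p when expected counts drop below 5;
(e) non-uniform breakpoint placement along the chromosome by one-sample
Kolmogorov–Smirnov, p ≤ 0.05, skipped (criterion fails) under 5
breakpoints. All five statistics are always computed — no short-circuit —
so boundary tests can isolate each. Copy-number states round half to even.

## Scar features and clustering

The per-sample feature vector has 12 entries: SNV, InDel and MNV rates per
genomic Mbp; length-weighted mean ploidy (Y excluded); total SV count; and
relative frequencies of seven SV categories (translocation, inversion —
orientations merged, insertion, tandem duplication and deletion each split
at 100 kbp, ties to the small class). A reduced mode drops ploidy, MNV and
insertion columns for cohorts lacking those calls.

Clustering scales each feature by its root mean square without centering,
takes d = 1 − Pearson r between sample rows, and applies Ward linkage to
those dissimilarities *without squaring* — the classic `ward.D` contract,
implemented via Lance–Williams updates with deterministic lowest-index tie
breaking and verified merge-for-merge against an independent hierarchical
clustering implementation on random instances. Leaf order is the exact
Bar-Joseph optimal-leaf-ordering dynamic program (we found a widely used
library routine measurably suboptimal against exhaustive enumeration of
tree-consistent orders, so the DP is implemented here and enumeration-
checked in the tests).

The cluster count is automated from the tree-cut cost curve. Two choices
matter and both were made deliberately: the cut cost is evaluated in the
same dissimilarity space the tree optimizes (sum of within-cluster
dissimilarities over cluster size — Euclidean cost on the scaled matrix is
incommensurate with a correlation-distance tree and buries genuine splits
under scale), and the max-distance-to-chord rule is applied to the log of
that cost, because the curve spans orders of magnitude and the log-chord
tracks where the curve flattens permanently — which is what visual
inspection of an elbow plot actually responds to. A warning flags weak
curvature (relative chord distance < 0.2, calibrated so that pure-noise
matrices warn and planted-structure matrices do not).

Bootstrap support resamples features (columns) with replacement, re-runs
scale → dissimilarity → ward, and scores each original node by the
fraction of replicate trees containing the identical leaf set — the
ordinary bootstrap probability; multiscale/AU approximation is out of
scope. Enrichment per (cluster, binary trait) is a two-sided Fisher exact
test with Benjamini–Hochberg correction applied jointly across all tests.
The supervised mutually-exclusive scheme assigns the first matching class
in the order ERG, ETV1, ETV4, FLI1 (gene breaks), SPOP, FOXA1, IDH1
(aberrations). Cohort comparison runs per-gene Fisher + BH on collapsed
aberration tables and a two-sided Wilcoxon rank-sum on burden vectors.
PCA diagnostics (centered and scaled) report per-feature cos² per
component; with all components kept, each feature's cos² sums to one.

## Enhancer-versus-gene copy ratio

For a locus pair (gene body, upstream enhancer — defaults for AR and
MYC/PCAT1 ship as an editable BED with approximate GRCh37 boundaries), a
region's copy number is the maximum over overlapping segments. The
per-sample statistic is r = log2(CN_enhancer) − log2(CN_gene) against a
1:1 null with no fitted parameters; studentization is leave-one-out:
t_i = r_i / RMS(r_{j≠i}). |t| > 1 classifies the sample enhancer- or
gene-enriched by sign; otherwise balanced. The classification is invariant
to global copy-number scaling, and antisymmetric under swapping the two
regions. Samples with missing or zero region copy number are excluded with
a warning.

## Synthetic cohort generator

The generator is first-class, tested code that defines the study
conditions. Eight genotype profiles plant the published per-cluster
medians: sizes 13/13/15/22/55/20/34/25 of 197 (rescaled to any cohort size
by largest remainder), coding TMB 36.8/2.4/3.0/4.3/2.1/2.5/2.1/2.3 per
Mbp, SNV/InDel ratios 0.99–7.28, SV counts 149–669, dominant SV category
(large tandem duplications for the CDK12-type cluster, small for its
neighbor, deletion-enriched with small-deletion emphasis for the HRD
cluster, insertions for cluster H), ploidies 1.92–3.35, cluster-defining
driver genes at their published within-cluster frequencies (MSH6/JAK1/CIC;
CDK12/FGF3/FGF4; BRCA2) over a common background (TP53, AR, PTEN, RB1),
per-cluster kataegis prevalence, and chromothripsis in 80% of cluster-F
samples.

Two profile aspects are the package's own choices, made once. First, the
clusters published with no dominant SV category are still distinct
clusters in the real feature space; the generator emulates that by giving
them mildly shifted backgrounds (translocation-shifted vs
inversion-shifted), and the chromothripsis cluster a background
near-balanced across the four orientation classes, as expected for
shattering-prone genomes. Second, within-genotype spread: lognormal rate
jitter (σ = 0.12), negative-binomial SV counts (dispersion 80), normal
ploidy (σ = 0.10, truncated at 1), Dirichlet-free category draws, beta
purity centered at 0.62 — moderate spreads consistent with the published
interquartile ranges.

The default test genome is a 370 Mbp miniature (three chromosomes,
150/120/100 Mbp) whose callable denominators equal its size, so per-Mbp
rates are recovered without rescaling. One consequence is deliberate: the
MSI rule's threshold is an absolute count, so MSI samples draw their
qualifying-InDel count directly (normal, mean 17,000, sd 2,000, clipped
≥ 12,500) — their InDel *density* is therefore higher than a full-size
genome would show, while the SNV/InDel ratio (~1) and coding TMB still
match the published medians. Kataegis foci are planted as 5–30 SNVs at
100–1500 bp spacing; chromothripsis as a 25-segment two-state
copy-number ladder over 40 Mbp of chr1 with ~28–36 clustered,
orientation-balanced SVs.

What the generator does **not** emulate: reference-consistent alleles
(positions are not tied to a FASTA), purity-coupled detection sensitivity,
germline contamination beyond a 1% high-population-frequency leak,
subclonal structure, and realistic inter-gene correlation of drivers.
Recovery results on this cohort therefore demonstrate that the
implementations compute what they claim on data with the planted
statistical structure — not clinical performance on real genomes.

## Problem sizes and determinism

All randomness flows through seeded NumPy generators; per-sample streams
are spawned from the master seed in sample order, so cohorts are
byte-identical per seed. The default validation cohort is 200 samples;
cluster recovery is checked over five seeds (adjusted Rand index vs planted
truth ≥ 0.8, elbow at the planted count). The end-to-end pipeline test runs
a 16-sample cohort — the exact kataegis DP on hypermutated samples is the
single expensive step, and one MSI sample suffices to exercise it. The NMF
survey in tests uses ranks 2–4 with ≤ 15 restarts.

## Known limitations

* The chromothripsis region finder is per-chromosome footprint, not SV
  cluster detection; multiple events on one chromosome merge, and heavy
  unclustered SV background on the same chromosome dilutes the equal-type
  and uniformity tests.
* `ward.D` heights are criterion values on unsquared dissimilarities and
  are not variance decompositions; they are comparable across runs but not
  interpretable as explained variance.
* The elbow automation replaces human judgment; on curves without a
  persistent plateau it warns rather than refuses.
* MSI classification is rule-based on repeat-annotated InDels; per-locus
  panel methods are out of scope, as are HRD scores (consumed as an
  optional input, never computed).
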