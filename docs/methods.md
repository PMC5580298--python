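# Methods

## Genetic model

The cross is an F1 between a volatile-producing parent and a
non-producer. The producer parent is heterozygous for a dominant allele
at every locus the model requires; the non-producer parent carries none.
Inheritance is disomic (segregation within one subgenome of the
octoploid, as the screen assumes), loci are unlinked, and each progeny
receives the dominant allele at each locus independently with
probability 1/2. A genotype is a *potential* producer iff it carries the
dominant allele at every model locus; the expected producer fraction is
therefore (1/2)^L for L ∈ {1, 2} loci, scaled by penetrance.

Penetrance has two forms. In the `genetics` module it is a single
effective per-study probability multiplying the model fraction. In the
simulator it acts per harvest, independently: a potential producer shows
a detectable phenotype in each harvest with probability π, so the
any-harvest detection rate converges to
`model_fraction x (1 − (1 − π)^n_harvests)`. The per-harvest form mimics
season-to-season variability of the volatile; the effective form is what
an exact binomial test of one pooled producer count can resolve.

## Phenotype model

Measurements are normalized peak areas (volatile ion peak over the
internal-standard peak), dimensionless. Detected harvests of producers
draw lognormal(μ=0, σ=0.5) signal (median 1.0); undetected harvests and
non-producers draw uniform noise on [0, 0.2·threshold]; the default
detection threshold is 0.05. Producer calling is *k-of-n*: default
`min_harvests = 1` (any-harvest detection), because the emulated design
treats a genotype with the volatile in any harvest as a producer; the
parameter is exposed for stricter calling. Percentages are reported raw
and rounded half-away-from-zero to integer percent.

## The RNA-seq subset

Expression is simulated only for the subset actually sequenced: both
parents plus `n_rnaseq_progeny` (default 14) progeny, composed of
`n_subset_producers` (2) strong producers, `n_subset_low` (5)
transcript-carrying progeny with sub-threshold phenotype, and
transcript-negative progeny for the remainder. The low class reflects a
real feature of such screens — the causal transcript is necessary but
not sufficient, so some non-producers express it — and it is also what
lets a contig be "present in at least six genotypes" when only three
strong producers are sequenced. Under the two-locus model the low class
arises naturally (single-locus carriers); under the one-locus model the
simulator designates carrier progeny and forces their phenotype below
threshold. At most `n_subset_low` records are altered, so
population-level segregation statistics are perturbed by ≤ 5/114.

## Count model

Target RPKM per cell: causal contigs get `mean_expression_present`
(default 100) in carriers of the transcript locus and
`mean_expression_absent` (0.5) otherwise; background contigs share one
mean (250) across all genotypes. The homogeneous background keeps the
null far from the 5/10 RPKM decision band, so recovery tests exercise
the filter logic rather than threshold-straddling noise; real
transcriptomes have a broad abundance distribution, which these
simulations deliberately do not model — passing recovery tests therefore
show correctness of the cascade, not its false-positive rate on real
data. Targets are back-converted to expected counts,
μ = RPKM·N·L/10⁹, with per-genotype library sizes N drawn lognormal
(log-mean log 5·10⁶, log-sd 0.2), and drawn from a negative binomial
parameterized by mean μ and dispersion α (variance μ + αμ², default
α = 0.1, Poisson at α = 0). Contig lengths are uniform on 300–3000 bp
and sequences uniform random over ACGT (no shared k-mers between
unrelated contigs except ~4⁻²¹-scale collisions).

## Dual assemblies

The second assembly is derived from the first: a fraction
`assembly_overlap_fraction` (default 0.9) of contigs is carried over as
an exact copy, a truncation keeping ≥ 50% of the length, or a two-way
split (probabilities 0.6/0.25/0.15), under new identifiers; the rest of
the second assembly is novel random sequence. Planted causal contigs are
always carried over (possibly truncated or split): the dual-assembly
filter models confirmation of a real transcript by two assemblers, and a
causal transcript absent from one assembly would make exact recovery
impossible by construction rather than by failure of the method.
Fragments below 42 bp (twice the matching k) are never produced; contigs
too short to truncate are copied whole.

## Assembly matching

Contigs are compared by sets of canonical 21-mers (numeric minimum of
the 2-bit packed k-mer and its reverse complement; k odd so a k-mer
never equals its own reverse complement). The score is containment,
|A∩B|/|A|, not Jaccard, so fragments score 1.0 against their source; a
pair qualifies when containment in either direction reaches 0.5. K-mers
containing non-ACGT characters are not indexed; contigs shorter than k
are recorded as unindexable. Ties for a contig's best partner break by
higher shared-kmer count, then lexicographic id; tables are sorted by
id pair, making output independent of input order.

## Filter cascade

Filter 1 (informative detection), filter 2 (absent in
≥ `min_absent_genotypes` with the non-producer parent required among
them, present in ≥ `min_present_genotypes`), filter 3 (dual-assembly
confirmation), strict producer-specificity (present in every
producer-bulk genotype, absent in the non-producer parent). "Detected"
in filter 2 means the trinary *present* call; ambiguous counts as
neither, since the thresholds exist precisely to define detection.
Counts are evaluated over individual genotype columns (the worked
example reports per-genotype RPKM); pooling reads within bulks before
RPKM is possible by summing count columns upstream. In the end-to-end
pipeline the dual-assembly filter is evaluated lazily — only contigs
surviving the expression filters are matched against the full second
assembly — which changes nothing in the candidate decisions (filter 3 is
per-contig membership) but avoids indexing thousands of query contigs
per run. In the per-contig report the filter-3 flag is therefore only
meaningful for contigs that passed the expression filters.

## Exact tests

The two-sided binomial p-value uses the minlike convention (sum of all
outcome probabilities ≤ the observed outcome's), computed with exact
rational arithmetic so probability ties — e.g. the mirror outcome at
p₀ = 1/2 — are included without floating-point ambiguity; above
n = 2000 the implementation delegates to scipy's equivalent test.
Confidence intervals are exact Clopper–Pearson (95%). Marker–transcript
co-segregation uses the two-sided conditional (Fisher) exact test on the
2×2 table; note that for a perfectly concordant 6/6 split in 12 progeny
the two-sided p is 2/C(12,6) = 2/924, since the perfectly anti-concordant
table is equally extreme. No continuity corrections anywhere; sample
sizes are small and exact methods are cheap.

## qPCR

Comparative CT with amplification efficiency fixed at 2 (perfect
doubling). Replicates aggregate by averaging ΔCt, not fold changes;
uncertainty propagates by the delta method,
SE(fold) = ln 2 · fold · SE(ΔΔCt), with sample and calibrator
standard errors combined in quadrature.

## Determinism and problem sizes

All simulator randomness flows through named substreams of one seed
(`numpy` SeedSequence spawn keys), so identical configuration yields
byte-identical outputs, including written files; the run configuration
is hashed (outdir excluded) into every output header. The test suite and
the acceptance script run the full pipeline at study defaults
(2005 contigs × 16 genotypes) over 20 seeds for recovery and 100 seeds
for the signal-free null, and calibrate the exact test on 10,000 null
draws by computing the test once per distinct observable count; these
sizes give Monte-Carlo standard errors well inside the asserted margins
while keeping a full run within a couple of minutes.

## Known limitations

No read-level simulation, alignment or assembly; no polyploid subgenome
structure or linkage; background expression is homogeneous (see above);
the phenotype noise model is a bounded uniform rather than a measured
limit-of-detection process; marker discordance is a simple symmetric
flip probability. The worked-example fixture stores printed two-decimal
RPKM values with contig lengths taken from the spanned reference-genome
intervals; those lengths play no role in threshold classification.
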