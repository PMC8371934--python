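# Methods

This note records the models, estimators and design choices behind each
stage, what the synthetic-data generator does and does not emulate, and
the numerical conventions.

## Genotype coding

Only sites where both inbred parents are non-missing homozygotes for
different alleles are informative in an F2 and enter the matrix; progeny
calls are coded `A` (parent-1 homozygote), `B` (parent-2 homozygote),
`H` (heterozygote). A progeny call carrying an allele absent from both
parental homozygotes is joint-calling noise: it degrades to missing and
is counted in a log summary rather than raised, because the correction
stage downstream is designed to absorb exactly this kind of error.
Multiallelic records are skipped with a warning — the A/B/H coding is
defined only for biallelic sites.

## Bin-map construction

Four steps, each a pure function of the previous stage's output.

**Redundancy with missing data.** Two marker vectors are *redundant* when
they agree at every individual where both are non-missing. Requiring
exact equality instead would let low-coverage missingness shatter true
bins; the chosen relaxation is transitive-safe in the implementation
because runs are extended against a running consensus that accumulates
the union of non-missing calls, so a later member that contradicts any
earlier member breaks the run.

**Collapsing (step 1).** Runs of redundant markers whose adjacent members
are closer than `min_gap_bp` (default 100 bp) merge into a representative
marker positioned at the first member. The representative code is the run
consensus; missing entries fill from the run's non-missing members.

**Window correction (step 2).** For each representative and individual,
the centered window of 15 markers (center included, shrunk at contig
edges) votes over its non-missing entries. A non-missing center that
disagrees with a strict majority (> half) is replaced; a missing center
with a strict majority is imputed; ties change nothing. The pass is
single and non-iterative, computed entirely from the input state, so it
is order-independent and cannot cascade: iterating to convergence was
rejected because repeated passes progressively erode genuine crossover
boundaries. Strict majority (rather than plurality) is what protects a
clean two-segment crossover pattern — at the boundary the window splits
8:7 and the 8-side always contains the center's own segment.

A consequence worth knowing: the window is defined in *markers*, so its
genetic width is 15/density cM. At low marker density (about 1 marker/cM)
the window spans ~15 cM and erases genuine double-crossover segments
shorter than ~8 markers, compressing the map by roughly 20%. At the
densities the method is meant for (several markers per cM and above) the
window is well under 2 cM wide and the compression is a few percent.
Validation simulations therefore use >= 5 markers/cM when map length
itself is the quantity under test.

**Bins (step 3) and the distortion filter (step 4).** Adjacent
representatives with compatible corrected vectors merge into bins, whose
`n_markers` sums the underlying original markers. A bin is removed iff
nA < 20 or nB < 20 or nH < 40 — the disjunction, not the conjunction,
because the thresholds add up to the 20 + 40 + 20 = 80 informative plants
an ideal 1:2:1 ratio implies. Note the filter is deliberately permissive:
a clean 1:2:1 bin sampled at n = 120 still trips it ~2–3% of the time
(the homozygote classes sit only ~2 SD above their thresholds); that is
the designed trade-off against letting distorted bins into the map.

## Linkage map

**Recombination fraction.** The F2 codominant maximum-likelihood
estimator with an EM iteration over the phase-ambiguous
double-heterozygote class: an `H`/`H` individual carries 0 or 2
recombinant gametes with posterior weights (1-r)^2 and r^2. Single-het
classes contribute exactly one recombinant gamete, `A`/`B` classes two,
concordant homozygote classes zero; the M-step divides the expected
recombinant-gamete count by 2n. Start r = 0.25, stop at |dr| < 1e-8 or
500 iterations; the likelihood is unimodal in practice and the estimator
is verified against a dense grid search in the test suite (agreement to
1e-4 on 1,000 random tables). Individuals missing at either locus drop
from that pair (complete-case pairwise estimation). All-pairs estimation
is vectorized: the nine 3x3 cell-count matrices for every bin pair come
from indicator-matrix products, and the EM update runs elementwise.

**Grouping and ordering.** Single linkage over pairs with linkage LOD
(log10 likelihood ratio against r = 0.5) at or above 12; groups with
fewer than 100 underlying markers are discarded. Within a group, bins are
ordered by physical position (contig order, then bp) — the markers are
genome-anchored, so de novo ordering would add noise without adding
information, and external ordering engines are out of scope.

**Spacing.** Adjacent-bin r-hat values pass through the Kosambi map
function d = 25 ln((1+2r)/(1-2r)) cM and accumulate from 0. The inverse
is r = tanh(d/50)/2; the round trip is exact to floating-point noise.
Values of r within 1e-6 of 0.5 are capped with a warning (the transform
diverges at 0.5). Map statistics report per-group length, bin and marker
counts, mean adjacent interval as length/(bins - 1), the count of gaps
>= 5 cM and the largest gap; the bundled study table's "average interval"
column follows a different, unstated convention and is not targeted.

## QTL scans

**Genotype probabilities.** At a test position between two flanking bins,
P(QTL genotype | flank codes) comes from the no-interference two-locus
transition products: the per-gamete haplotype joint over (left, QTL,
right) with switch probabilities r1, r2 (Kosambi-inverted from the cM
distances), convolved over the two gametes, then conditioned on the
observed flank pair. Missing flanks marginalize; positions at a bin
reduce to the indicator of that bin's code. Degenerate conditioning rows
(zero mass, possible when two bins are at identical cM) fall back to a
vanishing uniform floor (1e-300) rather than raising.

**Regression scan.** Haley–Knott regression: phenotype on intercept,
x = P(AA) - P(BB) and z = P(AH), with LOD = (n/2) log10(RSS0/RSS1). This
is a deterministic approximation to the mixture-likelihood EM of the
classic scan software; at F2 sample sizes and the effect sizes relevant
here the two are practically indistinguishable, and the regression form
is what makes permutations cheap. CIM adds forward-selected background
marker cofactors (additive + dominance columns, mean-imputed at missing
calls, BIC stopping, at most 5 by default) to both the null and full
models, excluding any cofactor within 10 cM of the test position. Designs
are reduced to orthonormal bases once per position, so a permutation
costs one projection per position; rank-deficient designs drop dependent
columns before projection.

**Thresholds and calls.** The genome-wide threshold is the (1 - alpha)
quantile of max-LOD over phenotype permutations (default 1,000 at
alpha = 0.05). Permutations shuffle the phenotype vector against whole
genotype rows, preserving the marker correlation structure that the
max-LOD null depends on. Each maximal super-threshold region yields one
QTL: peak at the argmax, flanking markers the nearest bins bounding the
region, and PVE the R^2 of the two-predictor regression at the bin
nearest the peak (complete-case at that bin). QTL names follow the
qSC<trait><group>.<k> convention.

**Model facade.** `QTLScanModel(...).fit()` wraps scan + threshold +
calling and returns a `QTLScanResults` with the profile, threshold,
calls, a `summary()` table and a `plot()`; the underlying operations are
public functions, so each step remains individually scriptable. The
repository adopts this fitted-model shape only where a model is actually
fitted; the surrounding stages are plain functions over plain containers.

## Interval consolidation

Boundary intervals are carried as integer hundredths of a cM (2-decimal
precision as printed), so all overlap arithmetic is exact. Overlap is
half-open [start, end): endpoint-touching intervals stay distinct — the
convention that keeps a hotspot's internal boundaries from collapsing
prematurely — while genuine overlap and nesting merge to the union.
Zero-length calls (single-marker QTLs with identical boundaries) have an
empty half-open range; they are absorbed into any consolidated interval
whose closed extent contains them and otherwise stand alone, which is the
only reading that attributes every QTL while preserving the distinct-
interval count. Clustering then merges chains of intervals separated by
<= 2 cM (config-exposed) into one spanning hotspot interval; 2 cM is the
smallest round value that merges the observed 1.66 cM hotspot gap while
leaving every larger inter-interval gap alone. Physical projection takes
the bp span of the bins whose cM positions fall in the closed interval,
one segment per contig; marker IDs of the form `<contig>-<bp>` parse by
splitting on the final hyphen, so contigs with internal hyphens or
underscores survive.

## Candidate screen

Three conjunctive conditions, each recorded per gene so non-passing
evidence is inspectable: (1) >= 1 bp overlap with a QTL physical segment
(flanking-marker bounds are themselves approximate, so boundary genes are
included); (2) >= 1 high-impact variant homozygous-alternate in the
black-seeded parent and homozygous-reference in both white lines, with
missing line genotypes excluded conservatively; (3) differential
expression at >= 1 of the late stages (10/15/20/25 DAF) and not at the
5 DAF control, at padj < 0.05 and |log2FC| > 1. Differential expression
itself is consumed from upstream tables, not computed — the screen needs
only the flags. The built-in effect caller covers the high-impact classes
(frameshift, stop gained/lost, start lost, splice acceptor/donor within
2 bp of an intron boundary, whole-exon loss) plus synonymous/missense,
and is verified against a translate-and-compare codon oracle over every
single-base substitution of random CDSs on both strands; UTR/regulatory
classes are intentionally absent (upstream/downstream variants are out of
scope) and non-coding positions fall through as modifiers. Pre-annotated
ANN-style effect strings can be consumed instead, mapping their impact
field directly. The high-impact variant is required to lie in a gene that
overlaps the segment, not itself inside the segment — the gene set, not
the variant set, is what the screen frames.

## Synthetic data

**What it emulates.** 13 chromosomes, 120 F2 individuals, dense biallelic
markers fixed for opposite parental alleles; meiosis with
Poisson(length/100) crossovers per gamete, uniform positions, no
interference (so map distances are additive and Kosambi is exact only at
short range — correctness tests use short intervals); the low-coverage
artifact as a two-stage process — each maximal true-heterozygote run
acquires, with probability `miscall_run_rate`, a geometric-length sub-run
(mean `miscall_run_length` markers) recoded to one random homozygote —
plus uniform missingness; 1–4 QTLs per trait with PVE up to 0.40;
correlated L/a/b phenotypes in colorimeter-like units. The published
study does not state its data's true miscall/missing rates; the defaults
(0.10 per run, 5% missing) are plausible for ~1x coverage and are
config-exposed, not asserted.

**PVE scaling.** Phenotypic variance is normalized to 1 per trait. A QTL
with additive shape a and dominance shape d contributes variance
a^2/2 + d^2/4 under 1:2:1 frequencies (the additive and dominance
predictors are uncorrelated there); each QTL's shape is rescaled so its
contribution equals its target PVE exactly, and the residual variance is
1 minus the summed PVEs. The closed form is exact for unlinked QTLs;
linked pairs (the hotspot default on chromosome 9) covary positively, so
their realized joint PVE runs a few points above nominal — accepted,
since the hotspot is meant to be strong. Residuals are drawn jointly
across traits from the configured correlation matrix scaled by the
residual SDs; realized *phenotype* correlations therefore match the
configured matrix exactly only when traits share no QTLs.

**Planted annotation fixtures.** Candidate genes are placed at the
simulated QTL positions (so recovered physical segments contain them) and
carry a stop-gain variant in the black/white/reference co-segregation
pattern plus DEG calls at >= 1 late stage and a clean 5 DAF control.
Decoys violate exactly one condition each, cycling through low-impact
variant, non-co-segregating variant, DEG at the control, and no late DEG;
background genes fill a grid elsewhere. Gene placement is collision-free
by construction (linear probing over 8 kb slots) and raises if the gene
budget exceeds the contig.

**What it does not emulate.** Read-level noise, genotype likelihoods,
crossover interference, segregation distortion from selection, reference
bias, or expression counts (DEG tables carry planted flags with random
but honest padj/log2FC values, not negative-binomial draws). Passing
tests therefore demonstrate the pipeline's statistical machinery under
its own stated assumptions, not robustness to every artifact of real
resequencing data.

## Numerical conventions and problem sizes

All coordinates are 1-based inclusive (VCF/GFF3 convention); BED output
is 0-based half-open. Genotype codes are int8 (A=0, H=1, B=2,
missing=-1). cM values print at 2 decimals and interval arithmetic runs
on integer hundredths. Permutation quantiles use linear interpolation, so
alpha = 1 degenerates to the minimum of the permutation maxima. A single
pipeline seed fans out to per-stage seeds through one generator, keeping
stages reproducible yet independent.

Validation simulations are sized to make their statistical claims at
desk scale: 1,000 random tables for the EM-vs-grid check, a 2,000-marker
x 120-individual panel for the correction benchmark, 200 null replicates
x 200 permutations for type-I calibration, and 200 replicates for
QTL-recovery medians; these sizes give Monte-Carlo error comfortably
inside the asserted tolerances.

## Known limitations

IM/CIM only — the multi-method triangulation some studies use (GCIM,
ICIM) is out of scope, as are genotype-likelihood imputation, HMM-based
error correction, de novo marker ordering, epistasis scans, and
enrichment analysis. The regression scan slightly underestimates LOD
relative to full mixture likelihood when genotype information is very
incomplete. The distortion filter's disjunctive reading and the 2 cM
hotspot gap are reconstructions of under-specified choices; both are
config-exposed.
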