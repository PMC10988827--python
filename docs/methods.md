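# Methods

This note documents the models implemented in `lateralis`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that matter for reproducibility.

## Phenotype similarity

Proband phenotypes are sets of terms from a rooted DAG of `is_a`
relations. Annotation sets are closed under the ancestor relation before
any frequency computation, so a proband annotated with "right atrial
isomerism" also counts for "heterotaxy" and "abnormal left-right
patterning".

**Information content.** The IC corpus is the analysis cohort itself:
`IC(t) = −ln(n_t/N)` in nats, where `n_t` counts probands whose closed set
contains `t`. The corpus choice matters — the upstream tooling this
mirrors leaves it unstated — so an external term-frequency table can be
supplied through `compute_ic(extra_counts=...)`. Terms never annotated
receive a floored count of 1; this keeps IC finite and similarity defined
for arbitrary query terms at the cost of slightly compressing the IC range
(the maximum attainable IC is `ln N`). IC is monotone non-increasing from
leaf to root on any closed corpus, floor included.

**Similarity.** Term–term similarity is Lin's measure with the
most-informative common ancestor; a term is its own ancestor, identity
scores 1 even for zero-IC terms, and two distinct terms whose only shared
ancestry has zero IC score 0. Set–set similarity is the symmetric
best-match average

    sym(A,B) = ½ [ mean_{a∈A} max_{b∈B} Lin(a,b) + mean_{b∈B} max_{a∈A} Lin(a,b) ]

— the standard symmetric combination; "symmetric Lin" alone does not pin
down the aggregation, so this choice is documented here and verified
against brute-force enumeration in the tests.

## Clustering

Distances are `d = 1 − s` (valid since `s ∈ [0,1]` with unit diagonal).
Ward agglomeration uses the Lance–Williams recurrence on squared
distances (the `ward.D2`-style criterion); "Ward" is ambiguous across
implementations, hence the explicit dialect. Merge ties are broken by the
lowest pair of current cluster indices after sorting probands
canonically by id, making assignments invariant to input order —
important here because probands with identical term sets produce exact
zero-distance ties. Heights are non-decreasing (Ward is reducible).
Cutting keeps exactly `k` clusters by undoing the last `k−1` merges;
labels are numbered along dendrogram leaf order, which is also the
heatmap row/column order.

**Gap statistic.** `W_k = Σ_r (1/n_r) Σ_{i<j∈C_r} d²_ij` from Ward cuts,
`Gap(k) = mean_b log W*_{k,b} − log W_k`, `s_k = sd_b·√(1+1/B)`, with
B = 100 reference datasets by default and a mandatory seed. Tibshirani's
reference distribution needs coordinates, which a pure distance matrix
lacks, so the matrix is embedded by classical MDS (components covering
≥ 95% of positive eigen-mass, capped at 10 dimensions) and references are
sampled uniformly in the per-dimension bounding box. `log W_k` is floored
at `log 1e-12` for degenerate all-duplicate cuts.

**Choosing k.** The default rule takes the k in [2, kmax−1] with the most
negative second difference of the gap curve — the point where the curve's
slope decreases most. A flat curve warns and returns the smallest k. The
Tibshirani one-standard-error rule and an explicit override are also
available. The packaged reference analysis cuts at k = 5 to match the
five highlighted phenotype groups; the slope rule on the packaged fixture
happens to agree, but the override is recorded because the two published
descriptions of the cluster count (four by the slope rule, five
highlighted) do not coincide, and the reference run follows the
five-cluster presentation.

Probands whose entire term set falls on the exclusion list abort the run
with `EmptyPhenotypeError` rather than being silently dropped: a missing
row would quietly change every downstream frequency.

## Variant prioritisation and phasing

The filter retains a record iff its gene is on the panel, the maximum MAF
across the available databases is strictly below 1×10⁻⁴ (0.01%), and
CADD-phred is strictly above 15. Absence from every frequency database
counts as frequency 0 (novel alleles must not be discarded); a missing
CADD score fails the score criterion, conservatively. Known alleles —
e.g. a founder allele whose population frequency exceeds the cutoff, or a
variant class CADD scores poorly — can be pre-specified on a rescue list
that bypasses both score criteria but not panel membership; rescues are
marked in the per-record decision log. The maximum-across-databases
combination and the rescue mechanism are package decisions; the upstream
workflow they mirror does not state how multi-database frequencies were
combined.

Parental origin: carried by exactly one parent → that parent; reference
in both observed parents → de novo (both parental genotypes are required
for a de novo call); both parents carriers → unknown (ambiguous origin,
including the homozygous-proband case); with one parent missing, a
heterozygous call is attributed to an observed carrier parent, otherwise
unknown.

Clone phasing calls *trans* when clones carrying only the first and only
the second variant are both observed and no doubly mutant clone exists;
*cis* when a doubly mutant clone exists and no single-mutant clone does;
anything else — including contradictory mixtures — is ambiguous.
Biallelic status promotes two heterozygous calls to compound het (trans)
only on explicit evidence (differing parental origins or trans clone
phase); an evidence-free pair stays `unphased_pair`.

Cohort yield tables allow overlapping lesion categories (a proband with
congenitally corrected transposition also counts under "any L-looping");
percentages are reported at one decimal and empty categories as NA.

## Enrichment statistics

The headline statistic is allele-based: heterozygotes contribute one and
homozygotes two variant alleles, cases contribute `2n` alleles total.
The odds ratio is `ad/bc` with a Wald 95% CI on the log scale using
z = 1.959964 (stated exactly because CI endpoints are reported at one
decimal); the Haldane–Anscombe +0.5 correction is applied to all cells
only when some cell is zero, and never to the Fisher test, which always
uses the raw counts. A carrier-based table is available but clearly
labelled secondary. Fisher's two-sided p is the hypergeometric tail sum
(via `scipy.stats.fisher_exact`) and is checked against full enumeration
in the tests.

## Deletion screen and junctions

The read-depth screen is a deliberately simple cohort-median ratio
method: per exon, the sample's RPKM (`reads·10⁹ / (length·total)`)
divided by the median RPKM of the remaining samples; maximal runs of
consecutive exons inside [0.3, 0.7] are heterozygous calls and at or
below 0.1 homozygous calls (one supporting exon suffices by default,
matching real single-exon deletion events). It requires ≥ 8 samples for
a stable median and skips zero-median exons with a warning. It is a
screening tool, not a segmentation algorithm: no GC correction, no
principal-component noise removal, no genome-wide calling.

Junction resolution is exact-match by design — Sanger-derived junction
sequences are high quality — with a 12 nt minimum seed per flank; a
mismatch-tolerant mode is deliberately deferred. The longest read prefix
found in the proximal reference and the longest suffix found in the
distal reference either overlap (microhomology), leave a gap
(untemplated insertion) or meet exactly (blunt junction). Because a
junction inside a homologous tract can slide anywhere along it, each
breakpoint is reported as an interval of width equal to the
microhomology length rather than a single base. Flanks must place
uniquely; multiple equally long placements raise an ambiguity error
listing the candidates.

Printed genomic coordinates for deletions are treated as inclusive
1-based positions whose absolute difference reproduces the printed size;
exon and repeat intervals are 0-based half-open (BED). AAMR candidacy
requires both breakpoints inside Alu-family repeats on the same strand
(directly oriented); with non-empty microhomology the event is
additionally flagged as forming a chimeric Alu. Repeat annotations are
consumed, never detected.

## Synthetic data

The generators emulate the structure of the study inputs, not their
biology:

* The mini-ontology (~40 terms) is fixed content, with a cardiac branch
  (looping, great-artery position, atrioventricular connections, valve
  atresia, septal defects) and laterality/spleen branches, including the
  four nonspecific terms that the primary analysis excludes (atrial and
  ventricular septal defects, secundum ASD, single ventricle).
* Phenotype cohorts draw probands from lesion archetypes with per-term
  dropout (default 0.15) and a spurious-term probability (default 0.1);
  defaults correspond to moderately noisy clinical annotation. The
  packaged 33-proband fixture reconstructs each case's term set from its
  lesion class and Van Praagh segmental anatomy; the real per-proband
  term lists are not public, so the fixture is approximate by
  construction, and the four biallelic probands carry the consistent
  right-atrial-isomerism/asplenia phenotype described for them.
* The 321-proband screening cohort encodes the published lesion-category
  totals and carrier counts (including 111 Hispanic probands with 10
  carriers, two homozygous) as a per-proband table; it is a composition
  fixture, not a simulation.
* Genotype cohorts draw two alleles per case at frequency `ρq`
  (enrichment factor ρ times the control frequency), then promote a
  designated fraction of carriers to homozygous. Trios cycle through
  paternal / maternal / de novo / homozygous / trans / cis patterns with
  noiseless genotypes and matched clone observations.
* Read counts follow a Poisson–Gamma (negative-binomial) model whose
  Gamma multiplier has mean 1 and coefficient of variation equal to the
  `dispersion` parameter (default 0.1, typical of exome depth ratios
  after normalisation); `dispersion = 0` is the exact noiseless limit.
  Heterozygous deletions scale exon means by 0.5, homozygous by 0.
* Junction cases assemble reads as proximal flank + shared tract (or
  insertion) + distal flank with explicit guards so the engineered
  microhomology is exactly the maximal one, and place the two repeat
  annotations across the breakpoints.

Passing tests on these generators demonstrate correctness of the
algorithms under the stated noise models; they do not demonstrate
robustness to real-exome artefacts (batch effects, GC bias, segmental
duplications), linkage structure, or annotation idiosyncrasies of the
full Human Phenotype Ontology.

## Problem sizes and determinism

The test suite and the acceptance script run at the cohort's native
sizes: 33 probands for clustering (gap statistic with B = 100), 111/64
cases for enrichment, 20 samples × 120 exons for the deletion screen,
and 200 junction cases. Every stochastic component takes an explicit
seed (`numpy.random.default_rng`); identical inputs and seed give
bitwise-identical outputs, and clustering output is invariant to proband
input order.

## Known limitations

* The Lin set-similarity aggregation and IC corpus are configuration
  decisions, not published constants; results shift slightly under other
  choices (e.g. Resnik IC from an external corpus).
* The gap-statistic reference distribution depends on the MDS embedding;
  distance matrices far from Euclidean may embed poorly.
* The second odds ratio published for the 64-proband lesion-restricted
  subgroup is not reproduced by the same allele-based construction that
  reproduces the cohort-wide value (it gives ≈ 47 rather than ≈ 51) and
  its construction is not stated, so the package does not report it.
* The deletion screen's thresholds assume a mostly diploid cohort at
  each exon; a deletion shared by many samples shifts the median and
  hides itself.
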