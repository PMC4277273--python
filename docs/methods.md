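# Methods

## Study design and data model

The package targets the CP (cross-pollinator style) full-sib design: two
unrelated outbred parents per family, two families, biallelic SNP markers
annotated with the EST contig they were discovered in, plus a handful of
multi-allelic microsatellites. Markers segregate in mixed configurations —
one parent heterozygous (testcross through that parent), both parents
heterozygous with the same alleles (intercross, partially informative) or
with distinguishable alleles (fully informative, microsatellites). Missing
genotypes are first-class and are never imputed.

## Quality control

Order matters and is fixed: offspring with a missing fraction strictly
above `max_missing_individual` (default 0.30) are removed first, against
the full marker panel; marker missingness is then computed over the
retained individuals of both families pooled and markers strictly above
`max_missing_marker` (default 0.30) are removed. Parents are never removed
(a family without a parent is unusable), only flagged. Mendelian screening
compares every offspring genotype with the set of genotypes producible by
the parental pair; one inconsistent offspring in either family excludes the
marker globally. Missing offspring genotypes never count as violations; a
missing parental genotype makes the marker uncheckable in that family and
is noted. Finally a marker is retained only if at least one parent is
heterozygous in at least one family; the segregation class is recorded per
family. QC is idempotent.

## Contig haplotypes

SNPs within one EST contig span a physically negligible genetic distance,
so their alleles should travel as one haplotype through every meiosis.
Each multi-SNP contig is phased per family by exhaustive enumeration over
parental phase assignments (2^(h−1) per parent for h heterozygous member
loci; contigs carry ≤4 SNPs so this is exact and cheap). If some phase pair
explains every offspring as one paternal plus one maternal haplotype
without intra-contig crossover, the contig becomes a single multi-allelic
marker (id `C<contig>`); an offspring with missing member genotypes is
compatible with a phase if any completion is, which avoids false
recombination calls. If no phase pair explains all offspring, the
minimum-conflict phase defines the evidence set, and one unambiguous
recombinant offspring (configurable) keeps the contig split. Offspring
whose haplotype pair is not uniquely determined are recorded as missing at
the combined marker; combination therefore only merges columns and never
manufactures information.

## Two-point analysis

For a marker pair the per-family genotype likelihood is built from the
parental transmission model: each parent passes one allele per locus, with
recombination probability r between the loci; unknown parental phases are
profiled (maximised over), matching the behaviour class of classic
pedigree-linkage programs. Offspring fall into at most ~10 distinct
genotype-pair classes whose probabilities are quadratic in r, so the
likelihood is evaluated exactly and maximised by a grid pass plus bounded
scalar refinement (tolerance 1e-6) over r ∈ [0, ½], jointly across
families. LOD is the base-10 likelihood ratio against r = ½. Configurations
in which every observed offspring resolves a transmission (testcross and
fully-distinguishable crosses) short-circuit to the exact closed form:
r̂ equals the recombinant fraction under the best phase, pooled across
family/parent units with per-unit phase flips.

Phase profiling inflates null LODs: each doubly-heterozygous pair
contributes up to four phase bits, so an unlinked pair has E[LOD] ≈ 0.2 per
profiled unit. The grouping/pooling thresholds below must be read against
that background.

## Grouping and pooling

Linkage groups are connected components of the marker graph with edges at
LOD ≥ 8. Small groups are then pooled: two groups merge if any cross pair
reaches LOD ≥ 4, or — only when one group has ≤5 markers — if more than
half of the cross pairs reach LOD ≥ 0.5. The size restriction on the weak
rule is deliberate: with profile-LOD inflation the null probability of a
cross pair at LOD ≥ 0.5 approaches 0.4 at these family sizes, and the
majority rule applied to two large unlinked groups would merge them almost
surely. Pooling runs to a fixed point and only coarsens the partition.

## Multipoint objective and ordering

Ordering works on *transmission chains*: per (family, parent), the loci at
which that parent is heterozygous, with each offspring's resolved
transmissions (0/1 = which parental allele) or unknowns (missing or
ambiguous genotypes). Chain phases are fixed once per group: a greedy
spanning alignment orients each locus against its strongest partner
(evidence |n−2k|), followed by majority-vote refinement.

Given an order, every maximal pair of consecutively-resolved loci per
meiosis contributes one span observation, pooled across chains into counts
(k, n) per marker pair. Adjacent-interval recombination rates are estimated
from the directly-adjacent spans (intervals nobody observes directly
inherit an even composite split of the pooled minimal-gap covering spans,
which keeps the objective invariant to inserting transmission-free loci and
symmetric under order reversal). The objective then scores *every* span
against the composite probability implied by those shared interval rates,
1−2p = Π(1−2rᵢ). Spans that skip loci — abundant, because intercross
genotypes are ambiguous for half the offspring — thereby act as
consistency checks: a transposed block makes the composite probability of
its skipping spans disagree with their observed recombinant fractions. On
fully observed data the objective collapses to the classical per-interval
closed form Σ k·ln r̂ + (n−k)·ln(1−r̂).

Spans whose *both* endpoints are resolvable only when the other parent
transmitted a matching allele (intercross × intercross) condition on
correlated events in both parents; their observed rate estimates
p²/(p²+(1−p)²), ½ or its complement depending on the relative parental
phase. They are scored under a per-span three-branch profile and excluded
from interval-rate estimation.

Ordering itself follows the classic build/flips pattern: the group is
seeded with the pair of highest informative-meiosis count, unplaced markers
are inserted where the best position beats the second-best by the current
support threshold (log₁₀ units), with the threshold lowered stepwise
3 → 2 → 1 → 0.5 → 0; markers never attracting positive support stay
unmapped. Refinement iterates window-5 permutations, single-marker
relocation and 2-opt segment reversals to a joint fixed point (reversals
escape inversion-type local optima a 5-window cannot reach); groups of ≤7
markers are simply ordered exhaustively. Groups pooled from several LOD-8
components are ordered per component and the components then arranged as
rigid blocks (full enumeration up to 3 blocks, greedy chaining beyond), so
that markers joined only by weak pooling evidence cannot interleave; blocks
are concatenated only along seams carrying a cross pair at the strong
pooling LOD (≥4) — a seam supported by the weak-majority rule alone is as
likely chance as real at these sample sizes, and such blocks are reported
as separate linkage groups.

Final map positions accumulate Kosambi distances of the interval rates
after a coordinate-wise maximum-likelihood polish against all spans (three
sweeps of ternary search per interval), which de-inflates the zigzag bias
residual ordering error would otherwise leave. Orders are cut at junctions
whose refined adjacent rate is ≥ 0.35 or which no meiosis spans at all:
0.35 sits between the 30 cM maximum credible map interval (r ≈ 0.27) and
the sampling noise of a truly unlinked junction (r̂ ≈ 0.5 ± 0.07). Groups
are numbered LG1, LG2, … by decreasing length (ties: marker count, then
smallest marker id); every tie-break in the engine is deterministic.

`D_av`, the average inter-marker distance, divides total length by
(mapped loci − groups), counting distinct map positions by default (raw
markers optionally). The published value (8.1 cM) is not reproducible from
any obvious definition given the published marker/contig/group counts, so
published-input computations treat it as a printed constant.

## Genome length and coverage

Two estimators: the chromosome-end correction (add 2·D_av per group), and
method 4 of the Chakravarti family (multiply each group length by
(m+1)/(m−1), m = locus count; groups with m < 2 are skipped with a
warning). The karyotype-corrected variant replaces the chromosome-end term
for surplus groups (beyond the haploid number) by one 30 cM maximum
credible gap each, and adds D_av once instead of twice per acrocentric
chromosome. The working genome length is the mean of both estimators;
coverage is observed length over that mean. All comparisons against
printed values are made at one decimal; computation is full precision.

## Comparative synteny

Hit tables are 12-column BLAST tabular (outfmt 6); rows at E ≥ 10⁻¹⁰ are
discarded (strict inequality retains) and the best hit per (contig,
species, chromosome) kept — highest bit score, then lowest e-value, then
lowest subject start. Minus-strand hits are normalised to start ≤ end with
the strand retained. The Oxford grid counts distinct contigs per (linkage
group, species chromosome); a contig hitting several chromosomes of one
species is counted once per chromosome and flagged as a potential paralog,
preserving the diagnostic that multigene families interfere with true
synteny. A parallel best-hit-only grid (one chromosome per contig per
species) backs decisions where paralog noise must not scatter evidence.

Conserved syntenic regions are order-agnostic: ≥2 distinct contigs of one
linkage group on one chromosome, with the subject-coordinate span in bp.

Chromosome assignment: per species chromosome the max-count linkage group
is marked; per A/B synteny-group label the marked groups of its member
chromosomes vote and the modal group becomes the label's primary linkage
group; each primary group defines one putative chromosome, and a group
primary for two A-labels is flagged as a fusion. Surplus groups (primary
nowhere) are folded into a putative chromosome iff their best hits fall
within that single label's chromosomes, else left unplaced with a conflict
record. All ties break lexicographically and are logged; the assignment is
a pure function of grid + scheme.

## Stepping stone

For each putative chromosome, every linkage group of the relative's
published map receives one vote per shared intermediate species in which
both map to the same chromosome. Groups reaching `min_support` votes
(default 2) are reported as homologs — several supported groups form a
composite homolog rather than being force-merged — and sub-threshold or
empty candidate sets are reported unresolved with their support listed.
Adding an intermediate species can only increase support.

## Synthetic-data generator

The generator emulates the study conditions end to end and exports its
ground truth (true positions, transmitted haplotypes per meiosis, parental
phases, ortholog assignments, scheme, bridge table) so every downstream
stage has an oracle. Defaults are the study scale: 21 chromosomes with
lengths uniform on 60–100 cM, 469 SNPs on 291 single-SNP plus 73 multi-SNP
contigs, 10 microsatellites (simulated as fully informative ab × cd
crosses), families of 46 and 35 offspring, 3 % missing genotypes, no
genotyping error. Informative SNPs draw their segregation class with
probabilities 0.4 (both parents heterozygous), 0.3 (sire only), 0.3 (dam
only) — values chosen once as realistic for a panel pre-selected for
informativeness; real EST panels were not published at this granularity.
Meioses are haplotype walks with independent per-interval switch
probability equal to the inverse Kosambi transform of the cM gap.
This makes two-point recovery exact by construction but simulates no
crossover interference, although the Kosambi function implies some — a
deliberate simplification: passing tests demonstrate engine correctness
under the stated model, not robustness to interference. Parents are
simulated fully genotyped, and intra-contig SNP spans default to 0 cM
(intra-contig recombinants are planted explicitly where needed).

Homology tables plant one true hit per contig per species with the
observed per-species detectability (stickleback 0.47, tilapia 0.39, medaka
0.31, pufferfish 0.30), strong e-values (10^−15…10^−60), and paralog noise
on random chromosomes at a configurable rate with e-values straddling the
10⁻¹⁰ threshold and bit scores below any true hit. Ancestral "units" define
the cross-species A-labels; a planted fusion joins two units into one focal
chromosome. The matching scheme and bridge table are generated alongside.
The shipped example scheme/bridge configurations are synthetic: the
published A/B membership matrix exists only as a figure and per-species
chromosome identities per label are not recoverable from text.

## Problem sizes used in the tests

Unit tests use hand-built families and one-chromosome simulations of 3–7
markers. The engine-oracle suite runs 100 seeded small-group simulations
(4–7 markers, 30+20 offspring) against exhaustive permutation optima. The
parameter-recovery check runs one full study-scale simulation (seed 1,
defaults above); synteny recovery uses a six-chromosome world with one
planted fusion, full detectability and 5 % paralog noise. These sizes are
the package's own choices: large enough to exhibit the study's information
structure, small enough that the whole suite runs in about a minute.

## Known limitations

* With 79 effective offspring, per-chromosome map-length estimates have a
  relative standard deviation of about 11 % even at the true marker order
  (mean error ≈ −1 %); one to three of 21 chromosomes per simulated
  replicate typically land outside a ±20 % band. Fine-scale marker order
  of tightly linked markers is likewise not identifiable at this sample
  size — the design's intrinsic information floor, not an implementation
  artifact.
* Intercross SNP pairs carry little linkage information and their
  conditioned transmission subsets are biased; the engine works around
  this (exact pair likelihoods, three-branch span scoring) rather than
  modelling the full joint hidden-origin process of both parents.
* Sex-specific maps, crossover interference and QTL analysis are out of
  scope; the map is sex-averaged.
* The surplus-merging rule trusts best hits only; a surplus group whose
  true chromosome is poorly detectable can remain unplaced.
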