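# Methods

## Genotype model and calling

The panel is a selfing diploid, so true genotypes are modelled as
homozygous: each site/sample cell is `REF`, `ALT` or `MISSING`. Calls are
made from the alternate-allele read depth over total depth, r = DV/DP,
gated on the site's variant quality:

* QUAL ≤ 40 (strict) or DP < 2 → `MISSING` (flagged low-qual / low-depth);
* r ≤ 0.2 → `REF`; r ≥ 0.8 → `ALT`;
* otherwise `MISSING` with a het-ambiguous flag.

The 0.2/0.8 cutoffs are symmetric, conventional values for inbred panels;
the original pipeline this emulates delegated them to an unpublished AWK
script, so they are explicit, configurable assumptions here
(`CallThresholds`). Treating intermediate ratios as missing rather than
heterozygous matches the homozygous-haplotype data model: in an inbred
panel an intermediate ratio is far more likely mismapping or contamination
than a true heterozygote, and the grouping step (below) degrades
gracefully under missingness.

Site filters: a site is kept when it is polymorphic among called samples,
its minor-allele frequency over non-missing calls is ≥ 1% and its missing
fraction is ≤ 90%. The published phrasing can be read as two or three
filters; we implement three (monomorphic, MAF, missingness), a superset.
The filter is idempotent (property-tested). Duplicated accessions are
connected components of the graph of pairs sharing > 99.8% of genome-wide
calls (identity = matching calls / co-called sites).

## Haplotype grouping

Samples with identical allele vectors over a region scope share a
molecular haplotype. Samples with missing calls are adopted by a haplotype
only when their called positions are consistent with exactly one existing
haplotype; otherwise they are `AMBIGUOUS`. This policy never invents
haplotypes and is deterministic. Haplotype ids are canonical: descending
carrier count, ties broken by the lexicographically smallest member, so
output is invariant to sample and site order (property-tested).

Combined locus haplotypes are (x, y) id pairs; ambiguity in either subunit
propagates. Flank consistency is the count difference between the
coding-only and coding-plus-flank combined partitions — widening a scope
can only split groups, so it is ≥ 0 on fully called data.

## Relationship matrix, distances, clades

Markers are coded −1/+1 with missing cells imputed to the marker mean
(the default of the kinship routine this follows), centred by 2p−1 where
p is the ALT frequency, and

    A = WW′ / (2 Σ p(1−p))      (VanRaden method 1)

Genetic distance is the Euclidean distance between rows of A. Monomorphic
markers are rejected (they must be filtered upstream; the denominator
would gain nothing and mean-imputation would silently hide them).

Agglomerative clustering (complete linkage by default, matching the
default of the clustering routine the analysis names) is cut into k_major
major clades and k_sub nested subclades from one dendrogram. Major clades
are labelled I, II, … by descending size; subclades are numbered
consecutively in that order. k_major = 3 and k_sub = 15 are configuration
defaults mirroring the emulated study's designations, not derived
quantities; on small panels k_sub is clipped to the sample count.
Clade sources are pluggable: a dendrogram cut, an imported newick tree
(clustered via its tip-to-tip distances), or a manual table —
downstream nomenclature and recombinant logic need only the partition.
Maximum-likelihood tree inference is deliberately out of scope; a
neighbor-joining tree (negative branches clamped to zero with a warning)
is provided for interchange with external tree viewers.

Haplotype-level clades are lifted from the single sample-level clustering
by carrier majority (ties toward the smaller label). Using one clustering
for both subunits keeps the major-clade labels of the x and y partitions
comparable — labels from two independent clusterings would not be.

## Nomenclature

Within each subclade, haplotypes are lettered a, b, c… in canonical order
(descending carrier count, then smallest member id): `Dx9a` is the first
x haplotype of subclade 9, and a combined name `x1a+y1b` pairs the two
subunits. Letters carry no meaning across subclades. Published letter
suffixes appear historical/arbitrary, so determinism was prioritised over
string-matching any published table; the structure (counts, clade
membership, pairings) is the reproduction target.

## Recombinant detection

For each x haplotype, the majority y major-clade among its carriers
defines the expected linkage. A combined haplotype is flagged when its x
and y major-clades differ **and** the pairing carries fewer than a
minority fraction (default 0.5, configurable) of that x haplotype's
carriers; the symmetric test runs from the y side and the union is
reported. Ties in the majority vote flag nothing (no linkage
expectation can be defined). This generalises the by-eye identification
of single recombinant accessions to a reproducible rule. A discordant
haplotype whose subunits have no concordant carriers at all cannot be
distinguished from a novel allele and is not flagged.

## Coding effects and the cysteine audit

Effects are classified per site against the reference codon under the
standard nuclear code (as per-site annotators do): synonymous, missense,
nonsense, start-loss, stop-loss; sites outside the CDS are `non-coding`
and excluded from the synonymous/non-synonymous tally. Multi-nucleotide
variants are rejected. Whole-haplotype CDS and protein sequences are also
built (reference CDS with ALT substitutions, minus-strand genes handled
by reverse-complement mapping) so multi-variant codons are visible at the
haplotype level. The cysteine delta is recorded for every non-synonymous
change that gains or loses a Cys — including a stop gain that removes
one, since the audited quantity is disulfide-bonding capacity. The N/C
terminal-domain windows for the audit are configuration inputs (codon
ranges per gene); the default is the whole CDS. The central repeat region
of these proteins is not reconstructible from short-read variants; it is
represented only by whatever SNVs tag it.

## k-mer lineage bins

A bin of size B is assigned to lineage L iff its L-specific k-mer count
exceeds **every** other lineage's count by more than margin = f·B
(default f = 10⁻⁴, i.e. 10 for 100 kb), strict inequality, applied
symmetrically to all lineages (the published rule is stated for one
lineage only; the symmetric generalisation reduces to it when labels are
restricted). The margin is per competitor, equivalent to max-of-competitors
for two competitors. Bins are 0-based half-open; a 1-based gene position p
maps to bin ⌊(p−1)/B⌋, so a boundary position counts only its containing
bin. Colocalization reports the assignment of every overlapping bin and a
consensus (or `MIXED`).

## Geography

Great-circle distances use the haversine formula with the IUGG mean Earth
radius R = 6371.0088 km. The Mantel statistic is the Pearson correlation
over strict upper-triangle entries; the test is one-sided (positive
association, matching the directional claim it quantifies) with
p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm) under joint row/column
permutations, seed-reproducible. Since a joint permutation only rearranges
the same multiset of off-diagonal values, the permuted mean and standard
deviation equal the observed ones, which the implementation exploits to
vectorise the permutation loop. The emulated study reports this
relationship qualitatively; the statistic is an added quantification and
is labelled as such in reports.

## Synthetic panels

The generator's defaults are the emulated study conditions: 117/143/8
accessions in lineages 1/2/3, ~10× mean depth, 308 sites split 60
(coding x) + 68 (coding y) + 180 (2.5 kb flanks), two planted
recombinants, one haplotype shared between lineages 1 and 2, duplicated
accessions, and the two genes ~55 kb apart at realistic chromosome-1D
coordinates with the y gene on the minus strand.

Generative model (fully deterministic per seed):

* every site carries one of the six non-constant three-lineage allele
  patterns, so all sites are polymorphic by construction and lineage bases
  differ at ~2/3 of sites (regenerated if any pair falls under 30%);
* within a lineage, haplotype j differs from the lineage base at one
  private coding site (pools larger than the coding site count are
  rejected as unrepresentable); flank sites carry the lineage base only,
  i.e. complete linkage — so flanks add no haplotypes, as observed;
* samples cycle through their lineage's pool; recombinant samples keep
  their own lineage's x haplotype and take the y haplotype of the next
  non-empty lineage; shared haplotypes plant lineage-1 pairs into
  lineage-2 samples; duplicates append re-noised copies of existing
  samples;
* depth is Poisson(mean_depth) clipped below at 2 reads (the emulated
  panel is sequenced > 7×, and the clip makes a zero-noise panel fully
  called); DV | DP is binomial with per-read miscall probability
  error_rate; a configured fraction of sites receives QUAL ≤ 40;
* collection sites are lineage centroids (Transcaucasia / south-east
  Caspian / wider range) plus isotropic Gaussian jitter — the minimal
  model that makes genetic and geographic distance correlate;
* a separate genome-wide binary call table (2,000 sites, 2% private
  mismatch per sample, one mismatch for duplicates) supports duplicate
  detection, since same-haplotype samples are identical at the locus
  itself.

The bundled validation fixture is the zero-noise panel 20/20/6 with
4+4+1 haplotype pools, 2 recombinants, 1 shared haplotype and 1 duplicate
pair: the 9 concordant pairs plus the 2 recombinant pairings give exactly
11 observed combined haplotypes, all recoverable exactly.

What the generator does **not** emulate: coalescent genealogies and
realistic site-frequency spectra, linkage decay within a gene, indels and
structural variants, alignment artefacts correlated across samples, and
repeat-region variation. Passing tests therefore demonstrate correctness
of the analytical machinery on panels with the stated structure, not
robustness to every artefact of real short-read data.

## Problem sizes and tolerances

The test suite and acceptance script run on the fixture panel
(47 samples × 80 sites), 20 random 6–10-sample instances for the
relationship/clustering oracles, exhaustive count triples in [0,25]³ for
the bin-classification oracle, all 9 SNVs of 50 random codons for the
effect oracle, 10 random additive 6-taxon matrices for NJ additivity
(1e-9), 1,000 random cases for caller monotonicity and filter
idempotence, and 200 independent-null Mantel replicates at 999
permutations (mean p within 0.5 ± 0.1). Numerical comparisons against
oracles use relative tolerance 1e-10 unless stated. The full-scale
drivers in `analysis/` use the study-sized defaults (270 samples,
308 sites) and complete in seconds.

## Known limitations

* Clade letters/numbers are deterministic but not string-identical to any
  published nomenclature table.
* Recombinant detection requires the participating subunit haplotypes to
  have concordant carriers; singleton discordances are indistinguishable
  from novel alleles.
* The Mantel test assumes exchangeability under permutation; strong
  within-lineage spatial autocorrelation would inflate significance.
* Effect classification is per-site; compound codon changes are visible
  only in the emitted haplotype protein sequences.
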