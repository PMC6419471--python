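# Methods

`motu-concord` implements a single-locus species-delimitation pathway
for COI-5P barcode data: pairwise Kimura two-parameter (K2P) distances,
barcode-gap auditing, three distance-threshold MOTU delimiters,
four-way concordance of MOTUs against reference species labels,
≥k-of-m consensus MOTUs and adjusted-Wallace partition agreement. This
note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Distance model

Distances are K2P, which corrects the observed transition proportion P
(A↔G, C↔T) and transversion proportion Q separately:

    K = −½ · ln((1 − 2P − Q) · √(1 − 2Q))

Sites where either sequence carries anything outside {A, C, G, T}
(N, gap, ?, IUPAC ambiguity) are deleted pairwise before P and Q are
computed. A pair is treated as *missing* when fewer than `min_overlap`
sites (default 100) survive pairwise deletion, or when the logarithm's
argument is non-positive (a saturated pair); missing pairs are excluded
from summaries with a logged warning and never link during clustering.
Distances are held as proportions; report writers render percent with
two decimals, half-up. Alignment is out of scope — inputs must be
pre-aligned or uniformly trimmed to equal length.

Rank-level divergence pools follow barcode distance-summary
conventions: the species level pools conspecific pairs, the genus level
pools congeneric *heterospecific* pairs, and the family level pools
*intergeneric* pairs — each rank measures divergence between units of
the rank below. The *normalized* intraspecific summary averages the
per-species mean distances with equal weight per species, removing the
bias from unequal specimen counts; singletons contribute no pairs and
are excluded throughout.

## Record filters

Records are removed, in order, by the first failing rule: (1) fewer
than 600 non-gap bases; (2) an internal stop codon in *all three*
forward reading frames under the invertebrate mitochondrial code
(NCBI table 5) — barcodes may start mid-codon, so a record is kept if
any forward frame is stop-free, and a stop in the final codon of a
frame is ignored; (3) any quality-control flag (`contaminant`,
`misidentified`, `error`). Flags are consumed from metadata, not
detected. An optional filter drops records whose fraction of ambiguous
bases exceeds 1%, mirroring barcode-compliance rules for cluster
registration; it is off by default because its wider applicability is
unclear.

## Delimiters

**Single-linkage threshold.** MOTUs are the connected components of
the graph linking pairs at or below a cutoff. The cutoff is either a
K2P proportion or an absolute mismatch count in bp, compared against
each pair's raw differing-site count on its retained sites (the
convention of bp-valued cutoff sweeps). The common anchor is 2%
(≈13 bp on a 658-bp barcode).

**Recursive gap partitioning.** An operational reading of automatic
barcode-gap discovery. Within a group, pairwise distances are sorted
ascending and consecutive differences scanned; the first difference
that (a) ends at or above a prior on maximum intraspecific divergence
and (b) exceeds `max(min_gap_width, sigma × mean of the preceding
consecutive differences)` is declared the barcode gap. The group is
split by single linkage at the gap midpoint and the procedure recurses
into each subgroup, stopping when no gap is found or a group has fewer
than three members. Defaults: `sigma = 1.5`, `min_gap_width = 0.001`.
When the candidate gap is the very first step of the ladder there are
no preceding differences; the mean over all consecutive differences is
then the baseline, so a uniformly spaced (gapless) ladder never yields
a spurious gap. This is a documented reinterpretation — bit-for-bit
agreement with the original barcode-gap-discovery program, whose slope
statistic is defined elsewhere, is a non-goal.

**Refined single linkage.** A two-stage approximation of the
refined-single-linkage procedure behind barcode index numbers (whose
exact refinement internals are unpublished): seed clusters are formed
by single linkage at a 2.2% *p-distance* threshold; each seed cluster
is then re-examined with the gap partitioner, using the cluster's
median internal distance as the prior, `sigma = split_ratio` (default
3.0), and a gap floor of half that median — inside a seed cluster a
split-worthy gap must be wide relative to the cluster's own divergence
scale, not just the global floor. A proposed split is accepted only if
every pair of resulting subclusters is separated by at least
`split_ratio` times the deeper subcluster's internal single-linkage
depth (its largest minimum-spanning-tree edge); accepted splits are
refined recursively. Reference cluster assignments (e.g. a BIN column
in the metadata) can instead be imported as a first-class partition,
which is how externally registered cluster numbers are reproduced
exactly.

## Concordance statistics

Each reference species S with MOTU set M(S) is classified:
**MATCH** (|M(S)| = 1, the MOTU holds only S), **MERGE** (|M(S)| = 1,
shared with other species), **SPLIT** (|M(S)| > 1, every MOTU pure),
**MIXTURE** (|M(S)| > 1, at least one MOTU shared). The categories are
mutually exclusive and partition the species set; a singleton species
can only MATCH or MERGE. Summaries are reported over two denominators
— all species, and multi-specimen species only — because singletons
cannot SPLIT and inflate the apparent concordance.

**Consensus MOTUs.** "Recovered by at least k of m methods" is read as
exact specimen-set identity: candidate sets are every MOTU of every
partition, support is the number of partitions containing exactly that
set, and sets with support ≥ k are kept. Overlaps are resolved
deterministically (higher support, then larger set, then
lexicographically smallest member); specimens covered by no kept set
are reported unassigned. Set identity is the only assessable reading
without trees; tree-aware consensus is a non-goal.

**Adjusted Wallace.** For partitions A → B, over all specimen pairs
co-clustered in A, W is the fraction also co-clustered in B. The
agreement expected by chance is 1 − SID(B), with SID Simpson's index
of diversity of B's cluster sizes, giving

    AW = (W − (1 − SID)) / SID

AW is undefined when B is a single cluster (SID = 0) or A has no
co-clustered pairs; the result object carries the reason. Specimens
whose A-cluster is a singleton are excluded by default, matching the
convention of discussing only multi-specimen clusters. The 95% CI is a
seeded percentile bootstrap over specimens (default 1000 replicates);
the original web tool's analytic interval is not reproduced here.

## Trees

NJ (Saitou–Nei) is implemented directly so tie-breaking is
deterministic — the lexicographically lowest index pair wins — with
negative branch-length estimates clamped to zero and the clamped total
logged. Trees terminate in a trifurcation (unrooted) and are rooted at
the midpoint of the longest leaf-to-leaf path; a zero-diameter tree is
rooted at the first internal node with a warning. Because
agglomeration order under ties can differ between NJ implementations,
trees are compared by clade sets and leaf-to-leaf path lengths, not by
byte identity. Trees are built on haplotype-collapsed data (exact
sequence identity only; sequences differing at an ambiguous site are
not merged).

## Synthetic data generator

The generator provides truth-known test beds with the statistical
structure the analysis assumes. Lineage history is a two-level star
phylogeny: lineage ancestors evolve independently from a random root,
specimens independently from their ancestor. Substitutions follow the
two-rate (K2P) process with transition/transversion rate ratio `kappa`;
site evolution uses the exact transition probabilities of the
continuous-time chain, so distances compose correctly along paths.
Branch lengths are calibrated by numeric inversion of the closed-form
expected K2P distance; because between-species and deep-split targets
describe *specimen-level* distances, ancestor branches are shortened by
the specimen-branch contribution. Simulated sequences are kept free of
internal stop codons in reading frame 0 (the third position of any
TAA/TAG is rewritten to C), since barcodes are protein-coding and the
package's own filter would otherwise reject them.

Defaults describe the divergence structure of a large katydid barcode
survey: 658-bp sequences, normalized within-species mean 1.4%,
congeneric between-species mean 15%, `kappa = 4.0` (a typical insect
mitochondrial transition/transversion rate ratio). Species are grouped
into genera of 4 and subfamilies of 20 for label structure; geographic
coordinates are species centroids scattered with 800 km standard
deviation around a central-China base point, with 50 km within-species
jitter. Planted discordance: a `cryptic_fraction` of species spans two
lineages separated by `deep_split` (default 8%, well above the 2%
deep-divergence flag), and `merge_pairs` label pairs share a single
lineage. Options inject runs of Ns and truncate records below 600 bp
to exercise pairwise deletion and the length filter.

What the star history does *not* model: rank-dependent depth structure
(all between-species splits are equally deep), coalescent variance in
split times, recombination, codon structure beyond stop avoidance, and
sequencing error beyond N-injection. Passing the recovery tests
therefore shows the pipeline is correct under a clean barcode gap; it
does not show robustness to gapless or overlapping divergence
distributions, which real surveys exhibit (that is precisely what the
gap audit is for).

## Problem sizes and numerical choices

Property tests and the acceptance script run the canonical planted-gap
conditions — 20 species × 5 specimens, within 1% / between 10%, fixed
seed — where all three delimiters recover the truth partition exactly
(adjusted Rand index 1.0). Across free seeds the noise tail of the
substitution process occasionally pushes one specimen past a cutoff
(within-species pairwise distances at 658 bp have standard deviation
≈0.4% around a 1% mean), so exact recovery holds on 84–98% of seeds
depending on the method and ARI never fell below 0.978 in 50 trials.
Tie-breaks everywhere are deterministic (first appearance or
lexicographic); all outputs are sorted where order is not semantic, so
pipeline reruns are byte-identical.

## Known limitations

* The gap partitioner is an operational reinterpretation, not a
  reimplementation, of automatic barcode-gap discovery; likewise the
  refined-single-linkage approximation cannot promise the exact cluster
  counts of the registry implementation, whose refinement step is
  unpublished.
* Tree-based delimiters (GMYC variants, PTP) are out of scope; their
  partitions can be imported from TSV and participate in concordance,
  consensus and Wallace comparisons.
* The midpoint-root tie-break (lexicographic leaf pair) and NJ
  tie-break may differ from other programs; compare trees structurally.
* Wallace bootstrap resamples specimens independently, ignoring any
  within-cluster dependence structure beyond what resampling induces.
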