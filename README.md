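# motu-concord

Single-locus species delimitation for DNA barcodes, and the statistics
for judging it. Given aligned COI-5P sequences and specimen metadata,
`motu-concord` computes Kimura two-parameter (K2P) pairwise distances
with pairwise deletion, audits each species' barcode gap, clusters
specimens into molecular operational taxonomic units (MOTUs) with three
distance-threshold delimiters, classifies every reference species
against each MOTU partition as **MATCH / MERGE / SPLIT / MIXTURE**,
builds ≥k-of-m consensus MOTUs across methods, and quantifies pairwise
partition agreement with adjusted Wallace coefficients. A synthetic
barcode generator with planted truth (cryptic deep splits, label
merges, singletons) provides a known-answer test bed for every stage.

It is aimed at barcoding surveys of diverse, under-described groups —
the setting where morphospecies labels and barcode clusters disagree
and the disagreement is the result of interest.

## The statistics at the core

* **K2P distance**, pairwise deletion of non-ACGT sites:
  `K = −½ ln((1 − 2P − Q)·√(1 − 2Q))` with P, Q the transition and
  transversion proportions. Pairs with < 100 overlapping sites or a
  non-positive log argument are treated as missing.
* **Barcode-gap audit**: per species, the mean and maximum
  intraspecific distance, the nearest-neighbour (NN) distance to any
  heterospecific specimen, and flags for NN < 2%, NN ≤ max intra (no
  local gap) and max intra > 2% (deep divergence).
* **Delimiters**: single-linkage clustering at a fixed cutoff
  (proportion or bp); recursive barcode-gap partitioning above a prior
  on intraspecific divergence; and a refined-single-linkage
  approximation (2.2% p-distance seeds, gap-based refinement with a
  split-ratio acceptance test). Reference cluster ids (e.g. a BIN
  column) can be imported as a partition as well.
* **Concordance**: species S with MOTU set M(S) is MATCH iff
  |M(S)| = 1 and the MOTU is pure, MERGE iff that single MOTU is
  shared, SPLIT iff |M(S)| > 1 with all MOTUs pure, MIXTURE otherwise;
  summaries are reported over all species and over multi-specimen
  species only.
* **Adjusted Wallace** A→B: of the specimen pairs co-clustered in A,
  the chance-corrected fraction also co-clustered in B,
  `AW = (W − (1 − SID_B)) / SID_B` with SID Simpson's index of
  diversity; 95% CI by seeded bootstrap.

See `docs/methods.md` for the full model descriptions, defaults and
limitations.

## Worked example

Simulate a survey with a clean barcode gap (20 species × 5 specimens,
1% within-species vs 10% between-species K2P, two of the species
secretly spanning two deep lineages), then run the whole pathway:

```sh
motu-concord simulate --seed 7 --n-species 20 --specimens 5 \
    --intra 0.01 --inter 0.10 --cryptic-fraction 0.1 --out demo/sim
motu-concord pipeline --fasta demo/sim/barcodes.fasta \
    --metadata demo/sim/metadata.tsv --out demo/run --seed 7
```

The run prints `pipeline complete: 8/8 artifacts`. The MOTU counts
(`demo/run/motu_counts.tsv`):

```
method     n_motus
threshold  22
gap        22
resl       22
bin        22
```

All three delimiters find 22 MOTUs — the 18 ordinary species plus the
two cryptic species split in two each — agreeing with the generator's
planted lineages (imported via the `bin` column). The concordance
table (`demo/run/concordance.tsv`, threshold method shown) makes the
cryptic pair visible as SPLIT species:

```
method     denominator  category  count  denom  percent
threshold  all_species  MATCH     18     20     90.0
threshold  all_species  MERGE     0      20     0.0
threshold  all_species  SPLIT     2      20     10.0
threshold  all_species  MIXTURE   0      20     0.0
```

and the divergence summary (`demo/run/summary.tsv`) shows the planted
gap — within-species distances averaging 1.53% (max 11.06%, driven by
the cryptic splits) against congeneric between-species distances
averaging 10.61%:

```
statistic       n_taxa  n_comparisons  min_pct  mean_pct  max_pct  se_pct
within_species  100     200            0.00     1.53      11.06    0.15
within_genus    100     750            6.87     10.61     21.36    0.09
```

The adjusted-Wallace matrix (`demo/run/wallace.tsv`) reads
directionally: two specimens co-clustered by any delimiter here have a
100% chance of sharing a species label, while two conspecific
specimens have a 93.8% chance of sharing a MOTU (the cryptic splits
cost the reverse direction):

```
method   species              threshold            gap
species                       0.938 (0.883-1.000)  0.938 (0.879-0.996)
threshold 1.000 (1.000-1.000)                      1.000 (1.000-1.000)
```

The bundle also contains the midpoint-rooted NJ-K2P haplotype tree
(`tree.nwk`), the per-species gap audit (`gap_report.tsv`), all
partitions as TSV, the ≥4-of-m consensus and a MANIFEST.

Everything is also available as a library:

```python
from motu_concord import (SimConfig, simulate_dataset, distance_matrix,
                          threshold_partition, classify_concordance, Partition)

ds, truth, table = simulate_dataset(SimConfig(seed=7))
dm = distance_matrix(ds)
motus = threshold_partition(dm, cutoff=0.02)
species = Partition({r.specimen_id: r.species for r in ds.records})
report = classify_concordance(species, motus)
print(report.counts())
```

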