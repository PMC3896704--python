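# pedibd

Identity-by-descent variant prioritization in extended multiplex pedigrees.

`pedibd` is for statistical geneticists analyzing families with several
affected relatives (at least one affected cousin pair). The premise: a
susceptibility allele of appreciable effect that entered such a family
through one ancestor must lie on a haplotype shared identical-by-descent
(IBD) by every affected member. The package therefore (1) maps each
family's all-affected IBD regions from SNP-array genotypes, (2) filters
annotated exome variants down to rare, predicted-damaging alterations that
segregate in all affected members inside those regions, (3) summarizes
surviving genes across families, and (4) tests candidate-gene enrichment.
A synthetic-data generator emulates the whole study design, so every stage
is exercised end to end without external data.

## The model

**IBD sharing.** Per chromosome, a hidden Markov model over inheritance
vectors v ∈ {0,1}^m (one bit per meiosis; Lander–Green factorization).
Transitions flip each bit independently with the Haldane recombination
fraction θ = (1 − e^(−2d))/2 for inter-marker distance d Morgans;
emissions sum over founder-allele assignments weighted by panel allele
frequencies. The output is the per-marker posterior

    sharing[i] = P( ∃ founder allele carried by every affected | data )

computed by forward–backward, exact for the pedigree (validated against
exhaustive enumeration to 1e−8). The X chromosome uses one bit per
maternal meiosis (fathers pass their single X to daughters intact) and is
analyzed only when the affection pattern is X-compatible.

**Segments.** A marker is IBD when it lies in a run of ≥ 10 consecutive
markers with sharing > 0.5 (a sliding 10-SNV window, strict threshold);
maximal runs become segments with endpoints at the outermost qualifying
markers.

**Filter cascade.** VQSLOD > 0 and depth ≥ 4 → amino-acid-altering or
splice-site effects → minor-allele frequency < 5% in three reference
panels, an external exome cohort, and 308 internal control exomes (with a
`novel` tier for variants absent from all public catalogs) → segregation
in all affected under heterozygous, homozygous, and/or X-linked hemizygous
models → restriction to the family's IBD segments.

**Enrichment.** With N captured genes, K candidate-list genes, n hit
genes and k overlapping, fold = (k/K)/(n/N) and the p-value is the
hypergeometric upper tail P(X ≥ k), summed in log space and cross-checked
against exact rational arithmetic and a permutation null.

## Worked example

Simulate a three-family cousin-pair study (four 62.5-cM autosomes, 250
markers each at 0.25 cM; 2,000 annotated exome records per family; one
injected heterozygous damaging variant per family at panel frequency 0)
and run the full pipeline:

```sh
pedibd simulate --out study --seed 7 --n-families 3 \
    --n-exome-variants 2000 --markers-per-chrom 250 --template cousin_pair
pedibd run-all --config study/study.yaml --out results
```

This takes a few seconds and writes `segments.bed`, `sharing.tsv`,
`candidates.tsv`, `gene_summary.tsv`, `enrichment.json`, `qc.json` and
`manifest.json`. The candidate table:

```
family  chrom  pos       ref  alt  gene     effect    model  rarity  control_counts
F001    1      29694906  T    C    G1X0296  missense  het    novel   5/608
F001    1      31250102  C    T    G1X0312  missense  het    novel   0/616
F002    1      31250102  C    T    G1X0312  missense  het    novel   0/616
F003    1      31250102  C    T    G1X0312  missense  het    novel   0/616
```

Each family's exome collapses from 2,001 records to 1–2 candidates
(`manifest.json` records the funnel: e.g. F001 input 2001 → quality 1903 →
damaging 989 → rare/novel 458 → segregating 5 → in IBD 2). The injected
causal variant (gene `G1X0312`, the same simulated locus in each family)
survives in all three families, so the gene summary flags it
`multi_family`:

```
gene     n_families  families        multi_family  cis_pair_families
G1X0296  1           F001            0             -
G1X0312  3           F001,F002,F003  1             -
```

`enrichment.json` reports fold 4.98 with P = 0.19 — the hit genes are 5×
enriched in the candidate list (which contains the causal genes among 251
decoys), but with only 2 hit genes the tail probability is rightly
unimpressive. `qc.json` shows cross-platform concordance of ~98.9–99.1%
per family (two simulated array platforms at 0.5% allele-flip error) and
per-sample call-rate QC at the inclusive 98% threshold.

The same machinery is available as a library:

```python
from pedibd import FamilyIBDModel, SegmentParams

model = FamilyIBDModel.from_plink("study/F001.ped", "study/markers.map",
                                  "study/markers.freq", genotype_error=0.01)
results = model.fit()
print(results.summary())            # per-chromosome markers, sharing, segments
segments = results.call_segments(SegmentParams(window_markers=10,
                                               sharing_threshold=0.5))
```

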