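# Methods

`pedibd` implements rare-variant prioritization in extended multiplex
pedigrees: families ascertained for several affected relatives (always
including an affected cousin pair) are genotyped on a SNP array to map the
genomic regions their affected members co-inherit from a common ancestor,
and exome variant calls are then filtered down to rare, predicted-damaging
alterations that segregate in all affected members inside those regions.
This note documents the models, the numerical choices, and what the
synthetic data generator does and does not emulate.

## Multipoint IBD sharing model

The hidden state of the per-chromosome HMM is the inheritance vector
v ∈ {0,1}^m, one bit per meiosis (bit 0: the parent transmitted their own
paternal allele).  Meioses are ordered deterministically — non-founders by
person id, paternal before maternal — so the bit index is part of the model
contract.  Pedigrees must be fully specified (both parents present or
none), outbred (no loops), and have at least one genotyped affected
member; the meiosis count is capped (default 20, configurable), with
practical limits set by the 2^m state space well below the cap.

*Transitions.*  Between adjacent markers each bit flips independently with
the Haldane recombination fraction θ = (1 − e^(−2d))/2, d the inter-marker
map distance in Morgans.  A single sex-averaged map is used.  The flip
operator is applied one bit-axis at a time on the 2^m tensor, so a
transition costs m·2^m operations rather than 4^m.

*Emissions.*  The probability of the observed unphased genotypes given v
sums over assignments of alleles to the 2f founder haplotypes, each
founder allele being the alternate with the marker's panel frequency.
This is computed exactly by enumerating all 2^(2f) assignments with
vectorized masks; memory is bounded by chunking over states.  Markers at
which all samples are missing — or whose genotypes are impossible given
the pedigree — contribute a uniform emission.  An optional per-genotype
error term e (weight 1−e on a match, e/2 per mismatching genotype) makes
emissions robust to array miscalls; the low-level default is e = 0, and
the pipeline runner uses e = 0.01, which is the appropriate setting for
noisy array data.

*Output.*  Forward–backward posteriors are contracted against the
indicator "some founder allele is carried by every affected member", the
event relevant to a dominant/heterozygous transmission model.  A family
with a single affected member therefore shares trivially (probability 1
everywhere).  Affection status `unknown` never enters the sharing event.

*X chromosome.*  On X the vector holds one bit per non-founder (the
maternal meiosis): fathers transmit their single X to daughters intact and
nothing to sons.  Male genotypes use the diploid {0,2} convention; an
observed heterozygous male X call is treated as missing.  X is analyzed
only for families whose affection pattern is compatible with a single
X-linked founder allele (checked by exhaustive X gene-dropping over the
descent space).

The HMM is validated against an independent brute-force implementation
(explicit 2^m × 2^m transition matrices, per-state assignment sums) to
≤ 1e−8 on pedigrees up to 10 meioses.

## Segment calling

Per-marker sharing probabilities are thresholded strictly at 0.5 and a
marker is declared IBD when it lies in a run of at least `window_markers`
(default 10) consecutive above-threshold markers — equivalent to the
covering-window formulation.  Chromosomes shorter than the window require
every marker to qualify.  Segment endpoints are the outermost qualifying
markers' physical positions, 1-based inclusive; BED export converts to
0-based half-open.  Raising the threshold or the window can only shrink
the called set (verified by property tests).

A consequence worth knowing: a variant physically between the last
qualifying marker and the next marker falls outside the called segment
even when the underlying haplotype is shared; segment resolution is the
marker grid.  With a w-marker window at spacing s cM, no segment shorter
than w·s cM can be called.  For a two-affected cousin pair the causal
segment is the sum of two exponential arms of mean 25 cM (four relevant
meioses at 1%/cM), so the window rule itself bounds attainable recall:
P(segment ≥ 10 cM) ≈ 0.94.  At the generator's default 0.25 cM marker
spacing the bound is ≈ 0.995 and measured end-to-end recall is ≈ 0.98.

## LD pruning

`ld_prune` reproduces windowed pairwise-r² greedy pruning (window 50
markers, step 5, r² > 0.5 removes the later marker; monomorphic markers
are never removed for correlation).  Pruning is meant for *population
reference* genotypes: r² estimated from the handful of relatives in one
family reflects their shared descent, and pruning on it would delete the
IBD signal itself.  The pipeline runner therefore does not prune family
genotypes by default (the simulator's markers are drawn in population
linkage equilibrium, i.e. pre-pruned); the stage is available through the
`prune` subcommand, the `prune:` config section, and the model's
`prune_params` argument for inputs that do need it.

## Variant filter cascade

Per family and per inheritance model, annotated exome records pass:

1. **Call quality** — VQSLOD strictly > 0; per-sample genotypes with depth
   < 4 become missing ("minimum depth 4" is inclusive of 4); records with
   no remaining genotype are dropped.
2. **Damaging consequence** — effect ∈ {missense, nonsense, splice_site};
   splice sites are defined at annotation time as the two nucleotides
   flanking an exon.
3. **Rarity** — minor-allele frequency strictly < 5% in each of three
   reference panels, in the external exome cohort, and in internal
   controls (alt/total called control chromosomes).  Survivors are tiered
   `novel` when absent from all public catalogs (external exomes,
   thousand-genomes flag, dbSNP); internal-control counts do not affect
   novelty.  Zero called control chromosomes leave the control frequency
   unknown — kept, flagged.
4. **Segregation** — het: every affected heterozygous; hom: every affected
   alternate-homozygous; xlinked: X records only, affected males
   hemizygous-alt, affected females heterozygous (homozygous acceptable
   via a config flag).  A missing genotype in any affected member fails
   the record; unaffected carriers are never penalized (incomplete
   penetrance).
5. **IBD restriction** — the position must fall inside one of the family's
   all-affected segments (inclusive bounds).

The output is ordered by (chromosome, position, model).  Gene summaries
aggregate candidates across families: genes hit in ≥ 2 families, and
families contributing ≥ 2 distinct variants in one gene — two heterozygous
variants that each segregate in all affected members of a family
necessarily ride the same shared haplotype, hence "cis pairs".

On outbred simulated families the homozygous model yields almost nothing
(mean < 0.1 survivors per family across replicates): an outbred pedigree
offers no mechanism for all affected to be homozygous for a rare allele
unless every married-in parent happens to carry it.

## Enrichment and QC

Candidate-gene enrichment uses the one-sided hypergeometric upper tail
P(X ≥ k) with N = genes captured by the exome design (supplied
explicitly), K = candidate-list genes in the universe, n = genes with
surviving variants, k = their overlap; fold = (k/K)/(n/N).  The tail is
summed in log space (log-gamma binomials) and matches exact rational
arithmetic to ≤ 1e−12 relative over all parameter combinations with
N ≤ 60, and a uniform permutation null within Monte-Carlo error.  Symbols
are compared uppercased and stripped; no alias resolution is attempted.

Cross-platform concordance matches sites on (chromosome, position),
complements dosages when the platforms label opposite alleles as the
alternate, excludes sites missing on either platform from the denominator,
and averages per-sample identical-call fractions unweighted.  Call-rate QC
passes a sample at ≥ 98% non-missing, inclusive.

## Synthetic data generator

The generator emulates the study design end to end so every stage is
testable without external data:

- **Pedigrees** from templates (cousin pair, cousin pair with affected
  sibs, avuncular plus cousins, second cousins), 2–5 affected with at
  least one affected cousin pair; affected sex is drawn 90% male,
  matching the strong male bias of the emulated phenotype.  Templates
  link branches through female transmitting parents so X-linked
  inheritance is structurally possible.
- **Markers**: evenly spaced per chromosome (default 4 autosomes × 500
  markers at 0.25 cM ≈ 2,000 markers; 1 cM ≡ 1 Mb), panel alternate
  frequencies uniform on [0.2, 0.8] so sharing is estimable.
- **Gene dropping**: founder haplotypes drawn allele-wise from panel
  frequencies; meioses transmit Haldane-recombinant gametes (no
  interference); X handled as above.  Gene-dropped tables are Mendelian
  consistent by construction (checked in tests).
- **Causal injection** by conditional resampling: the variant is placed on
  a haplotype of a founder ancestral to all affected and the causal
  chromosome's descent is redrawn until the configured model holds (het:
  all affected carry exactly one copy; hom: all affected homozygous, every
  founder contributing a carrier haplotype; xlinked: males hemizygous,
  females heterozygous).  Marker data and causal variant therefore share
  one coherent descent history; linking ancestors are obligate carriers
  automatically.
- **Array noise**: genotypes go missing at 1% and suffer single-allele
  flips at 0.5% (call rate ≈ 99%, cross-platform concordance of two
  independent noisy copies ≈ 98–99%).
- **Exome tables** (default 5,000 records per family; the emulated study's
  ~90,000 positions are reachable by config): a common/rare frequency
  mixture, catalog membership correlated with frequency, binomial control
  counts over 2 × 308 chromosomes with per-variant missingness uniform on
  [0, 2%] (denominators 604–616), depth/VQSLOD with configurable failure
  fractions (2% and 5%), and Mendelian single-locus genotype drops.

What it does **not** emulate: population LD between markers (markers are
pre-pruned by construction), sex-specific or non-uniform genetic maps,
genotyping batch effects, allelic dropout correlated with depth, indels,
annotation errors, and relatedness between families.  Passing tests
demonstrate correctness of the machinery under these idealized conditions,
not robustness to everything real arrays and exomes do.

## Numerical and design choices

- Strict inequalities exactly where the thresholds are worded strictly
  (VQSLOD > 0, MAF < 0.05, sharing > 0.5); inclusive where worded
  inclusively (depth ≥ 4, call rate ≥ 98%).
- Sharing event = "at least one founder allele carried by all affected"
  (the dominant-model reading); a pairwise-minimum alternative was
  considered and rejected as not matching the all-affected restriction.
- Segment windows require every marker above threshold; a window-mean rule
  was considered and rejected.
- Obligate carriers are the intersection over consistent transmission
  origins; a sibship's two candidate parents are returned as an ambiguous
  set rather than guessed.
- All randomness flows from one seed through `numpy` SeedSequence
  spawning; equal config and seed give byte-identical outputs.
- Desk-scale problem sizes used by the validation suite: oracle
  comparisons on ≤ 10-meiosis pedigrees with 15–20 markers; recall over
  100 single-family cousin-pair replicates with two 50-cM autosomes (200
  markers each) and 1,000 exome records; the exhaustive hypergeometric
  sweep at N ≤ 60.

## Known limitations

- The state space grows as 2^m; families beyond ~12–14 meioses need the
  cap raised and considerable memory/time, and founder-couple symmetry
  reduction is not implemented.
- Genotype error handling is a single symmetric per-genotype term, not a
  platform error model.
- Compound heterozygotes in trans are out of scope (the cascade reports
  cis pairs only), as are pedigrees with loops and half-founders.
- The hypergeometric test treats genes as exchangeable; no correction for
  gene length or capture efficiency is attempted.
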