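# longamp

Toolkit for comparing **long ribosomal-operon amplicons** (full 16S rRNA gene
+ internal transcribed spacer + 23S prefix, ~2.5 kb) against the short 16S
amplicons (V1–V3, V4) and full-16S designs they nest, for microbiome
profiling. It is aimed at researchers evaluating amplicon designs — how much
taxonomic resolution a longer amplicon buys, what biases and dropouts it
introduces, and whether it changes the statistical power of community
comparisons — without waiting on a sequencing run: everything can be
exercised end-to-end on synthetic communities with machine-readable ground
truth.

## What it does

- **Degenerate-primer in-silico PCR** (`longamp.primers`): IUPAC-aware primer
  site finding on both strands with per-primer mismatch budgets and exact
  3'-terminal matching; nearest-downstream pairing into products with
  insert-only coordinates; over-long products (e.g. from non-contiguous
  operons) are observed and then length-filtered rather than silently lost.
  `trim_to_subregion` derives nested short-amplicon datasets from long reads
  by internal primer trimming — the basis of like-for-like design comparison.
- **rRNA operon census** (`longamp.census`): one record per 16S copy, paired
  with the nearest same-strand downstream 23S; contiguity test (default gap
  threshold 2 kb); **theoretical ASV counts** per (taxon, design) — the number
  of distinct amplicon sequences a design can possibly yield from a genome —
  and a per-copy compatibility report (amplifiable / mismatch /
  non-contiguous / length).
- **Community profiling** (`longamp.profile`): exact-dereplication ASV
  calling, lowest-common-ancestor classification against a reference amplicon
  set (Hamming / banded edit distance), classification-depth rates per rank,
  taxon aggregation, and hypergeometric rarefaction.
- **Diversity statistics** (`longamp.diversity`): Bray-Curtis, Jaccard,
  unweighted and weighted UniFrac implemented from scratch (validated against
  branch-enumeration oracles and scikit-bio); neighbor-joining feature trees
  (midpoint-rooted); PCoA by Gower double-centering; single-factor
  adonis-style **PERMANOVA** with exact exhaustive enumeration at small n.
- **Mock-community evaluation** (`longamp.mock`): expected composition under
  equal-mass gDNA pooling (proportion ∝ rRNA copies / genome size),
  observed-vs-expected bias across replicates (mean ± sample SD, log2 bias),
  amplification-bias recovery, and theoretical-vs-observed ASV concordance.
- **Synthetic data** (`longamp.simulate`): genomes with controlled operon
  architecture (copy number, 16S/ITS variant structure, strain markers,
  non-contiguous operons), two-cohort communities with fold-change effects,
  and per-design amplicon reads with per-read provenance.

## The statistics at the core

For samples *i, j* with count vectors *x, y* over features (and a rooted
feature tree with branch lengths *l_b*):

- Bray-Curtis: `d = Σ|x_i − y_i| / Σ(x_i + y_i)`
- Jaccard: `d = 1 − |supp(x) ∩ supp(y)| / |supp(x) ∪ supp(y)|`
- unweighted UniFrac: shared-tree branch length unique to one sample over
  branch length covered by either
- weighted UniFrac (classic, non-normalized): `Σ_b l_b |A_b/A_T − B_b/B_T|`

PERMANOVA partitions the squared distances: `SS_total = Σ_{i<j} d²_{ij}/N`,
`SS_within = Σ_g Σ_{i<j∈g} d²_{ij}/n_g`, pseudo-F =
`(SS_between/(a−1)) / (SS_within/(N−a))`, `R² = SS_between/SS_total`, with
`p = (1 + #{F* ≥ F}) / (1 + n_permutations)` under group-size-preserving
label permutations (exact enumeration when the number of distinct labeled
assignments is ≤ 10,000).

Under equal-mass pooling of genomic DNA the expected read proportion of
taxon *i* with *c_i* operon copies and genome size *s_i* is
`(c_i/s_i) / Σ_j (c_j/s_j)`.

## Worked example

```python
import longamp as la

designs = la.default_designs()

# a genome with 10 operon copies carrying 3 ITS variants
g = la.generate_genome(la.GenomeSpec(
    name="Varia_testis_V1", n_operons=10, n_its_variants=3,
    genome_size=60_000, seed=11))

for name in ("V4", "V1V3", "FULL16S", "STRAINID"):
    rec = la.theoretical_asv_count([g.to_record()], designs[name])[0]
    print(name, rec.operon_copies, rec.unique_amplicons)
```

prints

```
V4 10 1
V1V3 10 1
FULL16S 10 1
STRAINID 10 3
```

— all ten copies share one 16S sequence, so every 16S-internal design
collapses them to a single ASV, while the operon-spanning design resolves
the three ITS variants. A non-contiguous operon shows the opposite failure
mode:

```python
tm7 = la.generate_genome(la.GenomeSpec(
    name="Nanosynbacter_like_N1", n_operons=1, its_length=450,
    non_contiguous=True, insertion_length=4_570, genome_size=20_000, seed=13))
h = la.in_silico_pcr(tm7.contigs, designs["STRAINID"])[0]
print(h.length, h.passed_length_filter)   # 7069 False
print(la.in_silico_pcr(tm7.contigs, designs["V1V3"])[0].passed_length_filter)  # True
```

The 7,069 bp product exceeds the long design's 3,500 bp ceiling, so the
taxon drops out of long-amplicon datasets while remaining visible to the
16S-internal design.

A CLI mirrors the library (`longamp ispcr | trim | census | profile |
diversity | permanova | mockeval | simulate`).

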