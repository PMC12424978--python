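# Methods

This note documents the models, conventions, and numerical choices behind
`longamp`, and what the synthetic-data generator does and does not emulate.

## Primer matching and in-silico PCR

Primers are IUPAC-degenerate oligos matched asymmetrically against an
unambiguous template: a primer code matches any base in its degeneracy set,
while a template `N` matches *no* primer base and counts as a mismatch.
This mirrors physical annealing — the synthesized oligo is a concrete
mixture, the template either pairs or it does not. Matching is implemented
as 4-bit base-set intersection over sliding windows, so a site is a window
whose mismatch count is within the per-primer budget (default 2) and whose
3'-terminal bases (default 3) are mismatch-free; the terminal-exactness
rule reflects that polymerase extension is far more sensitive to 3' than
internal mismatches. A site search covers both strands; a `-` strand hit
means the primer matches the reverse complement of the top strand.

In-silico PCR pairs each forward site with its *nearest downstream*
reverse site in both orientations. Products are scanned up to a hard
pairing ceiling of 10,000 bp, far beyond any plausible amplification
length, and only then length-filtered against the design's bounds
(short designs 100–600 bp, full-16S 1,200–1,800 bp, full-operon
1,000–3,500 bp). Observing before filtering is deliberate: an over-long
product from a non-contiguous operon is an analytically important *event*
(the taxon drops out of the long-amplicon dataset), not an absence of
signal. Reported amplicon sequences are the inter-primer insert only,
oriented 5'→3' from the forward primer, matching the primer-removal
convention of ASV workflows. Coordinates are 0-based half-open internally
and 1-based inclusive in TSV reports.

Nested datasets are derived from long reads by locating the sub-design's
primer sites *inside* each read and excising the insert. Sub-designs that
share the long design's forward primer (V1–V3, full 16S both start at 27F)
have no internal forward site in a primer-free read; the
`assume_shared_forward` option then anchors the forward boundary at the
read's 5' end. V4, whose sites are fully internal, needs no anchor. The
shipped default designs use the canonical universal primers (27F, 534R,
515F, 806R, 1492R); the long design's reverse primer is a **synthetic
stand-in** for the unpublished commercial kit primer, binding ~530 bp into
the 23S gene so the default product is ~2.5 kb. All designs are
overridable via a YAML config.

## Operon census and theoretical ASV counts

A census record is one 16S instance paired with the nearest same-strand
downstream 23S. An operon is *contiguous* when the 16S→23S gap is at most
2,000 bp (configurable); typical spacers are under 1.5 kb, so this cleanly
separates operons interrupted by protein-coding insertions. Unpaired 16S
copies (e.g. at contig ends in draft assemblies) are kept in the census
with an infinite-gap sentinel and can never amplify under operon-spanning
designs. Annotation-driven mode (GFF3 rRNA features) is preferred;
primer-driven fallback locates the 16S by the full-16S design and takes
the long design's reverse-primer site as 23S evidence, so its gap estimate
includes the ~530 bp 23S prefix and is documented as approximate.

The theoretical ASV count of a (taxon, design) pair is the number of
*distinct* insert sequences over the taxon's amplifiable operon copies —
the ceiling on how many ASVs an error-free experiment could observe. Every
census copy receives exactly one status per design (amplifiable, excluded
by mismatch, by non-contiguity, or by product length), so the statuses
partition the census; a copy with an observed but over-long product is
classed `length`, and `non_contiguous` is reserved for copies where no
product forms and the design spans the broken 16S–23S junction.

## Profiling

ASV calling is **exact sequence dereplication** with an optional minimum
total count. This is the pipeline's main deliberate divergence from
denoiser-based workflows: synthetic reads are error-free (or carry a known
substitution rate), so an error model would add machinery without changing
the analysis logic. Consequences: with error-free reads dereplication is
lossless and observed ASV sets equal the theoretical sets; with noisy
reads, error variants appear as singletons and the count filter stands in
for denoising.

Classification assigns each feature the lowest common ancestor of its
best-distance reference matches: substitution-only Hamming distance for
equal lengths, banded global edit distance (edlib) for length differences
up to 10, no match beyond that; the default radius is 1% of query length.
"Strain" in a reference lineage means *ribotype* — the set of rRNA operon
sequences — which is what rRNA amplicons can actually resolve.
Classification-depth rates are the per-sample read fraction classified at a
rank or deeper; the median across samples is the headline summary.
Rarefaction subsamples without replacement (multivariate hypergeometric),
drops samples below the target depth with a warning, and is deterministic
given a seed.

## Diversity statistics

The four community distances are implemented directly from their
definitions (see README for formulas). Weighted UniFrac defaults to the
classic non-normalized variant; the normalized form is a flag. UniFrac is
computed in one postorder pass accumulating subtree counts, and is
validated against an explicit per-branch enumeration oracle and against
scikit-bio to 1e-12.

Feature trees are neighbor-joining on pairwise p-distances (Hamming for
equal lengths, global edit distance over the longer length otherwise),
negative branch lengths clamped to zero, midpoint-rooted, with ids
processed in lexicographic order for determinism. No fidelity to any
externally built tree is claimed — UniFrac behaviour is validated against
oracles and synthetic truth, not against a reference tree.

PCoA double-centers −½D² (Gower), takes the symmetric eigendecomposition,
and returns coordinates for positive eigenvalues only; negative
eigenvalues (non-Euclidean distances) are reported and their axes dropped.
PERMANOVA is single-factor (the comparisons this package serves are one
factor each); p-values use the +1-corrected permutation estimator and are
reported raw — any multiplicity adjustment across metrics or comparisons
is left to the caller. When the number of distinct labeled assignments is
at most 10,000 the test enumerates all of them and p is exact; the
balanced 3+3 toy (within-distance 1, between-distance 2) gives p = 2/20
exactly. Degenerate inputs have fixed conventions: all-zero distances give
R² = 0 and p = 1; zero within-group sum of squares gives an infinite
pseudo-F sentinel with p still from permutations. At very small group
sizes the permutation p is conservative because distinct partitions are
few and ties with the observed F are common; calibration checks therefore
use groups of 6–10, where ties are negligible.

## Mock-community evaluation

Equal-mass gDNA pooling implies the expected *read* proportion of taxon
*i* is `(c_i/s_i)/Σ_j(c_j/s_j)` (operon copies per genome base). This
amplicon-level basis is the default because sequencing observes reads, not
cells; a genome-equivalents basis (`1/s_i`) is available by flag. The
shipped eight-strain reference table (genome sizes and rRNA copy numbers
of the standard equal-mass mock, *Bacillus subtilis* at 10 copies)
reproduces the vendor-stated community: Bacillus 0.174, Staphylococcus
0.155, Lactobacillus 0.184. Replicate summaries use the sample standard
deviation (n−1). `MockComparison.log2_bias` is log2(observed/expected),
which for a biased taxon under-states the planted fold because proportions
renormalize; `recover_amplification_bias` divides by the median
observed/expected ratio of the other taxa, which share the
renormalization factor, and recovers the fold itself.

## Synthetic data: what it emulates, and what it does not

A generated genome is a random background with *n* planted operons:
a fixed 1,540 bp 16S scaffold, a genome-specific ITS (300–700 bp), an
optional non-contiguity insertion, and a 900 bp 23S-prefix scaffold, on
alternating strands. The scaffolds are synthetic sequences shipped as
package data with the default designs' primer motifs embedded at the
canonical offsets; they are not real rRNA genes. Controlled structure:

- **Variant architecture** — `n_16s_variants`/`n_its_variants` derive
  variants by substituting disjoint position blocks (guaranteeing pairwise
  distinctness) at the given divergence rates (defaults 0.5% in 16S, 2% in
  ITS — divergence concentrated in the spacer, as in real operons),
  assigned to copies round-robin. The theoretical long-amplicon ASV count
  is then min(lcm(n16, nITS), n_operons), which the census reproduces
  exactly (round-trip test).
- **Strain markers** — `ssu_tag_mutations` plants a shared 16S marker in a
  chosen region, letting tests build strain pairs distinguishable only by
  specific sub-regions (only-ITS, V1–V3-but-not-V4, etc.).
- **Non-contiguous operons** — an insertion between ITS and 23S; the
  TM7x-style configuration used in validation (ITS 450 bp + 4,570 bp
  insertion) makes the long design's product exactly 7,069 bp, the scale
  of the known oral-Saccharibacteria case, which the 3,500 bp ceiling
  rejects while 16S-internal designs amplify normally.
- **Primer-site mismatches** — mutations centred in a named primer window
  (clear of the 3'-terminal bases on either strand), to emulate
  primer–template incompatibility.

Communities are two cohorts whose proportions differ by fold-changes on
named taxa (renormalized; closed-form), with optional Dirichlet
overdispersion. Reads draw a taxon per sample proportion, an operon copy
uniformly among amplifiable copies, and the design's insert with iid
substitutions; taxa with no amplifiable copy drop out silently (logged),
emulating amplification dropout. Per-read provenance (genome, operon copy)
is recorded; all randomness flows from per-operation seeds kept in the
truth objects.

Not emulated: platform-specific error profiles (indels, homopolymer
errors), chimeras, PCR saturation, extraction/lysis bias, paired-end
merging artifacts, 5S rRNA, and tRNAs inside the ITS. Passing tests
therefore demonstrate the correctness of the *analysis logic* — primer
arithmetic, census, dereplication, classification semantics, metric and
test calibration — not robustness to real sequencing noise or wet-lab
bias.

## Validation workloads and problem sizes

The validation suite (`longamp.validation`, driven by
`tests/test_acceptance.py` and `scripts/acceptance.py`) runs at desk
scale, chosen to finish in well under a minute total on one CPU: 10,000
random instances for the primer-matching oracle; 500 random ≤8-leaf trees
for the UniFrac oracle (agreement to 1e-12); 2,000 null simulations of 999
permutations each for PERMANOVA type-I error (two groups of 10, twenty
features, depth 1,000); bias recovery at depth 10⁵ over 5 replicates of an
eight-taxon equal-mass mock; cohort detection with 12 samples per cohort
at depth 5,000 with fold-3 effects on one common and one rare taxon (the
rare one straddles the detection threshold so presence/absence metrics
also carry signal). The type-I band [0.04, 0.06] is approximately ±2
Monte-Carlo standard errors around the exact 0.05 level, so a single
seeded estimate sits outside it for roughly one seed in twenty even for a
perfectly calibrated test.

## Known limitations

- Primer-driven census mode conflates the ITS with the 23S prefix in its
  gap estimate; use annotations when available.
- Exact dereplication is not a denoiser; real noisy data need DADA2-class
  error modelling upstream.
- LCA classification uses global distances, not alignment-free k-mer or
  local-alignment search; references must be amplicon-matched in span.
- NJ/p-distance trees are adequate for UniFrac's branch-sharing structure
  at desk scale but are not phylogenetically optimal.
- Single-factor PERMANOVA only; no strata, no multi-factor designs.
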