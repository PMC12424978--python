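"""End-to-end validation workloads: oracle agreement, statistical
calibration, parameter recovery, and structural reproductions of the
mock-community logic on synthetic truth.

Each function regenerates its own inputs from a seed and recomputes its
quantity from scratch through the package's public pipeline; the naive
reference implementations here (position-by-position primer scans,
per-branch UniFrac enumeration) deliberately share no code with the
optimized paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from . import census as census_mod
from .diversity import beta_diversity, build_tree, permanova, unifrac
from .mock import (
    compare_observed_expected,
    expected_composition,
    recover_amplification_bias,
)
from .primers import default_designs, find_primer_sites, in_silico_pcr
from .profile import aggregate_taxa, classify_table, dereplicate_asvs, relative_abundance
from .simulate import (
    GenomeSpec,
    generate_community,
    generate_genome,
    generate_reads,
    reference_from_genomes,
)

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _naive_sites(contig: str, primer: str, max_mismatch: int, terminal: int):
    k = len(primer)
    t = min(terminal, k)
    sets = [_IUPAC_SETS[c] for c in primer]
    out = []
    for pos in range(len(contig) - k + 1):
        win = contig[pos:pos + k]
        rc = "".join(_COMP[c] for c in reversed(win))
        m = sum(1 for s, c in zip(sets, win) if c not in s)
        if m <= max_mismatch and all(c in s for s, c in zip(sets[-t:], win[-t:])):
            out.append((pos, "+", m))
        m = sum(1 for s, c in zip(sets, rc) if c not in s)
        if m <= max_mismatch and all(c in s for s, c in zip(sets[-t:], rc[-t:])):
            out.append((pos, "-", m))
    out.sort()
    return out


def primer_oracle_agreement(n_instances: int = 10_000, seed: int = 0) -> dict:
    """Fraction of random (contig, primer) instances on which the optimized
    site finder returns exactly the exhaustive-scan hit list."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    alphabet = np.array(list("ACGTRYSWKMN"))
    agree = 0
    for _ in range(n_instances):
        contig = "".join(rng.choice(bases, size=60))
        primer = "".join(rng.choice(alphabet, size=12))
        got = [(h.position, h.strand, h.mismatches)
               for h in find_primer_sites(contig, primer, 2, 3)]
        if got == _naive_sites(contig, primer, 2, 3):
            agree += 1
    return {"agreement": agree / n_instances, "n": n_instances}


def _random_tree(rng: np.random.Generator, n_leaves: int):
    from skbio import TreeNode
    nodes = []
    for i in range(n_leaves):
        leaf = TreeNode(name=f"L{i}")
        leaf.length = float(rng.uniform(0.05, 1.0))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.05, 1.0))
        nodes = [x for x in nodes if x is not a and x is not b] + [parent]
    nodes[0].length = None
    return nodes[0]


def _enumerated_unifrac(tree, x, y, weighted):
    at, bt = sum(x.values()), sum(y.values())
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        leaves = {tip.name for tip in node.tips(include_self=True)}
        a = sum(x.get(l, 0) for l in leaves)
        b = sum(y.get(l, 0) for l in leaves)
        if weighted:
            num += length * abs(a / at - b / bt)
        else:
            if (a > 0) != (b > 0):
                num += length
            if a > 0 or b > 0:
                den += length
    return num if weighted else (num / den if den else 0.0)


def unifrac_oracle_max_delta(n_pairs: int = 500, seed: int = 0) -> dict:
    """Max |difference| between the postorder UniFrac implementation and a
    per-branch enumeration oracle, over random trees of up to 8 leaves."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_pairs:
        n = int(rng.integers(3, 9))
        tree = _random_tree(rng, n)
        x = {f"L{i}": int(v) for i, v in enumerate(rng.integers(0, 6, n))}
        y = {f"L{i}": int(v) for i, v in enumerate(rng.integers(0, 6, n))}
        if sum(x.values()) == 0 or sum(y.values()) == 0:
            continue
        for weighted in (False, True):
            d1 = unifrac(tree, x, y, weighted=weighted)
            d2 = _enumerated_unifrac(tree, x, y, weighted)
            worst = max(worst, abs(d1 - d2))
        done += 1
    return {"max_abs_delta": worst, "n": n_pairs}


def permanova_toy_exact_p() -> dict:
    """Balanced two-group toy (within-distance 1, between-distance 2):
    exhaustive enumeration of the 20 assignments gives p = 2/20."""
    n = 6
    d = np.full((n, n), 2.0)
    d[:3, :3] = 1.0
    d[3:, 3:] = 1.0
    np.fill_diagonal(d, 0.0)
    res = permanova(d, ["a"] * 3 + ["b"] * 3)
    return {"p": res.p_value, "n": n, "method": res.method}


def permanova_type_i_error(n_sims: int = 2_000, n_permutations: int = 999,
                           seed: int = 0) -> dict:
    """Rejection rate at alpha = 0.05 for iid null communities (two groups
    of 10; group sizes large enough that permutation ties are negligible)."""
    rng = np.random.default_rng(seed)
    n_per_group, n_feat, depth = 10, 20, 1_000
    n = 2 * n_per_group
    groups = ["a"] * n_per_group + ["b"] * n_per_group
    props = np.full(n_feat, 1.0 / n_feat)
    rejections = 0
    for _ in range(n_sims):
        counts = rng.multinomial(depth, props, size=n).astype(float)
        sums = counts[:, None, :] + counts[None, :, :]
        diffs = np.abs(counts[:, None, :] - counts[None, :, :])
        d = diffs.sum(axis=2) / sums.sum(axis=2)
        res = permanova(d, groups, n_permutations,
                        seed=int(rng.integers(2 ** 31)), exhaustive=False)
        if res.p_value <= 0.05:
            rejections += 1
    return {"rate": rejections / n_sims, "n": n_sims}


def _mock_genomes(seed: int):
    genera = ["Alpha", "Bravo", "Charlie", "Delta", "Echo", "Foxtrot", "Golf", "Hotel"]
    genomes, rows = {}, []
    for i, genus in enumerate(genera):
        name = f"{genus}_mockus_M{i + 1}"
        spec = GenomeSpec(name=name, n_operons=3 + i % 5,
                          n_its_variants=1 + i % 3,
                          genome_size=55_000 + 4_000 * i, seed=seed + i)
        genomes[name] = generate_genome(spec)
        rows.append((name, spec.genome_size, spec.n_operons))
    return genomes, expected_composition(rows)


def mock_bias_recovery(depth: int = 100_000, n_replicates: int = 5,
                       fold: float = 1.6, seed: int = 0) -> dict:
    """Plant a ``fold`` amplification bias on one taxon of an equal-mass
    synthetic mock, run the full pipeline, and recover log2(fold)."""
    genomes, expectations = _mock_genomes(seed + 1_000)
    taxa = [e.taxon for e in expectations]
    base = {e.taxon: e.expected_proportion for e in expectations}
    truth = generate_community(taxa, n_per_cohort=n_replicates,
                               base_composition=base,
                               cohort_names=("rep", "unused"), seed=seed + 1)
    truth.proportions = truth.proportions.loc[truth.cohorts == "rep"]
    biased = taxa[2]
    design = default_designs()["STRAINID"]
    rs = generate_reads(truth, genomes, design, depth, seed=seed + 2,
                        bias={biased: fold})
    table = dereplicate_asvs(rs.reads)
    reference = reference_from_genomes(list(genomes.values()), design)
    assignments = classify_table(table, reference, max_distance=0)
    agg = aggregate_taxa(table, assignments, "strain")
    reps = relative_abundance(agg)
    df = compare_observed_expected(reps, expectations)
    recovered = recover_amplification_bias(df, biased)
    # 3-sigma multinomial band via the delta method on the log2 ratio
    obs = df.set_index("taxon")["observed_mean"]
    n_reads = depth * n_replicates
    se = 0.0
    for t in (biased, taxa[0]):  # biased taxon and a baseline representative
        p = obs[t]
        se += (1 - p) / (p * n_reads)
    band = 3 * math.sqrt(se) / math.log(2)
    return {"recovered_log2": recovered, "target_log2": math.log2(fold),
            "band": band, "n": n_reads}


def cohort_effect_detection(fold: float = 3.0, n_per_cohort: int = 12,
                            depth: int = 5_000, seed: int = 0) -> dict:
    """Two cohorts, ``fold`` effect on two taxa: PERMANOVA p per metric.

    The base composition spans common to rare taxa; the effect hits one
    common and one rare taxon. The rare taxon sits near the detection
    threshold at the given depth, so the fold change shifts its
    per-sample presence as well as its abundance — giving the
    presence/absence metrics (Jaccard, unweighted UniFrac) signal, not
    just the abundance-weighted ones.
    """
    specs = [
        GenomeSpec(name=f"Taxon{chr(65 + i)}_synth_S{i + 1}", n_operons=3 + i % 3,
                   n_its_variants=1 + i % 2, genome_size=50_000, seed=seed + 50 + i)
        for i in range(8)
    ]
    genomes = {s.name: generate_genome(s) for s in specs}
    taxa = sorted(genomes)
    base = dict(zip(taxa, (0.30, 0.22, 0.16, 0.12, 0.09, 0.06, 0.0492, 0.0008)))
    truth = generate_community(taxa, n_per_cohort=n_per_cohort,
                               base_composition=base,
                               effects={taxa[0]: fold, taxa[-1]: 1 / fold},
                               seed=seed + 3)
    design = default_designs()["STRAINID"]
    rs = generate_reads(truth, genomes, design, depth, seed=seed + 4)
    table = dereplicate_asvs(rs.reads)
    tree = build_tree(table.sequences)
    groups = truth.cohorts.loc[table.sample_ids].tolist()
    pvals = {}
    for metric in ("braycurtis", "jaccard", "unweighted_unifrac", "weighted_unifrac"):
        dm = beta_diversity(table, metric, tree)
        res = permanova(dm, groups, 999, seed=seed + 5, exhaustive=False)
        pvals[metric] = res.p_value
    return {"p_values": pvals, "n": 2 * n_per_cohort}


def mock_structural_checks(seed: int = 0) -> dict:
    """Error-free pipeline vs theory: per-taxon observed == theoretical ASV
    counts; ASV counts monotone over nested designs; non-contiguous-operon
    taxon amplified by V1-V3 but not by the long design (7,069 bp product)."""
    designs = default_designs()
    genomes, expectations = _mock_genomes(seed + 2_000)
    taxa = [e.taxon for e in expectations]
    base = {e.taxon: e.expected_proportion for e in expectations}
    truth = generate_community(taxa, n_per_cohort=3, base_composition=base,
                               cohort_names=("rep", "unused"), seed=seed + 6)
    truth.proportions = truth.proportions.loc[truth.cohorts == "rep"]
    records = [g.to_record() for g in genomes.values()]

    # observed == theoretical per taxon (long design, error-free reads)
    design = designs["STRAINID"]
    rs = generate_reads(truth, genomes, design, depth=20_000, seed=seed + 7)
    table = dereplicate_asvs(rs.reads)
    reference = reference_from_genomes(list(genomes.values()), design)
    assignments = classify_table(table, reference, max_distance=0)
    from .mock import asv_concordance
    theo = census_mod.theoretical_asv_count(records, design)
    conc = asv_concordance(table, assignments, theo)
    concordant = float((conc["observed_asvs"] == conc["expected_asvs"]).mean())

    # nested monotonicity of theoretical counts
    order = ["V4", "V1V3", "FULL16S", "STRAINID"]
    per_design = {d: {r.taxon: r.unique_amplicons
                      for r in census_mod.theoretical_asv_count(records, designs[d])}
                  for d in order}
    monotone = all(
        per_design[a][t] <= per_design[b][t]
        for a, b in itertools.pairwise(order) for t in taxa
    )

    # non-contiguous operon: long design product over-long, short design fine
    tm7 = generate_genome(GenomeSpec(
        name="Nanosynbacter_like_N1", n_operons=1, its_length=450,
        non_contiguous=True, insertion_length=4_570, genome_size=20_000,
        seed=seed + 8))
    long_hits = in_silico_pcr(tm7.contigs, designs["STRAINID"], tm7.name)
    short_hits = in_silico_pcr(tm7.contigs, designs["V1V3"], tm7.name)
    return {
        "concordant_fraction": concordant,
        "monotone": monotone,
        "long_product_bp": long_hits[0].length if long_hits else 0,
        "long_passes": sum(h.passed_length_filter for h in long_hits),
        "short_passes": sum(h.passed_length_filter for h in short_hits),
        "n_taxa": len(taxa),
    }
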