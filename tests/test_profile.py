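"""ASV dereplication, LCA classification, rarefaction, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longamp import (
    FeatureTable,
    ReferenceRecord,
    aggregate_taxa,
    classification_rate,
    classify_lca,
    classify_table,
    dereplicate_asvs,
    generate_community,
    generate_reads,
    rarefy,
    relative_abundance,
    theoretical_asv_count,
)
from longamp.simulate import reference_from_genomes


class TestDereplicate:
    def test_identical_reads_collapse(self):
        t = dereplicate_asvs({"s1": ["ACGT"] * 100})
        assert t.counts.shape == (1, 1)
        assert t.counts.iloc[0, 0] == 100
        assert t.sequences[t.feature_ids[0]] == "ACGT"

    def test_min_total_count_threshold(self):
        reads = {"s1": ["AAAA"] * 5 + ["CCCC"] * 3 + ["GGGG"]}
        t = dereplicate_asvs(reads, min_total_count=2)
        assert t.counts.shape[0] == 2
        assert set(t.sequences.values()) == {"AAAA", "CCCC"}

    def test_empty_input_gives_empty_table(self):
        t = dereplicate_asvs({"s1": []})
        assert t.counts.shape == (0, 1)

    def test_lossless_on_error_free_reads(self, small_community, designs):
        """Dereplicated feature set == theoretical amplicon set per design."""
        taxa = sorted(small_community)
        truth = generate_community(taxa, n_per_cohort=3, seed=31)
        for dname in ("V4", "STRAINID"):
            rs = generate_reads(truth, small_community, designs[dname],
                                depth=800, seed=32)
            table = dereplicate_asvs(rs.reads)
            theo = theoretical_asv_count(
                [g.to_record() for g in small_community.values()], designs[dname])
            expected = set().union(*(r.amplicon_sequences for r in theo))
            assert set(table.sequences.values()) == expected


class TestFeatureTable:
    def test_all_zero_features_dropped_and_negative_rejected(self):
        counts = pd.DataFrame({"s1": [3, 0], "s2": [1, 0]}, index=["f1", "f2"])
        t = FeatureTable(counts, {"f1": "AA", "f2": "CC"})
        assert t.feature_ids == ["f1"]
        with pytest.raises(ValueError):
            FeatureTable(counts - 2, {"f1": "AA", "f2": "CC"})

    def test_missing_sequence_rejected(self):
        counts = pd.DataFrame({"s1": [3]}, index=["f1"])
        with pytest.raises(ValueError, match="without sequences"):
            FeatureTable(counts, {})


REFS = [
    ReferenceRecord("r1", ("Bacteria", "P", "C", "O", "F", "GenusA", "sp1", "strainX"),
                    "AAAAAAAAAACCCCCCCCCC"),
    ReferenceRecord("r2", ("Bacteria", "P", "C", "O", "F", "GenusA", "sp2", "strainY"),
                    "AAAAAAAAAAGGGGGGGGGG"),
]


class TestClassifyLca:
    def test_exact_match_gives_full_strain_lineage(self):
        a = classify_lca("AAAAAAAAAACCCCCCCCCC", REFS)
        assert a.deepest_rank == "strain"
        assert a.lineage[-1] == "strainX"

    def test_equidistant_references_collapse_to_shared_genus(self):
        # 5 substitutions from each reference -> tie at distance 5
        q = "AAAAAAAAAACCCCCGGGGG"
        a = classify_lca(q, REFS, max_distance=6)
        assert a.deepest_rank == "genus"
        assert a.lineage[-1] == "GenusA"

    def test_no_reference_in_range_is_unclassified(self):
        a = classify_lca("TTTTTTTTTTTTTTTTTTTT", REFS)
        assert a.deepest_rank == "unclassified"
        assert a.lineage == ()

    def test_order_independent(self):
        q = "AAAAAAAAAACCCCCCCCCG"
        assert classify_lca(q, REFS) == classify_lca(q, REFS[::-1])

    def test_small_length_difference_uses_edit_distance(self):
        q = "AAAAAAAAAACCCCCCCCC"  # one deletion
        a = classify_lca(q, REFS, max_distance=2)
        assert a.deepest_rank == "strain"

    def test_malformed_lineage_rejected_at_load(self):
        with pytest.raises(ValueError, match="lineage"):
            ReferenceRecord("bad", ("Bacteria", "", "C"), "ACGT")


class TestClassificationRate:
    def _table(self):
        counts = pd.DataFrame({"s1": [80, 20], "s2": [50, 50]}, index=["f1", "f2"])
        return FeatureTable(counts, {"f1": "A" * 10, "f2": "C" * 10})

    def test_all_strain_classified_rates_one(self):
        t = self._table()
        assignments = {f: classify_lca(t.sequences[f],
                                       [ReferenceRecord("r", tuple("ABCDEFGH"),
                                                        t.sequences[f])])
                       for f in t.feature_ids}
        for rank in ("genus", "species", "strain"):
            assert (classification_rate(t, assignments, rank) == 1.0).all()

    def test_partial_rate_arithmetic(self):
        t = self._table()
        from longamp.profile import TaxonomyAssignment
        assignments = {
            "f1": TaxonomyAssignment("f1", ("Bacteria", "P", "C", "O", "F", "G"), "genus"),
            "f2": TaxonomyAssignment("f2", ("Bacteria",), "domain"),
        }
        rates = classification_rate(t, assignments, "genus")
        assert rates["s1"] == pytest.approx(0.8)
        assert rates["s2"] == pytest.approx(0.5)
        assert classification_rate(t, assignments, "species").sum() == 0


class TestRarefy:
    def _table(self, counts):
        ids = [f"f{i}" for i in range(len(counts))]
        df = pd.DataFrame({"s1": counts}, index=ids)
        return FeatureTable(df, {i: "ACGT" for i in ids})

    def test_exact_depth_unchanged(self):
        t = self._table([60, 40])
        out = rarefy(t, 100, seed=0)
        assert out.counts["s1"].tolist() == [60, 40]

    def test_shallow_sample_dropped(self):
        t = self._table([30, 40])
        out = rarefy(t, 100, seed=0)
        assert out.sample_ids == []

    def test_row_sums_equal_depth(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(0, 200, size=(20, 4)),
                              index=[f"f{i}" for i in range(20)],
                              columns=list("abcd"))
        t = FeatureTable(counts, {f"f{i}": "ACGT" for i in range(20)})
        out = rarefy(t, 100, seed=1)
        assert (out.sample_totals() == 100).all()

    def test_mean_matches_hypergeometric_expectation(self):
        t = self._table([900, 100])
        draws = np.array([rarefy(t, 100, seed=s).counts["s1"].iloc[1]
                          for s in range(3000)])
        # E = 10, Var = 100*.1*.9*(900/999)
        se = np.sqrt(100 * 0.1 * 0.9 * (900 / 999) / 3000)
        assert abs(draws.mean() - 10.0) < 3 * se

    def test_nonpositive_depth_is_error(self):
        with pytest.raises(ValueError):
            rarefy(self._table([10]), 0)


class TestAggregation:
    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_count_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n_feat = rng.integers(2, 12)
        counts = pd.DataFrame(rng.integers(0, 50, size=(n_feat, 3)),
                              index=[f"f{i}" for i in range(n_feat)],
                              columns=list("xyz"))
        counts.iloc[0] += 1  # keep at least one non-zero feature
        t = FeatureTable(counts, {f"f{i}": "ACGT" for i in range(n_feat)})
        from longamp.profile import TaxonomyAssignment
        genera = ["GenusA", "GenusB"]
        assignments = {
            f: TaxonomyAssignment(
                f, ("Bacteria", "P", "C", "O", "F", genera[i % 2]), "genus")
            if i % 3 else TaxonomyAssignment(f, (), "unclassified")
            for i, f in enumerate(t.feature_ids)
        }
        agg = aggregate_taxa(t, assignments, "genus")
        assert agg.counts.to_numpy().sum() == t.counts.to_numpy().sum()
        rel = relative_abundance(agg)
        assert np.allclose(rel.sum(axis=0), 1.0)

    def test_same_genus_features_sum(self):
        counts = pd.DataFrame({"s1": [3, 7]}, index=["f1", "f2"])
        t = FeatureTable(counts, {"f1": "AA", "f2": "CC"})
        from longamp.profile import TaxonomyAssignment
        lin = ("Bacteria", "P", "C", "O", "F", "GenusA")
        assignments = {f: TaxonomyAssignment(f, lin, "genus") for f in ("f1", "f2")}
        agg = aggregate_taxa(t, assignments, "genus")
        assert agg.counts.loc["GenusA", "s1"] == 10

    def test_relative_abundance_simple(self):
        counts = pd.DataFrame({"s1": [2, 2]}, index=["f1", "f2"])
        t = FeatureTable(counts, {"f1": "AA", "f2": "CC"})
        assert relative_abundance(t)["s1"].tolist() == [0.5, 0.5]


class TestResolutionGradient:
    def test_strain_rate_increases_with_amplicon_span(self, designs):
        """Strain pairs differing only in the ITS are resolved by the
        long-operon design but not by 16S-internal designs; pairs differing
        in V1-V3 are resolved by FULL16S but not V4."""
        from longamp import GenomeSpec, generate_genome
        specs = [
            # strains of species Aa differ only in ITS
            GenomeSpec(name="Aa_x_S1", n_operons=2, genome_size=40_000, seed=61),
            GenomeSpec(name="Aa_x_S2", n_operons=2, genome_size=40_000, seed=62),
            # strains of species Bb differ inside 16S V1-V3 (outside V4)
            GenomeSpec(name="Bb_y_S1", n_operons=2, genome_size=40_000, seed=63),
            GenomeSpec(name="Bb_y_S2", n_operons=2, genome_size=40_000, seed=64,
                       ssu_tag_mutations=5, ssu_tag_region=(50, 500)),
        ]
        lineages = {
            "Aa_x_S1": ("Bacteria", "P", "C", "O", "F", "Aa", "Aa_x", "Aa_x_S1"),
            "Aa_x_S2": ("Bacteria", "P", "C", "O", "F", "Aa", "Aa_x", "Aa_x_S2"),
            "Bb_y_S1": ("Bacteria", "P", "C", "O", "F", "Bb", "Bb_y", "Bb_y_S1"),
            "Bb_y_S2": ("Bacteria", "P", "C", "O", "F", "Bb", "Bb_y", "Bb_y_S2"),
        }
        genomes = {}
        for s in specs:
            s.lineage = lineages[s.name]
            genomes[s.name] = generate_genome(s)
        taxa = sorted(genomes)
        truth = generate_community(taxa, n_per_cohort=2, seed=65)
        rates = {}
        for dname in ("V4", "FULL16S", "STRAINID"):
            design = designs[dname]
            rs = generate_reads(truth, genomes, design, depth=600, seed=66)
            table = dereplicate_asvs(rs.reads)
            reference = reference_from_genomes(list(genomes.values()), design)
            assignments = classify_table(table, reference, max_distance=0)
            rates[dname] = classification_rate(table, assignments, "strain").median()
        assert rates["V4"] < rates["FULL16S"] < rates["STRAINID"]
        assert rates["STRAINID"] == 1.0
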