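"""Consensus merge, hard filters, percent genome altered, gene tallies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cohloop as cl
from cohloop.simulate import VARIANT_COLUMNS


def variant(pos=1000, callers=("MuTect", "Strelka2"), depth=100, alt=20,
            gvaf=0.0, csq="missense_variant", dbsnp=False, sample="s1",
            gene="GeneA"):
    return {"sample_id": sample, "chrom": "chr1", "pos": pos, "ref": "A",
            "alt": "T", "tumor_depth": depth, "tumor_alt": alt,
            "germline_vaf": gvaf, "consequence": csq, "dbsnp": dbsnp,
            "gene": gene, "callers": callers}


def caller_tables(variants):
    tables = {}
    for caller in ("MuTect", "Strelka2", "VarScan"):
        rows = [{k: v for k, v in rec.items() if k != "callers"}
                for rec in variants if caller in rec["callers"]]
        tables[caller] = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return tables


class TestConsensusMerge:
    def test_two_caller_variant_retained_with_caller_set(self):
        tables = caller_tables([variant(callers=("Strelka2", "VarScan"))])
        merged = cl.consensus_merge(tables)
        assert len(merged) == 1
        assert merged["callers"].iloc[0] == ("Strelka2", "VarScan")

    def test_single_caller_variant_dropped(self):
        tables = caller_tables([variant(callers=("MuTect",))])
        assert len(cl.consensus_merge(tables)) == 0

    def test_three_caller_variant_kept(self):
        tables = caller_tables([variant(callers=("MuTect", "Strelka2",
                                                 "VarScan"))])
        merged = cl.consensus_merge(tables)
        assert merged["n_callers"].iloc[0] == 3

    def test_field_values_follow_priority_order(self):
        v = variant(callers=("MuTect", "Strelka2"))
        tables = caller_tables([v])
        tables["MuTect"].loc[0, "tumor_depth"] = 50
        tables["Strelka2"].loc[0, "tumor_depth"] = 77
        merged = cl.consensus_merge(tables, priority=["Strelka2", "MuTect",
                                                      "VarScan"])
        assert merged["tumor_depth"].iloc[0] == 77

    def test_duplicate_key_within_caller_rejected(self):
        tables = caller_tables([variant(), variant()])
        with pytest.raises(ValueError, match="duplicate"):
            cl.consensus_merge(tables)

    def test_fewer_than_two_tables_rejected(self):
        with pytest.raises(ValueError):
            cl.consensus_merge({"MuTect": pd.DataFrame()})


class TestHardFilters:
    def run_single(self, **kw):
        tables = caller_tables([variant(**kw)])
        merged = cl.consensus_merge(tables)
        return cl.apply_hard_filters(merged)

    def test_clean_variant_retained(self):
        retained, report = self.run_single(depth=100, alt=20)
        assert len(retained) == 1 and report.n_retained == 1

    @pytest.mark.parametrize("kw,rule", [
        (dict(depth=25, alt=10), "depth"),
        (dict(depth=100, alt=4), "alt_reads"),
        (dict(depth=100, alt=8), "tumor_vaf"),          # VAF 8% < 10%
        (dict(depth=100, alt=20, gvaf=0.02), "germline_vaf"),
        (dict(depth=100, alt=20, dbsnp=True), "dbsnp"),
        (dict(depth=100, alt=20, csq="intron_variant"), "consequence"),
        (dict(depth=0, alt=0), "depth"),
    ])
    def test_each_rule_drops_and_is_attributed(self, kw, rule):
        retained, report = self.run_single(**kw)
        assert len(retained) == 0
        assert report.dropped[rule] == 1

    @pytest.mark.parametrize("kw", [
        dict(depth=30, alt=5, gvaf=0.01),   # every threshold exactly at bound
        dict(depth=50, alt=5),              # VAF exactly 10%
    ])
    def test_boundaries_are_inclusive_for_retention(self, kw):
        retained, _ = self.run_single(**kw)
        assert len(retained) == 1

    def test_report_partitions_input(self):
        tables, truth = cl.simulate_variant_tables(150, seed=3)
        merged = cl.consensus_merge(tables)
        retained, report = cl.apply_hard_filters(merged)
        assert report.n_retained + sum(report.dropped.values()) == report.n_input
        assert report.n_input == len(merged)

    def test_filters_reproduce_generator_truth_labels(self):
        tables, truth = cl.simulate_variant_tables(200, seed=5)
        retained = cl.ConsensusVariantFilter().transform(tables)
        kept = set(zip(retained["chrom"], retained["pos"]))
        predicted = np.where([(c, p) in kept for c, p in
                              zip(truth["chrom"], truth["pos"])],
                             "pass", "drop")
        assert (predicted == truth["truth"].to_numpy()).all()


class TestPGA:
    def segs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "log2_ratio"])

    def test_worked_examples(self):
        gain, loss = cl.percent_genome_altered(
            self.segs([("chr1", 0, 5_000_000, 0.3)]), 100_000_000)
        assert (gain, loss) == (5.0, 0.0)
        gain, loss = cl.percent_genome_altered(
            self.segs([("chr1", 0, 10_000_000, -0.2),
                       ("chr2", 0, 2_000_000, 0.15)]), 100_000_000)
        assert (gain, loss) == (2.0, 10.0)

    def test_subthreshold_segment_ignored(self):
        gain, loss = cl.percent_genome_altered(
            self.segs([("chr1", 0, 5_000_000, 0.05),
                       ("chr1", 5_000_000, 9_000_000, -0.1)]), 100_000_000)
        assert (gain, loss) == (0.0, 0.0)  # |log2|=0.1 is not > 0.1

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            cl.percent_genome_altered(
                self.segs([("chr1", 0, 5_000_000, 0.3),
                           ("chr1", 4_000_000, 6_000_000, 0.3)]), 100_000_000)

    @settings(max_examples=30, deadline=None)
    @given(cut=st.integers(min_value=1, max_value=4_999_999))
    def test_invariant_to_segment_splitting(self, cut):
        whole = self.segs([("chr1", 0, 5_000_000, 0.3)])
        split = self.segs([("chr1", 0, cut, 0.3),
                           ("chr1", cut, 5_000_000, 0.3)])
        assert cl.percent_genome_altered(whole, 10**8) == \
            cl.percent_genome_altered(split, 10**8)


class TestGeneTally:
    def test_frequency_counts_samples_once(self):
        variants = pd.DataFrame([
            {"sample_id": "s1", "gene": "g1"},
            {"sample_id": "s1", "gene": "g1"},   # second hit, same sample
            {"sample_id": "s2", "gene": "g1"},
            {"sample_id": "s3", "gene": "g2"},
        ])
        groups = {f"s{k}": "tumor" for k in range(1, 5)}
        tally = cl.gene_mutation_tally(variants, ["g1", "g2", "g3"], groups)
        t = tally.set_index(["gene", "group"])
        assert t.loc[("g1", "tumor"), "frequency"] == 0.5
        assert t.loc[("g2", "tumor"), "n_mutated"] == 1
        assert t.loc[("g3", "tumor"), "frequency"] == 0.0

    def test_empty_variants_all_zero(self):
        variants = pd.DataFrame(columns=["sample_id", "gene"])
        tally = cl.gene_mutation_tally(variants, ["g1"], {"s1": "a"})
        assert (tally["frequency"] == 0).all()

    def test_unknown_sample_group_rejected(self):
        variants = pd.DataFrame([{"sample_id": "sX", "gene": "g1"}])
        with pytest.raises(ValueError, match="unknown group"):
            cl.gene_mutation_tally(variants, ["g1"], {"s1": "a"})
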