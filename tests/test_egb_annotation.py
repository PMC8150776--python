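import numpy as np
import pytest
from scipy import stats

from mcseed.dmr_calling import DMR
from mcseed.egb_annotation import (
    GeneModel,
    REGION_DOWNSTREAM,
    REGION_GENE_BODY,
    REGION_UPSTREAM,
    STATUS_AMBIGUOUS,
    STATUS_DEMETHYLATED,
    STATUS_METHYLATED,
    assign_dmrs_to_regions,
    build_egb_regions,
    classify_gene_regions,
    disaggregate_egb,
    dmr_feature_counts,
    load_gene_models,
    metagene_profile,
    summarize_region_counts,
)

from conftest import make_dmp


def make_dmr(start, end, direction=STATUS_METHYLATED, chrom="chr1", context="CG"):
    return DMR(
        chrom=chrom,
        start=start,
        end=end,
        context=context,
        direction=direction,
        n_dmps=2,
        region_q=0.01,
    )


GFF_ONE_GENE = """##gff-version 3
chr1\tsrc\tgene\t5001\t7000\t.\t+\t.\tID=geneA
chr1\tsrc\tmRNA\t5001\t7000\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\tsrc\texon\t5001\t7000\t.\t+\t.\tID=geneA.t1.e1;Parent=geneA.t1
"""

GFF_MINUS = """##gff-version 3
chr1\tsrc\tgene\t5001\t7000\t.\t-\t.\tID=geneB
chr1\tsrc\tmRNA\t5001\t7000\t.\t-\t.\tID=geneB.t1;Parent=geneB
chr1\tsrc\texon\t5001\t7000\t.\t-\t.\tID=geneB.t1.e1;Parent=geneB.t1
"""

GFF_TWO_TRANSCRIPTS = """##gff-version 3
chr2\tsrc\tgene\t1001\t1800\t.\t+\t.\tID=geneC
chr2\tsrc\tmRNA\t1001\t1500\t.\t+\t.\tID=geneC.t1;Parent=geneC
chr2\tsrc\texon\t1001\t1500\t.\t+\t.\tID=geneC.t1.e1;Parent=geneC.t1
chr2\tsrc\tmRNA\t1001\t1800\t.\t+\t.\tID=geneC.t2;Parent=geneC
chr2\tsrc\texon\t1001\t1800\t.\t+\t.\tID=geneC.t2.e1;Parent=geneC.t2
"""


class TestLoadGeneModels:
    def test_minimal_plus_strand(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_ONE_GENE)
        [g] = load_gene_models(p)
        assert g.gene_id == "geneA"
        assert (g.chrom, g.strand, g.start, g.end) == ("chr1", "+", 5000, 7000)
        assert g.exons == ((5000, 7000),)

    def test_minus_strand_span_unchanged(self, tmp_path):
        p = tmp_path / "b.gff3"
        p.write_text(GFF_MINUS)
        [g] = load_gene_models(p)
        assert g.strand == "-"
        assert (g.start, g.end) == (5000, 7000)

    def test_longest_transcript_wins(self, tmp_path):
        p = tmp_path / "c.gff3"
        p.write_text(GFF_TWO_TRANSCRIPTS)
        [g] = load_gene_models(p)
        assert (g.start, g.end) == (1000, 1800)  # 800 bp transcript

    def test_strandless_gene_skipped(self, tmp_path):
        p = tmp_path / "d.gff3"
        p.write_text(
            "##gff-version 3\nchr1\tsrc\tgene\t100\t200\t.\t.\t.\tID=geneX\n"
        )
        with pytest.warns(UserWarning, match="geneX"):
            genes = load_gene_models(p)
        assert genes == []


def gene(start=5000, end=7000, strand="+", gene_id="g", chrom="chr1"):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, start=start, end=end
    )


class TestDisaggregateEGB:
    def test_plus_strand(self):
        up, body, down = disaggregate_egb(gene(), chrom_length=1_000_000)
        assert (up.start, up.end) == (3000, 5000)
        assert (body.start, body.end) == (5000, 7000)
        assert (down.start, down.end) == (7000, 9000)

    def test_minus_strand_mirrored(self):
        up, body, down = disaggregate_egb(gene(strand="-"), chrom_length=1_000_000)
        assert (up.start, up.end) == (7000, 9000)
        assert (down.start, down.end) == (3000, 5000)

    def test_clipped_at_chromosome_start(self):
        up, _, _ = disaggregate_egb(gene(start=500, end=1500))
        assert (up.start, up.end) == (0, 500)

    def test_partition_covers_flanked_span_once(self):
        for strand in "+-":
            regions = disaggregate_egb(gene(strand=strand), chrom_length=10**6)
            ivs = sorted((r.start, r.end) for r in regions)
            assert ivs[0][0] == 3000 and ivs[-1][1] == 9000
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 == s2  # no gaps, no overlaps


class TestAssignDmrs:
    def test_single_overlap(self):
        regions = build_egb_regions([gene()])
        overlaps = assign_dmrs_to_regions([make_dmr(5100, 5200)], regions)
        assert len(overlaps) == 1
        assert overlaps[0][1].region == REGION_GENE_BODY

    def test_boundary_spanning_dmr_hits_both(self):
        regions = build_egb_regions([gene()])
        overlaps = assign_dmrs_to_regions([make_dmr(4990, 5010)], regions)
        assert {o[1].region for o in overlaps} == {REGION_UPSTREAM, REGION_GENE_BODY}

    def test_touching_boundary_is_not_overlap(self):
        regions = build_egb_regions([gene()])
        overlaps = assign_dmrs_to_regions([make_dmr(4990, 5000)], regions)
        assert [o[1].region for o in overlaps] == [REGION_UPSTREAM]

    def test_brute_force_oracle(self, rng):
        genes = [
            gene(
                start=int(s),
                end=int(s) + int(rng.integers(500, 4000)),
                strand="+" if rng.random() < 0.5 else "-",
                gene_id=f"g{i}",
                chrom=f"chr{1 + i % 3}",
            )
            for i, s in enumerate(
                rng.choice(np.arange(3000, 200_000, 10_000), size=18, replace=False)
            )
        ]
        regions = build_egb_regions(genes)
        dmrs = [
            make_dmr(int(s), int(s) + int(rng.integers(50, 3000)),
                     chrom=f"chr{1 + int(rng.integers(0, 3))}")
            for s in rng.integers(0, 210_000, size=200)
        ]
        got = {
            (id(d), r.gene_id, r.region)
            for d, r in assign_dmrs_to_regions(dmrs, regions)
        }
        expected = {
            (id(d), r.gene_id, r.region)
            for d in dmrs
            for r in regions
            if r.chrom == d.chrom and d.start < r.end and r.start < d.end
        }
        assert got == expected


class TestClassify:
    def test_single_methylated_dmr(self):
        regions = build_egb_regions([gene()])
        overlaps = assign_dmrs_to_regions([make_dmr(3100, 3200)], regions)
        [call] = classify_gene_regions(overlaps)
        assert call.region == REGION_UPSTREAM
        assert call.status == STATUS_METHYLATED

    def test_mixed_directions_ambiguous(self):
        regions = build_egb_regions([gene()])
        dmrs = [
            make_dmr(5100, 5200, STATUS_METHYLATED),
            make_dmr(6100, 6200, STATUS_DEMETHYLATED),
        ]
        overlaps = assign_dmrs_to_regions(dmrs, regions)
        [call] = classify_gene_regions(overlaps)
        assert call.status == STATUS_AMBIGUOUS

    def test_planted_truth_statuses(self, rng):
        genes = [
            gene(start=10_000 + 20_000 * i, end=15_000 + 20_000 * i, gene_id=f"g{i}")
            for i in range(10)
        ]
        regions = build_egb_regions(genes)
        truth = {}
        dmrs = []
        for i, g in enumerate(genes):
            direction = STATUS_METHYLATED if i % 2 else STATUS_DEMETHYLATED
            dmrs.append(make_dmr(g.start + 100, g.start + 300, direction))
            truth[(g.gene_id, REGION_GENE_BODY)] = direction
        calls = classify_gene_regions(assign_dmrs_to_regions(dmrs, regions))
        assert {(c.gene_id, c.region): c.status for c in calls} == truth

    def test_every_supporting_dmr_overlaps(self):
        regions = build_egb_regions([gene()])
        dmrs = [make_dmr(3100, 3300), make_dmr(8000, 8100)]
        calls = classify_gene_regions(assign_dmrs_to_regions(dmrs, regions))
        region_index = {(r.gene_id, r.region): r for r in regions}
        for c in calls:
            reg = region_index[(c.gene_id, c.region)]
            for d in c.supporting_dmrs:
                assert d.overlaps(reg.start, reg.end)


class TestSummary:
    def test_empty_calls_all_zero(self):
        summary = summarize_region_counts([])
        assert summary.total_dmrs() == 0
        assert summary.to_frame()[["upstream_meth"]].sum().sum() == 0

    def test_counts_match_statuses(self):
        regions = build_egb_regions([gene(gene_id="a"), gene(start=50_000, end=52_000, gene_id="b")])
        dmrs = [
            make_dmr(5100, 5200, STATUS_METHYLATED),
            make_dmr(50_100, 50_200, STATUS_DEMETHYLATED),
        ]
        calls = classify_gene_regions(assign_dmrs_to_regions(dmrs, regions))
        summary = summarize_region_counts(calls, {"CG": dmrs})
        assert summary.region_count("CG", REGION_GENE_BODY, STATUS_METHYLATED) == 1
        assert summary.region_count("CG", REGION_GENE_BODY, STATUS_DEMETHYLATED) == 1
        assert summary.region_overlap_total(REGION_GENE_BODY) == 2
        assert summary.total_dmrs() == 2
        # non-ambiguous call count equals meth + demeth totals
        n_called = sum(
            1 for c in calls if c.status in (STATUS_METHYLATED, STATUS_DEMETHYLATED)
        )
        total = sum(
            summary.region_overlap_total(reg)
            for reg in (REGION_UPSTREAM, REGION_GENE_BODY, REGION_DOWNSTREAM)
        )
        assert total == n_called


class TestMetagene:
    def test_dmp_upstream_of_atg_bin(self):
        g = gene(start=10_000, end=20_000)
        profile = metagene_profile([make_dmp(9850)], [g])
        # offset -150 falls in bin [-200, -100): index 18
        assert profile.atg_counts[18] == 1
        assert profile.atg_counts.sum() == 1

    def test_strand_mirror_same_bin(self):
        g_plus = gene(start=10_000, end=20_000, strand="+")
        g_minus = gene(start=10_000, end=20_000, strand="-")
        p_plus = metagene_profile([make_dmp(9850)], [g_plus])
        # mirrored: 150 bp beyond the 3' genomic end = 5' of the - strand ATG
        p_minus = metagene_profile([make_dmp(20_149)], [g_minus])
        np.testing.assert_array_equal(p_plus.atg_counts, p_minus.atg_counts)
        np.testing.assert_array_equal(p_plus.stop_counts, p_minus.stop_counts)

    def test_uniform_dmps_flat_profile(self, rng):
        genes = [
            gene(start=s, end=s + 50_000, gene_id=f"g{i}")
            for i, s in enumerate(range(10_000, 1_000_000, 60_000))
        ]
        dmps = [make_dmp(int(p)) for p in np.sort(
            rng.integers(0, 1_000_000, size=4000)
        )]
        profile = metagene_profile(dmps, genes)
        for counts in (profile.atg_counts, profile.stop_counts):
            expected = counts.sum() / len(counts)
            chi2 = ((counts - expected) ** 2 / expected).sum()
            p = stats.chi2.sf(chi2, len(counts) - 1)
            assert p > 0.01

    def test_bin_count(self):
        profile = metagene_profile([], [gene()])
        assert profile.n_bins == 40
        assert len(profile.atg_counts) == 40


class TestFeatureCounts:
    def test_intergenic_only(self):
        df = dmr_feature_counts([make_dmr(100, 200)], [gene()])
        counts = dict(zip(df.feature, df.n_dmrs))
        assert counts == {"exon": 0, "intron": 0, "intergenic": 1}

    def test_exon_and_intron(self):
        g = GeneModel(
            gene_id="g",
            chrom="chr1",
            strand="+",
            start=1000,
            end=3000,
            exons=((1000, 1500), (2500, 3000)),
        )
        df = dmr_feature_counts([make_dmr(1400, 2600)], [g])
        counts = dict(zip(df.feature, df.n_dmrs))
        assert counts == {"exon": 1, "intron": 1, "intergenic": 0}
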