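"""The four raw selection metrics and their stratified assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gims.annotation import TranscriptModel, build_coding_sites
from gims.metrics import (
    ConservationTrack,
    FunctionalScoreTable,
    compute_unit_metrics,
    fraction_rare,
    match_variants,
    mean_conservation,
    mean_functional,
    snv_density,
)


def variants_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf"])


def sites_df(chrom, entries):
    """entries: (pos, ref_plus) pairs; minimal site table for one stratum."""
    return pd.DataFrame(
        {
            "chrom": [chrom] * len(entries),
            "genomic_pos": [p for p, _ in entries],
            "ref_plus": [r for _, r in entries],
        }
    )


class TestMeanConservation:
    def test_arithmetic_mean(self):
        track = ConservationTrack({("c", 1): 2.0, ("c", 2): 4.0})
        mean, cov = mean_conservation(sites_df("c", [(1, "A"), (2, "A")]), track)
        assert mean == 3.0 and cov == 1.0

    def test_unscored_positions_skipped_with_coverage(self):
        track = ConservationTrack({("c", 1): 5.0})
        mean, cov = mean_conservation(sites_df("c", [(1, "A"), (2, "A")]), track)
        assert mean == 5.0 and cov == 0.5

    def test_no_sites_is_missing(self):
        mean, cov = mean_conservation(sites_df("c", []), ConservationTrack())
        assert mean is None and cov is None

    def test_unlisted_position_is_missing_not_zero(self):
        track = ConservationTrack({("c", 1): -3.0})
        assert track.get("c", 99) is None
        mean, _ = mean_conservation(sites_df("c", [(1, "A"), (99, "A")]), track)
        assert mean == -3.0


class TestMeanFunctional:
    def test_single_position_mean(self):
        table = FunctionalScoreTable(
            {("c", 1, "A", "C"): 0.0, ("c", 1, "A", "G"): 0.5, ("c", 1, "A", "T"): 1.0}
        )
        assert mean_functional(sites_df("c", [(1, "A")]), table) == 0.5

    def test_pooled_over_substitutions_not_per_site(self):
        # {1.0} at one site and {0.0, 0.0} at another: pooled mean is 1/3,
        # a per-site mean of means would give 1/4
        table = FunctionalScoreTable(
            {
                ("c", 1, "A", "C"): 1.0,
                ("c", 2, "G", "A"): 0.0,
                ("c", 2, "G", "T"): 0.0,
            }
        )
        result = mean_functional(sites_df("c", [(1, "A"), (2, "G")]), table)
        assert result == pytest.approx(1 / 3)

    def test_no_scored_substitutions_is_missing(self):
        assert (
            mean_functional(sites_df("c", [(1, "A")]), FunctionalScoreTable())
            is None
        )

    def test_out_of_range_scores_clamped_on_load(self, caplog):
        table = FunctionalScoreTable({("c", 1, "A", "C"): 1.7})
        assert table.get("c", 1, "A", "C") == 1.0

    def test_ref_equal_alt_rejected(self):
        with pytest.raises(ValueError):
            FunctionalScoreTable({("c", 1, "A", "A"): 0.5})


class TestSnvDensity:
    def test_per_kilobase_ratio(self):
        sites = sites_df("c", [(i, "A") for i in range(1, 601)])
        vs = variants_df([("c", 1, "A", "C", 0.1), ("c", 2, "A", "G", 0.1),
                          ("c", 3, "A", "T", 0.1)])
        density, n = snv_density(sites, vs)
        assert density == 5.0 and n == 3

    def test_zero_variants_gives_zero_density(self):
        sites = sites_df("c", [(i, "A") for i in range(1, 501)])
        density, n = snv_density(sites, variants_df([]))
        assert density == 0.0 and n == 0

    def test_split_multiallelic_counts_twice(self):
        sites = sites_df("c", [(1, "A")])
        vs = variants_df([("c", 1, "A", "C", 0.1), ("c", 1, "A", "G", 0.2)])
        _, n = snv_density(sites, vs)
        assert n == 2

    def test_ref_mismatch_skipped_with_warning(self, caplog):
        sites = sites_df("c", [(1, "A")])
        vs = variants_df([("c", 1, "T", "C", 0.1)])
        with caplog.at_level("WARNING"):
            matched = match_variants(sites, vs)
        assert len(matched) == 0
        assert "REF disagrees" in caplog.text

    def test_off_site_variants_ignored(self):
        sites = sites_df("c", [(1, "A")])
        vs = variants_df([("c", 7, "A", "C", 0.1)])
        assert len(match_variants(sites, vs)) == 0


class TestFractionRare:
    def test_threshold_count(self):
        frac, n_common = fraction_rare([0.001, 0.004, 0.02])
        assert frac == pytest.approx(2 / 3) and n_common == 1

    def test_boundary_maf_is_rare(self):
        # "common" requires MAF strictly > 0.5%
        frac, _ = fraction_rare([0.005])
        assert frac == 1.0

    def test_all_common(self):
        frac, n_common = fraction_rare([0.2, 0.3])
        assert frac == 0.0 and n_common == 2

    def test_no_variants_is_missing(self):
        frac, _ = fraction_rare([])
        assert frac is None

    @given(
        mafs=st.lists(st.floats(0.0, 0.5), min_size=1, max_size=50),
        t1=st.floats(0.0, 0.5),
        t2=st.floats(0.0, 0.5),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_threshold(self, mafs, t1, t2):
        # frac_rare counts maf <= t, so it grows with t; the *common*
        # fraction 1 - frac is the one depleted by selection
        lo, hi = min(t1, t2), max(t1, t2)
        assert fraction_rare(mafs, lo)[0] <= fraction_rare(mafs, hi)[0]


class TestComputeUnitMetrics:
    def hand_fixture(self, toy_transcript, toy_sites):
        track = ConservationTrack(
            {("chrT", 1): 2.0, ("chrT", 2): 4.0, ("chrT", 8): 5.0}
        )
        table = FunctionalScoreTable(
            {
                ("chrT", 1, "A", "C"): 1.0,
                ("chrT", 2, "T", "A"): 0.0,
                ("chrT", 2, "T", "C"): 0.0,
                ("chrT", 8, "G", "A"): 0.5,
                ("chrT", 8, "G", "C"): 0.7,
                ("chrT", 8, "G", "T"): 0.9,
            }
        )
        vs = variants_df(
            [
                ("chrT", 3, "G", "A", 0.001),
                ("chrT", 3, "G", "T", 0.02),   # split record, second allele
                ("chrT", 8, "G", "A", 0.004),  # the CpG nd site
                ("chrT", 7, "C", "T", 0.3),    # 2-fold site: not in ndCDS
                ("chrT", 1, "C", "G", 0.1),    # wrong REF: skipped
            ]
        )
        return compute_unit_metrics(toy_transcript, toy_sites, track, table, vs)

    def test_hand_worked_values(self, toy_transcript, toy_sites):
        gm = self.hand_fixture(toy_transcript, toy_sites)
        assert gm.n_nd_sites == {"cpg": 1, "noncpg": 8}
        assert gm.mean_conservation["noncpg"] == 3.0
        assert gm.conservation_coverage["noncpg"] == pytest.approx(2 / 8)
        assert gm.mean_conservation["cpg"] == 5.0
        assert gm.mean_functional["noncpg"] == pytest.approx(1 / 3)
        assert gm.mean_functional["cpg"] == pytest.approx(0.7)
        assert gm.n_snvs == {"cpg": 1, "noncpg": 2}
        assert gm.snv_per_kb["noncpg"] == pytest.approx(250.0)
        assert gm.snv_per_kb["cpg"] == pytest.approx(1000.0)
        assert gm.frac_rare["noncpg"] == pytest.approx(0.5)
        assert gm.frac_rare["cpg"] == 1.0
        assert gm.n_common == {"cpg": 0, "noncpg": 1}

    def test_snv_counts_partition_over_strata(self, toy_transcript, toy_sites):
        gm = self.hand_fixture(toy_transcript, toy_sites)
        # 3 of the 5 records fall on ndCDS with a matching REF
        assert gm.n_snvs["cpg"] + gm.n_snvs["noncpg"] == 3

    def test_stratum_without_sites_is_missing(self):
        # AAA AAA: no CpG anywhere
        t = TranscriptModel("G", "T", "c", "+", ((0, 6),), 6)
        sites = build_coding_sites(t, {"c": "AAAAAA"})
        gm = compute_unit_metrics(
            t, sites, ConservationTrack({("c", 1): 1.0}),
            FunctionalScoreTable(), variants_df([]),
        )
        assert gm.n_nd_sites["cpg"] == 0
        assert gm.mean_conservation["cpg"] is None
        assert gm.mean_conservation["noncpg"] == 1.0

    def test_unit_without_nd_sites_excluded(self):
        # CTC GGA: every position has a synonymous alternative except none?
        # use a site table filtered to nothing instead
        t = TranscriptModel("G", "T", "c", "+", ((0, 6),), 6)
        sites = build_coding_sites(t, {"c": "CTCGGA"}).assign(
            is_nondegenerate=False
        )
        gm = compute_unit_metrics(
            t, sites, ConservationTrack(), FunctionalScoreTable(), variants_df([])
        )
        assert gm is None

    def test_metrics_invariant_under_unit_doubling(self, toy_transcript,
                                                   toy_genome, toy_sites):
        """Concatenating a transcript with itself (duplicating its scores
        and variants) leaves all four metrics unchanged."""
        gm1 = self.hand_fixture(toy_transcript, toy_sites)
        seq = toy_genome["chrT"]
        genome2 = {"chrT": seq + seq}
        t2 = TranscriptModel("G", "T2", "chrT", "+", ((0, 12), (12, 24)), 24)
        sites2 = build_coding_sites(t2, genome2)
        track2 = ConservationTrack(
            {("chrT", p + off): v
             for off in (0, 12)
             for p, v in [(1, 2.0), (2, 4.0), (8, 5.0)]}
        )
        table2 = FunctionalScoreTable(
            {("chrT", p + off, r, a): v
             for off in (0, 12)
             for (p, r, a), v in {
                 (1, "A", "C"): 1.0, (2, "T", "A"): 0.0, (2, "T", "C"): 0.0,
                 (8, "G", "A"): 0.5, (8, "G", "C"): 0.7, (8, "G", "T"): 0.9,
             }.items()}
        )
        vs2 = variants_df(
            [("chrT", p + off, r, a, m)
             for off in (0, 12)
             for p, r, a, m in [
                 (3, "G", "A", 0.001), (3, "G", "T", 0.02), (8, "G", "A", 0.004)
             ]]
        )
        gm2 = compute_unit_metrics(t2, sites2, track2, table2, vs2)
        for s in ("cpg", "noncpg"):
            assert gm2.n_nd_sites[s] == 2 * gm1.n_nd_sites[s]
            assert gm2.mean_conservation[s] == pytest.approx(
                gm1.mean_conservation[s]
            )
            assert gm2.mean_functional[s] == pytest.approx(
                gm1.mean_functional[s]
            )
            assert gm2.snv_per_kb[s] == pytest.approx(gm1.snv_per_kb[s])
            assert gm2.frac_rare[s] == pytest.approx(gm1.frac_rare[s])


class TestLoaders:
    def test_tracks_round_trip_through_tsv(self, tmp_path):
        cons = tmp_path / "cons.tsv"
        cons.write_text("chrom\tpos\tscore\nc\t5\t-1.25\nc\t6\t3.5\n")
        track = ConservationTrack.from_tsv(cons)
        assert track.get("c", 5) == -1.25 and track.get("c", 7) is None
        func = tmp_path / "func.tsv"
        func.write_text("chrom\tpos\tref\talt\tscore\nc\t5\tA\tG\t0.75\n")
        table = FunctionalScoreTable.from_tsv(func)
        assert table.get("c", 5, "A", "G") == 0.75

    def test_vcf_af_and_multiallelic_split(self, tmp_path):
        from gims.metrics import load_variants

        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
            '##INFO=<ID=AC,Number=A,Type=Integer,Description="AC">\n'
            '##INFO=<ID=AN,Number=1,Type=Integer,Description="AN">\n'
            "##contig=<ID=c,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "c\t10\t.\tA\tC,G\t.\t.\tAF=0.3,0.001\n"
            "c\t20\t.\tT\tG\t.\t.\tAC=3;AN=100\n"
            "c\t30\t.\tT\tTG\t.\t.\tAF=0.9\n"
        )
        df = load_variants(vcf)
        # multiallelic split into two rows; the indel row dropped
        assert len(df) == 3
        row_c = df[(df.pos == 10) & (df.alt == "C")].iloc[0]
        assert row_c.maf == pytest.approx(0.3)
        row_acan = df[df.pos == 20].iloc[0]
        assert row_acan.maf == pytest.approx(0.03)

    def test_maf_folds_high_allele_frequencies(self, tmp_path):
        from gims.metrics import load_variants

        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
            "##contig=<ID=c,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "c\t10\t.\tA\tC\t.\t.\tAF=0.99\n"
        )
        df = load_variants(vcf)
        assert df.iloc[0].maf == pytest.approx(0.01, rel=1e-5)
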