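"""Statistics table, filters, genome scan and genotype export."""

import math

import numpy as np
import pytest

import snvmart as sm
from snvmart.errors import QueryError
from snvmart.query import SITE_SUMMARY_COLUMNS

import _oracles as orc
from conftest import raw_groups_from_vcf

FOUR_GROUPS = ("AFR", "EUR", "EAS", "AME")
GROUP_POPS = {"AFR": "YRI", "EUR": "CEU", "EAS": "CHB", "AME": "MXL"}


@pytest.fixture(scope="module")
def fig_raw(fig_paths, fig_panel):
    return raw_groups_from_vcf(fig_paths["vcf"], fig_panel)


def region_spec(selection=FOUR_GROUPS, merge=False, filters=sm.Filters()):
    return sm.QuerySpec(
        mode="region", payload=("2", 1, 243_199_373),
        selection=selection, merge=merge, filters=filters,
    )


class TestRunQuery:
    def test_worked_example_row(self, fig_mart):
        """The lactase-persistence marker over four continental groups."""
        rows = sm.run_query(
            fig_mart,
            sm.QuerySpec(mode="rs_list", payload=["rs4988235"], selection=FOUR_GROUPS),
        )
        (r,) = rows
        assert r.genes == ("MCM6",)
        assert r.ancestral_allele == "G"
        assert r.minor_allele == "A" and r.maf == pytest.approx(0.285)
        assert r.f_st_class == "very_high"
        assert 0.25 <= r.f_st <= 1.0
        assert r.n_samples == 100 and r.call_rate == 1.0

    def test_every_statistic_matches_naive_full_rescan(self, fig_mart, fig_raw):
        """run_query equals literal re-evaluation from the raw VCF, site by site."""
        rows = sm.run_query(fig_mart, region_spec())
        assert len(rows) == 8
        for r in rows:
            groups = [fig_raw[r.variant_id][GROUP_POPS[g]] for g in FOUR_GROUPS]
            pool = orc.pooled(groups)
            ma, maf = orc.minor_allele(pool)
            assert (r.minor_allele, r.maf) == (ma, pytest.approx(maf, abs=1e-12))
            assert r.h_exp == pytest.approx(orc.h_exp(pool), abs=1e-12)
            ho = orc.h_obs(pool)
            assert r.h_obs == (None if ho is None else pytest.approx(ho, abs=1e-12))
            fi = orc.f_is(pool)
            assert r.f_is == (None if fi is None else pytest.approx(fi, abs=1e-12))
            fs = orc.f_st(groups)
            assert r.f_st == (None if fs is None else pytest.approx(fs, abs=1e-12))
            if fs is not None:
                assert r.i_n == pytest.approx(orc.informativeness(groups), abs=1e-12)
            assert r.call_rate == pytest.approx(orc.call_rate(pool), abs=1e-12)

    def test_single_unit_and_merged_selections_report_na(self, fig_mart):
        single = sm.run_query(fig_mart, region_spec(selection=("CEU",)))
        merged = sm.run_query(fig_mart, region_spec(merge=True))
        for rows in (single, merged):
            assert all(r.f_st is None and r.i_n is None for r in rows)
        # merged pool over everything still reports within-pool statistics
        assert any(r.maf > 0 for r in merged)

    def test_rs_mode_preserves_input_order(self, fig_mart):
        rows = sm.run_query(
            fig_mart,
            sm.QuerySpec(
                mode="rs_list",
                payload=["rs5551008", "rs5551001"],
                selection=("ALL",),
                merge=True,
            ),
        )
        assert [r.variant_id for r in rows] == ["rs5551008", "rs5551001"]

    def test_monomorphic_site_conventions(self, fig_mart):
        rows = sm.run_query(
            fig_mart,
            sm.QuerySpec(mode="rs_list", payload=["rs5551003"], selection=FOUR_GROUPS),
        )
        (r,) = rows
        assert r.minor_allele is None and r.maf == 0.0
        assert r.f_st is None and r.f_is is None and r.f_st_class is None


class TestFilters:
    def test_no_filters_is_identity(self, fig_mart):
        rows = sm.run_query(fig_mart, region_spec())
        assert sm.apply_filters(rows, sm.Filters()) == rows

    def test_bounds_match_naive_count(self, fig_mart, fig_raw):
        filters = sm.Filters(maf_min=0.05, fst_min=0.25)
        rows = sm.run_query(fig_mart, region_spec(filters=filters))
        expected = 0
        for vid, per_pop in fig_raw.items():
            groups = [per_pop[GROUP_POPS[g]] for g in FOUR_GROUPS]
            _, maf = orc.minor_allele(orc.pooled(groups))
            fs = orc.f_st(groups)
            if maf >= 0.05 and fs is not None and fs >= 0.25:
                expected += 1
        assert len(rows) == expected > 0

    def test_fst_bound_drops_undefined_rows(self, fig_mart):
        rows = sm.run_query(fig_mart, region_spec())
        kept = sm.apply_filters(rows, sm.Filters(fst_min=0.0))
        assert all(r.f_st is not None for r in kept)
        assert len(kept) == sum(1 for r in rows if r.f_st is not None)

    def test_filtering_is_idempotent_and_commutes(self, fig_mart):
        rows = sm.run_query(fig_mart, region_spec())
        maf_f, fst_f = sm.Filters(maf_min=0.1), sm.Filters(fst_min=0.05)
        once = sm.apply_filters(sm.apply_filters(rows, maf_f), fst_f)
        assert sm.apply_filters(once, maf_f) == once
        swapped = sm.apply_filters(sm.apply_filters(rows, fst_f), maf_f)
        assert once == swapped

    def test_impossible_maf_bound_is_empty_not_an_error(self, fig_mart):
        rows = sm.run_query(fig_mart, region_spec(filters=sm.Filters(maf_min=0.6)))
        assert rows == []

    def test_invalid_bounds_are_errors(self):
        with pytest.raises(QueryError):
            sm.Filters(maf_min=0.5, maf_max=0.1).validate()
        with pytest.raises(QueryError):
            sm.Filters(fst_min=-0.2).validate()


class TestGenomeScan:
    def test_windows_and_flags_match_direct_oracle(self, fig_mart, fig_raw):
        scan = sm.fst_genome_scan(fig_mart, FOUR_GROUPS)
        expected = {}
        for vid, per_pop in fig_raw.items():
            fs = orc.f_st([per_pop[GROUP_POPS[g]] for g in FOUR_GROUPS])
            if fs is not None:
                expected[vid] = fs
        got = dict(zip(scan.sites["variant_id"], scan.sites["f_st"]))
        assert got == pytest.approx(expected, abs=1e-12)
        flags, thr = orc.upper_tail_flags(scan.sites["f_st"].to_numpy(), 0.975)
        assert (scan.sites["flagged"].to_numpy() == flags).all()
        assert scan.quantile_threshold == pytest.approx(thr)
        # windows: recompute means per 1-Mb bin
        bins = {}
        positions = {
            r.annotation.variant_id: r.annotation.pos for r in fig_mart.iter_all()
        }
        for vid, fs in expected.items():
            start = (positions[vid] - 1) // 1_000_000 * 1_000_000 + 1
            bins.setdefault(start, []).append(fs)
        for _, row in scan.windows.iterrows():
            vals = bins[row["window_start"]]
            assert row["mean_f_st"] == pytest.approx(sum(vals) / len(vals), abs=1e-12)
            assert row["n_sites"] == len(vals)

    def test_engineered_fixed_difference_tops_the_list(self, fig_mart):
        scan = sm.fst_genome_scan(fig_mart, FOUR_GROUPS)
        assert scan.top_hits.iloc[0]["variant_id"] == "rs5551002"
        assert scan.top_hits.iloc[0]["f_st"] == pytest.approx(1.0)
        assert bool(
            scan.sites.loc[scan.sites["variant_id"] == "rs5551002", "flagged"].iloc[0]
        )

    def test_identical_populations_scan_is_flat(self, tmp_path):
        vcf = tmp_path / "flat.vcf"
        body = "\t".join(["0/1"] * 4)
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA1\tA2\tB1\tB2\n"
            f"1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t{body}\n"
            f"1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t{body}\n"
        )
        pfile = tmp_path / "p"
        pfile.write_text("A1 P1\nA2 P1\nB1 P2\nB2 P2\n")
        mart = sm.build_datamart(vcf, sm.read_panel(pfile), out_path=tmp_path / "f.mart")
        scan = sm.fst_genome_scan(mart, ["P1", "P2"])
        assert (scan.sites["f_st"] == 0.0).all()
        assert len(scan.top_hits) == 0
        mart.close()

    def test_sub_mb_windows_align_to_position_one(self, fig_mart):
        scan = sm.fst_genome_scan(fig_mart, FOUR_GROUPS, window_bp=100_000)
        assert ((scan.windows["window_start"] - 1) % 100_000 == 0).all()


class TestExportAndRendering:
    def test_structure_export_shape(self, fig_mart, fig_paths, fig_panel, tmp_path):
        rows = sm.run_query(
            fig_mart,
            sm.QuerySpec(mode="gene_list", payload=["MCM6"], selection=("EUR",)),
        )
        out = sm.export_genotypes(
            fig_paths["vcf"], rows, fig_panel, ("EUR",), tmp_path / "mcm6.str"
        )
        lines = [l.split("\t") for l in out.read_text().splitlines()]
        assert len(lines) == 2 * 25
        assert all(len(l) == 2 + len(rows) for l in lines)

    def test_export_without_rows_or_vcf_fails(self, fig_mart, fig_paths, fig_panel, tmp_path):
        with pytest.raises(QueryError, match="nothing to export"):
            sm.export_genotypes(fig_paths["vcf"], [], fig_panel, ("EUR",), tmp_path / "x")
        rows = sm.run_query(
            fig_mart, sm.QuerySpec(mode="rs_list", payload=["rs4988235"], selection=("EUR",))
        )
        with pytest.raises(QueryError, match="raw VCF"):
            sm.export_genotypes(tmp_path / "gone.vcf", rows, fig_panel, ("EUR",), tmp_path / "x")

    def test_tsv_has_fixed_header_and_na_rendering(self, fig_mart, tmp_path):
        rows = sm.run_query(fig_mart, region_spec(selection=("CEU",)))
        path = sm.write_summaries(rows, tmp_path / "out.tsv")
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == list(SITE_SUMMARY_COLUMNS)
        mono = [l for l in lines if l.startswith("rs5551003")][0].split("\t")
        cols = dict(zip(SITE_SUMMARY_COLUMNS, mono))
        assert cols["f_st"] == "NA" and cols["minor_allele"] == "NA"

    def test_repeated_queries_are_byte_identical(self, fig_mart, tmp_path):
        spec = region_spec()
        a = sm.write_summaries(sm.run_query(fig_mart, spec), tmp_path / "a.tsv")
        b = sm.write_summaries(sm.run_query(fig_mart, spec), tmp_path / "b.tsv")
        assert a.read_bytes() == b.read_bytes()
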