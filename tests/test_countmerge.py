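"""Row alignment, split-row merging, conservation, and match statistics."""

import numpy as np
import pandas as pd
import pytest

from orthospec.countmerge import (
    MatchStats,
    MergeAmbiguityError,
    align_rows,
    improvement_percent,
    match_statistics_report,
    merge_split_rows,
)
from orthospec.orthomap import OrthologMap, OrthologPair
from orthospec.synthdata import (
    SimConfig,
    generate_alignment_table,
    generate_count_tables,
    generate_protein_dbs,
)
from orthospec.orthomap import best_hits, combine_directions, hits_from_frame, split_directions


def _pair(m, s, fwd=True, rev=True, bits=100.0):
    return OrthologPair(
        maize=m,
        sorghum=s,
        supported_fwd=fwd,
        supported_rev=rev,
        bitscore_fwd=bits if fwd else float("nan"),
        bitscore_rev=bits if rev else float("nan"),
    )


def _table(rows, samples):
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    df.index.name = "accession"
    return df.astype(np.int64)


SAMPLES_M = ["Zm_WW1", "Zm_WD1"]
SAMPLES_S = ["Sb_WW1", "Sb_WD1"]


def _world(cfg):
    mdb, sdb, truth = generate_protein_dbs(cfg)
    table = generate_alignment_table(truth, cfg)
    fwd, rev = split_directions(hits_from_frame(table), set(mdb), set(sdb))
    omap = combine_directions(best_hits(rev), best_hits(fwd))
    counts_m, counts_s, design = generate_count_tables(truth, cfg)
    return truth, omap, counts_m, counts_s


class TestAlignRows:
    def test_empty_map_excludes_everything(self):
        cm = _table({"M1": [3, 4], "M2": [1, 0]}, SAMPLES_M)
        cs = _table({"S1": [2, 2]}, SAMPLES_S)
        matrix, stats = align_rows(cm, cs, OrthologMap(pairs=[]))
        assert len(matrix) == 0
        assert stats.n_no_ortholog == stats.n_total_entries == 3

    def test_fully_matched_fixture(self):
        cm = _table({"M1": [3, 4], "M2": [1, 0], "M3": [5, 9]}, SAMPLES_M)
        cs = _table({"S1": [2, 2], "S2": [0, 1], "S3": [7, 7]}, SAMPLES_S)
        omap = OrthologMap(
            pairs=[_pair("M1", "S1"), _pair("M2", "S2"), _pair("M3", "S3")]
        )
        matrix, stats = align_rows(cm, cs, omap)
        assert len(matrix) == 3
        assert stats.matched_before_merge == 3
        assert stats.n_both_species == 6
        assert stats.n_no_ortholog == 0

    def test_missing_partner_yields_flagged_one_sided_row(self):
        cm = _table({"M1": [3, 4]}, SAMPLES_M)
        cs = _table({}, SAMPLES_S)
        matrix, stats = align_rows(cm, cs, OrthologMap(pairs=[_pair("M1", "S1")]))
        (row,) = matrix.rows
        assert row.one_sided
        assert row.sorghum_counts.tolist() == [0, 0]
        assert stats.matched_before_merge == 0

    def test_shared_accession_namespace_rejected(self):
        cm = _table({"X1": [1, 1]}, SAMPLES_M)
        cs = _table({"X1": [1, 1]}, SAMPLES_S)
        with pytest.raises(ValueError, match="disjoint"):
            align_rows(cm, cs, OrthologMap(pairs=[]))

    def test_negative_counts_rejected(self):
        cm = _table({"M1": [1, 1]}, SAMPLES_M)
        cm.iloc[0, 0] = -1
        cs = _table({"S1": [1, 1]}, SAMPLES_S)
        with pytest.raises(ValueError, match="negative"):
            align_rows(cm, cs, OrthologMap(pairs=[_pair("M1", "S1")]))


class TestMergeSplitRows:
    def test_no_splits_is_identity(self):
        cm = _table({"M1": [3, 4], "M2": [1, 0]}, SAMPLES_M)
        cs = _table({"S1": [2, 2], "S2": [0, 1]}, SAMPLES_S)
        omap = OrthologMap(pairs=[_pair("M1", "S1"), _pair("M2", "S2")])
        matrix, _ = align_rows(cm, cs, omap)
        merged = merge_split_rows(matrix, omap)
        pd.testing.assert_frame_equal(matrix.to_frame(), merged.to_frame())

    def test_two_one_sided_rows_join_into_one(self):
        # maize counts sit under M1 (forward hit) while the sorghum row's own
        # best hit named the paralog M1b: two one-sided rows, one merge.
        cm = _table({"M1": [3, 4]}, SAMPLES_M)
        cs = _table({"S1": [2, 5]}, SAMPLES_S)
        omap = OrthologMap(
            pairs=[
                _pair("M1", "S1", fwd=True, rev=False),
                _pair("M1b", "S1", fwd=False, rev=True),
            ]
        )
        matrix, stats = align_rows(cm, cs, omap)
        assert len(matrix) == 2
        assert all(r.one_sided for r in matrix.rows)
        merged = merge_split_rows(matrix, omap)
        assert len(merged) == 1
        (row,) = merged.rows
        assert not row.one_sided
        assert row.maize_counts.tolist() == [3, 4]
        assert row.sorghum_counts.tolist() == [2, 5]
        assert merged.stats.matched_after_merge == 1
        assert merged.stats.n_cross_identified == 2

    @pytest.mark.parametrize("k", [0, 1, 5])
    def test_row_count_drops_by_planted_split_count(self, k):
        cfg = SimConfig(
            n_ortholog_pairs=8,
            n_paralog_split_pairs=k,
            n_orphans_per_species=0,
            seed=21 + k,
        )
        _, omap, counts_m, counts_s = _world(cfg)
        matrix, stats = align_rows(counts_m, counts_s, omap)
        merged = merge_split_rows(matrix, omap)
        assert len(matrix) - len(merged) == k
        assert (
            merged.stats.matched_after_merge - stats.matched_before_merge == k
        )

    @pytest.mark.parametrize("k", [0, 1, 5])
    def test_per_sample_totals_conserved(self, k):
        cfg = SimConfig(
            n_ortholog_pairs=8,
            n_paralog_split_pairs=k,
            n_orphans_per_species=0,
            seed=31 + k,
        )
        _, omap, counts_m, counts_s = _world(cfg)
        matrix, _ = align_rows(counts_m, counts_s, omap)
        merged = merge_split_rows(matrix, omap)
        before_m, before_s = matrix.totals()
        after_m, after_s = merged.totals()
        np.testing.assert_array_equal(before_m, after_m)
        np.testing.assert_array_equal(before_s, after_s)
        # and the matrix conserves the matched subset of the input tables
        np.testing.assert_array_equal(
            after_m, counts_m.to_numpy().sum(axis=0)
        )

    def test_idempotent(self, small_world, small_matrix):
        again = merge_split_rows(small_matrix, small_world["omap"])
        pd.testing.assert_frame_equal(small_matrix.to_frame(), again.to_frame())

    def test_many_to_many_merge_rejected(self):
        # two rows that each carry both species' counts linked by a map pair
        cm = _table({"M1": [3, 4], "M2": [1, 1]}, SAMPLES_M)
        cs = _table({"S1": [2, 5], "S2": [2, 2]}, SAMPLES_S)
        omap = OrthologMap(
            pairs=[
                _pair("M1", "S1"),
                _pair("M2", "S2"),
                _pair("M1", "S2", fwd=False, rev=False),
            ]
        )
        matrix, _ = align_rows(cm, cs, omap)
        assert all(not r.one_sided for r in matrix.rows)
        with pytest.raises(MergeAmbiguityError, match="M1"):
            merge_split_rows(matrix, omap)

    def test_split_rows_sum_to_latent_pair_counts(self):
        cfg = SimConfig(
            n_ortholog_pairs=4,
            n_paralog_split_pairs=2,
            n_orphans_per_species=0,
            seed=17,
        )
        truth, omap, counts_m, counts_s = _world(cfg)
        matrix, _ = align_rows(counts_m, counts_s, omap)
        merged = merge_split_rows(matrix, omap)
        for (m_acc, s_acc), split in zip(truth.ortholog_pairs, truth.split_flags):
            if not split:
                continue
            (row,) = [r for r in merged.rows if m_acc in r.maize_accessions]
            np.testing.assert_array_equal(
                row.maize_counts, counts_m.loc[m_acc].to_numpy()
            )
            np.testing.assert_array_equal(
                row.sorghum_counts, counts_s.loc[s_acc].to_numpy()
            )


class TestStatisticsArithmetic:
    @pytest.mark.parametrize(
        "before, after, expected",
        [(416, 951, 129), (100, 150, 50), (7, 7, 0), (3, 4, 33)],
    )
    def test_improvement_percent(self, before, after, expected):
        assert improvement_percent(before, after) == expected

    def test_improvement_percent_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            improvement_percent(0, 10)
        with pytest.raises(ValueError):
            improvement_percent(10, 5)

    @pytest.mark.parametrize(
        "count, expected", [(718, 23), (945, 30), (416, 13), (1070, 34), (0, 0)]
    )
    def test_report_percentages_of_entries(self, count, expected):
        stats = MatchStats(n_total_entries=3154)
        assert stats.percent(count) == expected

    def test_report_table_recomputes_percentages(self):
        stats = MatchStats(
            n_total_entries=3154,
            n_no_ortholog=718,
            n_named_in_map=945,
            n_both_species=416,
            n_cross_identified=1070,
            matched_before_merge=416,
            matched_after_merge=951,
        )
        report = match_statistics_report(stats)
        by_cat = report.set_index("category")
        assert by_cat.loc["no ortholog named", "percent"] == 23
        assert by_cat.loc["named in map, unmatched", "percent"] == 30
        assert by_cat.loc["matched in both species at alignment", "percent"] == 13
        assert by_cat.loc["cross-identified via row merge", "percent"] == 34
        assert by_cat.loc["merge improvement (%)", "count"] == 129
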