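import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirlink import ContingencyTable, fisher_two_tailed, load_target_map
from mirlink.integration import TargetMap, pair_summary, reciprocal_pairs, screen_mirnas

from oracles import fisher_two_tailed_enum


def de_frame(calls: dict[str, str], stage="3w") -> pd.DataFrame:
    """Minimal DE table: feature -> call, with filler statistics."""
    return pd.DataFrame(
        {
            "feature_id": list(calls),
            "stage": stage,
            "log2_fc": [2.0 if c == "up" else -2.0 if c == "down" else 0.0
                        for c in calls.values()],
            "p_value": [0.001 if c != "ns" else 0.8 for c in calls.values()],
            "call": list(calls.values()),
        }
    )


class TestTargetMap:
    def test_load_dedup_and_query(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("mirna_id\tgene_id\nm1\tg1\nm1\tg2\nm2\tg2\nm1\tg1\n")
        tmap = load_target_map(p)
        assert len(tmap) == 3
        assert tmap.targets("m1") == {"g1", "g2"}
        assert tmap.mirnas("g2") == {"m1", "m2"}
        assert ("m1", "g1") in tmap and ("m2", "g1") not in tmap

    def test_headerless_file(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("m1\tg1\nm2\tg2\nm3\tg3\n")
        assert len(load_target_map(p)) == 3

    def test_empty_file_warns(self, tmp_path, caplog):
        p = tmp_path / "map.tsv"
        p.write_text("")
        with caplog.at_level("WARNING", logger="mirlink"):
            tmap = load_target_map(p)
        assert len(tmap) == 0
        assert any("no edges" in r.message for r in caplog.records)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("mirna_id\tgene_id\nm1\tg1\njustonefield\n")
        with pytest.raises(Exception, match=":3"):
            load_target_map(p)


class TestFisherTwoTailed:
    def test_degenerate_margin(self):
        odds, p = fisher_two_tailed(ContingencyTable(0, 5, 0, 5))
        assert p == 1.0
        assert np.isnan(odds)

    def test_enumeration_worked_example(self):
        """Margins (4,4)x(4,4) on N=8: two-tailed p of table (3,1,1,3) is
        34/70 by explicit enumeration of the five possible tables."""
        odds, p = fisher_two_tailed(ContingencyTable(3, 1, 1, 3))
        assert p == pytest.approx(34 / 70)
        assert odds == 9.0

    def test_transpose_symmetry(self):
        _, p1 = fisher_two_tailed(ContingencyTable(3, 1, 2, 8))
        _, p2 = fisher_two_tailed(ContingencyTable(3, 2, 1, 8))
        assert p1 == pytest.approx(p2)

    def test_infinite_and_zero_odds(self):
        odds, _ = fisher_two_tailed(ContingencyTable(4, 0, 1, 5))
        assert odds == np.inf
        odds, _ = fisher_two_tailed(ContingencyTable(0, 4, 5, 1))
        assert odds == 0.0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        _, p = fisher_two_tailed(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(fisher_two_tailed_enum(a, b, c, d), rel=1e-8, abs=1e-12)


class TestScreenMirnas:
    def test_no_de_mirnas_gives_empty_result(self):
        mirna_de = de_frame({"m1": "ns"})
        mrna_de = de_frame({f"g{i}": "ns" for i in range(10)})
        out = screen_mirnas(mirna_de, mrna_de, TargetMap([("m1", "g1")]))
        assert len(out) == 0

    def test_targets_equal_down_list_is_significant(self):
        """A miRNA whose targets are exactly the down-regulated list in a
        much larger universe screens at the enumeration-oracle minimum."""
        genes = {f"g{i}": "ns" for i in range(60)}
        for g in ("g0", "g1", "g2", "g3", "g4"):
            genes[g] = "down"
        mrna_de = de_frame(genes)
        mirna_de = de_frame({"m1": "up"})
        tmap = TargetMap([("m1", g) for g in ("g0", "g1", "g2", "g3", "g4")])
        out = screen_mirnas(mirna_de, mrna_de, tmap)
        row = out[out["mrna_list_direction"] == "down"].iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (5, 0, 0, 55)
        assert row["p_two_tailed"] == pytest.approx(
            fisher_two_tailed_enum(5, 0, 0, 55), rel=1e-8
        )
        assert row["significant"]
        up_row = out[out["mrna_list_direction"] == "up"].iloc[0]
        assert not up_row["significant"]

    def test_zero_target_mirna_marked_not_raised(self):
        mirna_de = de_frame({"m1": "up"})
        mrna_de = de_frame({"g1": "down", "g2": "ns"})
        out = screen_mirnas(mirna_de, mrna_de, TargetMap([("m1", "outside_gene")]))
        assert len(out) == 2
        assert out["zero_targets"].all()
        assert (out["p_two_tailed"] == 1.0).all()

    def test_mixed_stage_input_rejected(self):
        mirna_de = de_frame({"m1": "up"}, stage="3w")
        mrna_de = de_frame({"g1": "down"}, stage="12w")
        with pytest.raises(Exception, match="stage"):
            screen_mirnas(mirna_de, mrna_de, TargetMap([("m1", "g1")]))

    def test_universe_is_tested_mrna_features(self):
        mirna_de = de_frame({"m1": "up"})
        mrna_de = de_frame({"g1": "down", "g2": "ns", "g3": "ns"})
        out = screen_mirnas(mirna_de, mrna_de, TargetMap([("m1", "g1"), ("m1", "gX")]))
        row = out[out["mrna_list_direction"] == "down"].iloc[0]
        # gX is outside the universe: only g1 counts as a target
        assert row[["a", "b", "c", "d"]].sum() == 3

    def test_repressing_mirnas_rank_first_across_seeds(self):
        """Across 100 seeded draws, a miRNA whose targets concentrate in the
        down-regulated list out-ranks (smaller p) a miRNA with random
        targets in at least 95 of them."""
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            genes = [f"g{i}" for i in range(200)]
            down = set(rng.choice(genes, size=30, replace=False))
            calls = {g: ("down" if g in down else "ns") for g in genes}
            repressor_targets = list(rng.choice(sorted(down), size=12, replace=False)) + list(
                rng.choice(sorted(set(genes) - down), size=8, replace=False)
            )
            random_targets = rng.choice(genes, size=20, replace=False)
            tmap = TargetMap(
                [("mR", g) for g in repressor_targets] + [("mN", g) for g in random_targets]
            )
            out = screen_mirnas(
                de_frame({"mR": "up", "mN": "up"}), de_frame(calls), tmap
            )
            down_rows = out[out["mrna_list_direction"] == "down"].set_index("mirna_id")
            if down_rows.loc["mR", "p_two_tailed"] < down_rows.loc["mN", "p_two_tailed"]:
                wins += 1
        assert wins >= 0.95 * n_seeds


class TestReciprocalPairs:
    def test_definition_and_exclusions(self):
        tmap = TargetMap([("mX", "G"), ("mX", "H"), ("mY", "G")])
        mirna_de = de_frame({"mX": "up", "mY": "up"})
        mrna_de = de_frame({"G": "down", "H": "up"})
        pairs = reciprocal_pairs(mirna_de, mrna_de, tmap)
        assert len(pairs) == 2  # (mX,G) and (mY,G); (mX,H) same-direction excluded
        assert set(zip(pairs["mirna_id"], pairs["gene_id"])) == {("mX", "G"), ("mY", "G")}
        assert (pairs["mirna_call"] != pairs["gene_call"]).all()

    def test_no_de_features_empty(self):
        pairs = reciprocal_pairs(
            de_frame({"m1": "ns"}), de_frame({"g1": "ns"}), TargetMap([("m1", "g1")])
        )
        assert len(pairs) == 0

    def test_pairs_require_prediction_edge(self):
        pairs = reciprocal_pairs(
            de_frame({"m1": "up"}), de_frame({"g1": "down"}), TargetMap([("m2", "g1")])
        )
        assert len(pairs) == 0

    def test_referential_integrity_on_fixture(self, small_design, small_effects):
        """Every extracted pair is reachable from its stage's DE calls and
        the prediction map."""
        from mirlink.synthetic import generate_expression, generate_truth
        from mirlink.preprocess import preprocess_pipeline
        from mirlink.diffexpr import run_de

        truth = generate_truth(small_design, small_effects)
        mrna, mirna = generate_expression(truth, small_design, small_effects)
        feat_mrna, _ = preprocess_pipeline(mrna)
        feat_mirna, _ = preprocess_pipeline(mirna)
        tmap = TargetMap(truth.predicted_edges)
        for stage in small_design.stages:
            de_mrna = run_de(feat_mrna, stage)
            de_mirna = run_de(feat_mirna, stage)
            pairs = reciprocal_pairs(de_mirna, de_mrna, tmap, stage)
            mrna_calls = dict(zip(de_mrna["feature_id"], de_mrna["call"]))
            mirna_calls = dict(zip(de_mirna["feature_id"], de_mirna["call"]))
            for row in pairs.itertuples():
                assert (row.mirna_id, row.gene_id) in tmap
                assert mirna_calls[row.mirna_id] == row.mirna_call
                assert mrna_calls[row.gene_id] == row.gene_call
                assert row.mirna_call != row.gene_call


class TestPairSummary:
    def test_empty(self):
        empty = reciprocal_pairs(
            de_frame({"m1": "ns"}), de_frame({"g1": "ns"}), TargetMap([("m1", "g1")])
        )
        assert len(pair_summary(empty)) == 0

    def test_distinct_counts_by_hand(self):
        pairs = pd.DataFrame(
            [
                {"mirna_id": "m1", "gene_id": "g1", "stage": "3w",
                 "mirna_call": "up", "gene_call": "down"},
                {"mirna_id": "m1", "gene_id": "g2", "stage": "3w",
                 "mirna_call": "up", "gene_call": "down"},
                {"mirna_id": "m2", "gene_id": "g2", "stage": "3w",
                 "mirna_call": "up", "gene_call": "down"},
            ]
        )
        row = pair_summary(pairs).iloc[0]
        assert row["n_up_mirnas"] == 2
        assert row["n_down_target_genes"] == 2
        assert row["n_down_mirnas"] == 0
        assert row["n_up_target_genes"] == 0
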