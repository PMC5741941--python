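"""GMT round trips, competitive enrichment and over-representation analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import qsig.genesets as gs
from qsig.diffexpr import group_residuals, moderated_t_test
from qsig.genesets import (
    camera_test,
    enrichment_matrix,
    fisher_ora,
    read_gmt,
    variance_inflation,
    write_gmt,
)
from qsig.types import GeneSetCollection, ValidationError

from conftest import make_dataset


class TestGmtRoundTrip:
    def test_write_then_read_preserves_collection(self, tmp_path):
        collection = GeneSetCollection(
            name="demo",
            sets={"s1": {"a", "b"}, "s2": {"b", "c", "d"}, "s3": {"e"}},
            universe={"a", "b", "c", "d", "e", "f"},
        )
        path = tmp_path / "demo.gmt"
        write_gmt(collection, path)
        back = read_gmt(path, universe=collection.universe)
        assert back.sets == collection.sets
        assert back.universe == collection.universe

    def test_malformed_line_errors_with_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("ok\tdesc\tg1\tg2\nbroken\tonly-two-fields\n")
        with pytest.raises(ValidationError, match=":2"):
            read_gmt(path)

    def test_duplicate_genes_counted_once(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("s\tdesc\tg1\tg1\tg2\n")
        collection = read_gmt(path)
        assert collection.sets["s"] == {"g1", "g2"}


class TestCameraTest:
    def test_vif_arithmetic(self):
        assert variance_inflation(11, 0.1) == pytest.approx(2.0)
        assert variance_inflation(1, 0.9) == 1.0  # (m-1)=0
        assert variance_inflation(10, -0.5) == 1.0  # floored

    @pytest.fixture()
    def de_and_residuals(self):
        dataset = make_dataset(n_genes=100, n_qsc=4, n_asc=4, seed=21)
        de = moderated_t_test(dataset)
        return dataset, de, group_residuals(dataset)

    def test_singleton_set_has_unit_vif(self, de_and_residuals):
        _, de, res = de_and_residuals
        collection = GeneSetCollection(
            "c", {"solo": {de.index[0]}}, universe=set(de.index)
        )
        table = camera_test(de, res, collection, min_set_size=1)
        assert table.loc["solo", "vif"] == 1.0
        assert table.loc["solo", "rho_bar"] == 0.0

    def test_no_residuals_matches_vif_disabled(self, de_and_residuals):
        _, de, res = de_and_residuals
        collection = GeneSetCollection(
            "c", {"s": set(de.index[:20])}, universe=set(de.index)
        )
        without = camera_test(de, None, collection)
        forced = camera_test(de, res, collection, use_vif=False)
        assert without.loc["s", "p"] == pytest.approx(forced.loc["s", "p"], abs=1e-12)
        assert without.loc["s", "z_set"] == pytest.approx(forced.loc["s", "z_set"], abs=1e-12)

    def test_statistic_invariant_to_score_shift(self, de_and_residuals, monkeypatch):
        _, de, res = de_and_residuals
        collection = GeneSetCollection(
            "c", {"s": set(de.index[:15])}, universe=set(de.index)
        )
        base = camera_test(de, res, collection)
        original = gs._gene_scores
        monkeypatch.setattr(gs, "_gene_scores", lambda t, d: original(t, d) + 5.0)
        shifted = camera_test(de, res, collection)
        assert shifted.loc["s", "z_set"] == pytest.approx(base.loc["s", "z_set"], abs=1e-10)
        assert shifted.loc["s", "p"] == pytest.approx(base.loc["s", "p"], abs=1e-10)

    def test_label_swap_flips_direction_and_preserves_p(self):
        dataset = make_dataset(
            n_genes=100, n_qsc=4, n_asc=4, seed=22,
            effect_genes={f"G{i:04d}": 1.5 for i in range(10)},
        )
        flipped_conditions = {
            s: ("ASC" if c == "QSC" else "QSC") for s, c in dataset.conditions.items()
        }
        from qsig.types import ExpressionDataset

        flipped = ExpressionDataset("F", dataset.matrix, flipped_conditions)
        collection = GeneSetCollection(
            "c", {"sig": {f"G{i:04d}" for i in range(10)}},
            universe={f"G{i:04d}" for i in range(100)},
        )
        prior = moderated_t_test(dataset).attrs["prior"]
        a = camera_test(moderated_t_test(dataset, prior=prior),
                        group_residuals(dataset), collection)
        b = camera_test(moderated_t_test(flipped, prior=prior),
                        group_residuals(flipped), collection)
        assert a.loc["sig", "direction"] == "Up"
        assert b.loc["sig", "direction"] == "Down"
        assert a.loc["sig", "p"] == pytest.approx(b.loc["sig", "p"], rel=1e-9)

    def test_planted_signal_set_is_top_ranked(self):
        dataset = make_dataset(
            n_genes=200, n_qsc=4, n_asc=4, seed=23,
            effect_genes={f"G{i:04d}": 2.0 for i in range(15)},
        )
        sets = {"signal": {f"G{i:04d}" for i in range(15)}}
        rng = np.random.default_rng(5)
        for j in range(10):
            sets[f"null{j}"] = set(
                f"G{i:04d}" for i in rng.choice(np.arange(15, 200), size=15, replace=False)
            )
        collection = GeneSetCollection("c", sets, universe=set(dataset.matrix.index))
        de = moderated_t_test(dataset)
        table = camera_test(de, group_residuals(dataset), collection)
        assert table["p"].idxmin() == "signal"
        assert table.loc["signal", "direction"] == "Up"


class TestFisherOra:
    def test_hypergeometric_hand_example(self):
        universe = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(5)}  # K=5
        members = {"g0", "g1", "g2", "g10"}  # n=4, overlap k=3
        collection = GeneSetCollection("c", {"s": members}, universe=universe)
        table = fisher_ora(query, collection)
        assert table.loc["s", "k"] == 3
        assert table.loc["s", "p"] == pytest.approx(155 / 4845, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        collection = GeneSetCollection("c", {"s": {"g8", "g9"}}, universe=universe)
        table = fisher_ora({"g0", "g1"}, collection)
        assert table.loc["s", "p"] == 1.0

    def test_degenerate_full_table_gives_p_one(self):
        universe = {"a", "b", "c"}
        collection = GeneSetCollection("c", {"s": set(universe)}, universe=universe)
        table = fisher_ora(set(universe), collection)
        assert table.loc["s", "p"] == 1.0

    def test_query_outside_universe_dropped_and_empty_query_rejected(self):
        universe = {"a", "b"}
        collection = GeneSetCollection("c", {"s": {"a"}}, universe=universe)
        table = fisher_ora({"a", "zzz"}, collection)
        assert table.loc["s", "K"] == 1
        with pytest.raises(ValidationError):
            fisher_ora({"zzz"}, collection)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(30)
        n_draws = 20_000
        for _ in range(5):
            N = int(rng.integers(30, 80))
            n = int(rng.integers(5, N // 2))
            K = int(rng.integers(5, N // 2))
            universe = [f"g{i}" for i in range(N)]
            members = set(universe[:n])
            query = set(rng.choice(universe, size=K, replace=False))
            collection = GeneSetCollection("c", {"s": members}, universe=set(universe))
            k = len(query & members)
            p = fisher_ora(query, collection).loc["s", "p"]
            draws = np.array([
                len(set(rng.choice(universe, size=K, replace=False)) & members)
                for _ in range(n_draws)
            ])
            p_mc = (draws >= k).mean()
            se = max(np.sqrt(p_mc * (1 - p_mc) / n_draws), 1.0 / n_draws)
            assert abs(p - p_mc) <= 3 * se + 1e-9


class TestEnrichmentMatrix:
    def _table(self, rows):
        t = pd.DataFrame(rows, columns=["set", "direction", "adj_p"]).set_index("set")
        t.attrs["collection"] = "c"
        return t

    def test_direction_codes_and_counts(self):
        results = {
            f"DS{i}": self._table([("a", "Up", 0.01), ("b", "Down", 0.2)])
            for i in range(9)
        }
        results["DS9"] = self._table([("a", "Down", 0.01), ("b", "Down", 0.01)])
        matrix = enrichment_matrix(results, fdr_max=0.05)
        assert matrix.loc["a"].sum() == 9 - 1
        assert int((matrix.loc["a"] != 0).sum()) == 10
        assert matrix.loc["b"].tolist() == [0] * 9 + [-1]

    def test_nothing_significant_gives_zero_matrix(self):
        results = {"DS1": self._table([("a", "Up", 0.9)]),
                   "DS2": self._table([("a", "Down", 0.8)])}
        matrix = enrichment_matrix(results, fdr_max=0.05)
        assert (matrix == 0).all().all()

    def test_single_dataset_column_matches_significant_sets(self):
        results = {"DS1": self._table([("a", "Up", 0.01), ("b", "Down", 0.04),
                                       ("c", "Up", 0.5)])}
        matrix = enrichment_matrix(results, fdr_max=0.05)
        assert matrix["DS1"].to_dict() == {"a": 1, "b": -1, "c": 0}

    def test_mixed_collections_rejected(self):
        t1 = self._table([("a", "Up", 0.01)])
        t2 = self._table([("a", "Up", 0.01)])
        t2.attrs["collection"] = "other"
        with pytest.raises(ValidationError):
            enrichment_matrix({"DS1": t1, "DS2": t2})
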