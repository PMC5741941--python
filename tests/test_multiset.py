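"""Jaccard similarity, intersection landscape, ranking and consensus."""

import itertools

import numpy as np
import pytest
from scipy import stats

from qsig.multiset import (
    consensus_signature,
    exact_intersection_test,
    flag_suspect_genes,
    intersection_landscape,
    jaccard,
    jaccard_matrix,
    landscape_table,
    rank_datasets,
)
from qsig.types import DegSets, ValidationError


def make_degs(up: dict, down: dict | None = None, N: int = 1000) -> DegSets:
    down = down or {ds: set() for ds in up}
    return DegSets(up={k: set(v) for k, v in up.items()},
                   down={k: set(v) for k, v in down.items()},
                   background={ds: N for ds in up})


class TestJaccard:
    def test_half_overlap(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_identical_and_disjoint(self):
        assert jaccard({"a"}, {"a"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_both_empty_is_zero_by_convention(self):
        assert jaccard(set(), set()) == 0.0


class TestJaccardMatrix:
    def test_identical_sets_give_all_ones_and_zero_heights(self):
        degs = make_degs({ds: {"g1", "g2"} for ds in ("A", "B", "C")})
        jm = jaccard_matrix(degs, "up")
        assert (jm.matrix.to_numpy() == 1.0).all()
        assert np.allclose(jm.linkage[:, 2], 0.0)

    def test_disjoint_sets_give_identity_matrix(self):
        degs = make_degs({"A": {"a"}, "B": {"b"}, "C": {"c"}})
        jm = jaccard_matrix(degs, "up")
        assert np.array_equal(jm.matrix.to_numpy(), np.eye(3))

    def test_near_identical_pair_merges_first(self):
        degs = make_degs({
            "A": {f"g{i}" for i in range(10)},
            "B": {f"g{i}" for i in range(9)} | {"x"},
            "C": {"y1", "y2", "y3"},
        })
        jm = jaccard_matrix(degs, "up")
        # first merge row joins leaves 0 (A) and 1 (B)
        assert sorted(jm.linkage[0, :2].astype(int).tolist()) == [0, 1]

    def test_single_dataset_rejected(self):
        with pytest.raises(ValidationError):
            jaccard_matrix(make_degs({"A": {"a"}}), "up")


class TestExactIntersectionTest:
    def test_m2_reduces_to_hypergeometric(self):
        expected, p = exact_intersection_test([5, 4], N=20, observed=3)
        assert p == pytest.approx(155 / 4845, abs=1e-12)
        rng = np.random.default_rng(3)
        for _ in range(30):
            N = int(rng.integers(20, 200))
            n1, n2 = int(rng.integers(1, N)), int(rng.integers(1, N))
            k = int(rng.integers(0, min(n1, n2) + 1))
            _, p = exact_intersection_test([n1, n2], N, k)
            assert p == pytest.approx(float(stats.hypergeom.sf(k - 1, N, n1, n2)),
                                      abs=1e-12)

    def test_expected_size_product_formula(self):
        expected, _ = exact_intersection_test([50, 50, 50], N=100, observed=0)
        assert expected == pytest.approx(12.5)

    def test_m3_matches_monte_carlo(self):
        rng = np.random.default_rng(8)
        N, sizes, k = 30, [10, 10, 10], 2
        _, p = exact_intersection_test(sizes, N, k)
        n_draws = 200_000
        hits = 0
        universe = np.arange(N)
        for _ in range(n_draws):
            inter = None
            for n in sizes:
                s = set(rng.choice(universe, size=n, replace=False))
                inter = s if inter is None else (inter & s)
            hits += len(inter) >= k
        p_mc = hits / n_draws
        se = np.sqrt(p_mc * (1 - p_mc) / n_draws)
        assert abs(p - p_mc) <= 3 * se

    def test_observed_above_smallest_set_rejected(self):
        with pytest.raises(ValidationError):
            exact_intersection_test([5, 4], N=20, observed=5)


def brute_force_landscape(degs: DegSets, objective: str = "both"):
    """Independent enumeration: recompute every subset's overlap from scratch."""
    ids = degs.dataset_ids
    best = {}
    for k in range(2, len(ids) + 1):
        candidates = []
        for combo in itertools.combinations(ids, k):
            up = set.intersection(*[degs.up[d] for d in combo])
            down = set.intersection(*[degs.down[d] for d in combo])
            score = {"both": len(up) + len(down), "up": len(up),
                     "down": len(down)}[objective]
            candidates.append((-score, combo, len(up), len(down)))
        candidates.sort()
        _, combo, n_up, n_down = candidates[0]
        best[k] = (combo, n_up, n_down)
    return best


class TestIntersectionLandscape:
    def test_hand_enumerable_example(self):
        degs = make_degs({"A": {"g1", "g2", "g3"}, "B": {"g2", "g3", "g4"},
                          "C": {"g3", "g5"}})
        records = intersection_landscape(degs)
        by_degree = {r.degree: r for r in records}
        assert by_degree[2].combination == ("A", "B")
        assert by_degree[2].up_size == 2
        assert by_degree[3].up_size == 1

    def test_shared_identical_sets_keep_size_at_all_degrees(self):
        shared = {f"g{i}" for i in range(7)}
        degs = make_degs({ds: shared for ds in ("A", "B", "C", "D")})
        for record in intersection_landscape(degs):
            assert record.up_size == 7

    def test_matches_bruteforce_on_random_compendia(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(60)]
        for _ in range(10):
            K = int(rng.integers(3, 6))
            up = {f"D{j}": set(rng.choice(genes, size=rng.integers(5, 30), replace=False))
                  for j in range(K)}
            down = {f"D{j}": set(rng.choice(genes, size=rng.integers(5, 30), replace=False))
                    for j in range(K)}
            down = {ds: down[ds] - up[ds] for ds in down}
            degs = make_degs(up, down, N=60)
            oracle = brute_force_landscape(degs)
            for record in intersection_landscape(degs):
                combo, n_up, n_down = oracle[record.degree]
                assert record.combination == combo
                assert (record.up_size, record.down_size) == (n_up, n_down)

    def test_best_overlap_nonincreasing_in_degree(self):
        rng = np.random.default_rng(18)
        genes = [f"g{i}" for i in range(50)]
        up = {f"D{j}": set(rng.choice(genes, size=20, replace=False)) for j in range(6)}
        degs = make_degs(up, N=50)
        sizes = [r.up_size + r.down_size for r in intersection_landscape(degs)]
        assert sizes == sorted(sizes, reverse=True)

    def test_degree_out_of_range_rejected(self):
        degs = make_degs({"A": {"a"}, "B": {"b"}})
        with pytest.raises(ValidationError):
            intersection_landscape(degs, degrees=[3])

    def test_table_view_has_one_row_per_degree(self):
        degs = make_degs({"A": {"a", "c"}, "B": {"a"}, "C": {"c"}})
        table = landscape_table(intersection_landscape(degs))
        assert list(table.index) == [2, 3]


class TestRankDatasets:
    def _degs(self):
        good_up = {f"g{i}" for i in range(40)}
        good_down = {f"h{i}" for i in range(40)}
        return make_degs(
            {"A": good_up, "B": good_up | {"x1"}, "C": {"g1", "MKRnone"}},
            {"A": good_down, "B": good_down, "C": {"h1"}},
        )

    def test_low_deg_count_fails_first_criterion(self):
        report = rank_datasets(self._degs(), markers=["g0"], min_deg=50,
                               min_marker_frac=0.5)
        assert not report.loc["C", "pass_n_deg"]
        assert not report.loc["C", "include"]
        assert report.loc["A", "include"]

    def test_missing_markers_fail_second_criterion(self):
        degs = self._degs()
        markers = ["m1", "m2", "m3", "m4", "m5", "m6"]  # absent everywhere
        report = rank_datasets(degs, markers=markers, min_deg=10, min_marker_frac=0.5)
        assert not report["pass_markers"].any()

    def test_marker_criterion_requires_markers(self):
        with pytest.raises(ValidationError):
            rank_datasets(self._degs(), markers=[])

    def test_criteria_can_be_disabled(self):
        report = rank_datasets(self._degs(), markers=None, min_deg=50,
                               criteria=("n_deg",))
        assert report.loc["A", "pass_markers"] is None
        assert report.loc["A", "include"]


class TestConsensusSignature:
    def test_pairwise_intersection(self):
        degs = make_degs({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
        sig = consensus_signature(degs, ensemble=["A", "B"])
        assert sig.up == ["g2"]

    def test_empty_member_empties_signature(self):
        degs = make_degs({"A": {"g1"}, "B": set()})
        sig = consensus_signature(degs, ensemble=["A", "B"])
        assert sig.up == []

    def test_small_ensemble_rejected(self):
        degs = make_degs({"A": {"g1"}, "B": {"g1"}})
        with pytest.raises(ValidationError):
            consensus_signature(degs, ensemble=["A"])

    def test_suspect_genes_are_flagged_not_removed(self):
        degs = make_degs({"A": {"g1", "fos"}, "B": {"g1", "fos"}})
        sig = consensus_signature(degs, ensemble=["A", "B"], suspects=["fos"])
        assert "fos" in sig.up  # kept
        assert sig.flagged_up == ["fos"]
        assert flag_suspect_genes(sig, ["fos", "jun"]) == ["fos"]

    def test_signature_genes_are_degs_everywhere(self, benchmark_run):
        sig = benchmark_run["signature"]
        degs = benchmark_run["degs"]
        for gene in sig.up:
            assert all(gene in degs.up[ds] for ds in sig.ensemble)
        for gene in sig.down:
            assert all(gene in degs.down[ds] for ds in sig.ensemble)
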