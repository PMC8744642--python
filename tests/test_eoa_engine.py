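import itertools
import json
import math

import numpy as np
import pytest

from enrichopt.eoa_engine import (
    AnnealingSchedule,
    EoaModel,
    MoveConfig,
    objective_value,
    optimize,
    primary_score,
    propose_move,
    rank_compounds,
    secondary_score,
)
from enrichopt.preprocessing import zscore_normalize
from enrichopt.screening_metrics import auc
from enrichopt.synthetic_benchmark import BenchmarkParams, generate_benchmark

from conftest import make_dataset, ranked_from_labels


class TestRanking:
    def test_orders_by_descending_score(self):
        ds = make_dataset(np.array([[0.5], [2.0], [-1.0]]), [1, 0, 0], ids=["C1", "C2", "C3"])
        model = EoaModel(["d0"], np.array([1.0]))
        ranked = rank_compounds(model, ds)
        assert ranked.compound_ids == ["C2", "C1", "C3"]

    def test_all_ties_keep_input_order(self):
        ds = make_dataset(np.zeros((4, 1)), [0, 1, 0, 1], ids=list("abcd"))
        ranked = rank_compounds(EoaModel(["d0"], np.array([1.0])), ds)
        assert ranked.compound_ids == list("abcd")

    def test_two_descriptor_hand_example(self):
        # weights (1, -2) on C1:(1,1), C2:(2,0), C3:(0,-1) -> scores (-1, 2, 2)
        ds = make_dataset(
            np.array([[1.0, 1.0], [2.0, 0.0], [0.0, -1.0]]), [1, 0, 0], ids=["C1", "C2", "C3"]
        )
        ranked = rank_compounds(EoaModel(["d0", "d1"], np.array([1.0, -2.0])), ds)
        assert ranked.compound_ids == ["C2", "C3", "C1"]

    def test_missing_descriptor_named(self):
        ds = make_dataset(np.zeros((2, 1)), [1, 0])
        with pytest.raises(ValueError, match="dX"):
            rank_compounds(EoaModel(["dX"], np.array([1.0])), ds)


class TestObjective:
    def test_perfect_ranking_scores_L(self):
        ranked = ranked_from_labels([1, 1, 1, 0, 0])
        assert primary_score(ranked, 3) == 3

    def test_alternating_example(self):
        assert primary_score(ranked_from_labels([1, 0, 1, 0]), 2) == 1

    def test_L_must_match_active_count(self):
        with pytest.raises(ValueError, match="actives"):
            primary_score(ranked_from_labels([1, 0, 1, 0]), 3)

    @pytest.mark.parametrize(
        "labels,L,tau,expected_D,expected_secondary",
        [
            ([1, 1, 0, 0], 2, 2.0, 0, 1.0),
            ([1, 0, 1, 0], 2, 2.0, 2, 2 / (1 + math.e)),
            ([0, 0, 1, 1], 2, 2.0, 6, 2 / (1 + math.e**3)),
        ],
    )
    def test_secondary_hand_examples(self, labels, L, tau, expected_D, expected_secondary):
        D, s = secondary_score(ranked_from_labels(labels), L, tau)
        assert D == expected_D
        assert s == pytest.approx(expected_secondary, abs=1e-10)

    def test_total_combines_primary_and_secondary(self):
        obj = objective_value(ranked_from_labels([1, 0, 1, 0]), 2, tau=2.0)
        assert obj.total == pytest.approx(1 + 2 / (1 + math.e), abs=1e-10)
        perfect = objective_value(ranked_from_labels([1, 1, 0, 0]), 2)
        assert perfect.total == pytest.approx(3.0)

    @pytest.mark.parametrize("L,O", [(3, 3), (4, 4)])
    def test_total_sorts_lexicographically_by_exhaustion(self, L, O):
        """Over all orderings, total ranks by (primary, -displacement) and
        peaks uniquely at perfect separation."""
        n = L + O
        evaluated = []
        for active_pos in itertools.combinations(range(n), L):
            labels = np.zeros(n, dtype=bool)
            labels[list(active_pos)] = True
            obj = objective_value(ranked_from_labels(labels), L)
            evaluated.append(obj)
            assert 0 < obj.secondary <= 1
            assert (obj.secondary == 1.0) == (obj.displacement == 0)
        for a, b in itertools.combinations(evaluated, 2):
            if (a.primary, -a.displacement) > (b.primary, -b.displacement):
                assert a.total > b.total
            elif (a.primary, -a.displacement) < (b.primary, -b.displacement):
                assert a.total < b.total
            else:
                assert a.total == pytest.approx(b.total)
        totals = sorted(o.total for o in evaluated)
        assert totals[-1] == pytest.approx(L + 1.0)
        assert totals[-1] > totals[-2]  # unique global maximum


class TestSchedule:
    def test_default_saw_tooth_arithmetic(self):
        s = AnnealingSchedule()
        assert s.n_rungs == 100
        np.testing.assert_allclose(s.ladder, [1.0 - 0.01 * i for i in range(100)], atol=1e-12)
        assert s.ladder[0] == 1.0 and s.ladder[-1] == 0.01
        assert s.cycle_steps == 40_000
        assert s.total_steps // s.cycle_steps == 25
        assert s.rt_at(0) == 1.0
        assert s.rt_at(399) == 1.0
        assert s.rt_at(400) == 0.99
        assert s.rt_at(39_999) == 0.01
        assert s.rt_at(40_000) == 1.0  # saw-tooth reset

    def test_invalid_programs_rejected(self):
        with pytest.raises(ValueError):
            AnnealingSchedule(rt_start=0.01, rt_end=1.0)
        with pytest.raises(ValueError):
            AnnealingSchedule(rt_step=0.0)


class TestProposeMove:
    POOL = [f"d{i}" for i in range(10)]

    def _model(self):
        return EoaModel(["d0", "d1", "d2"], np.array([0.3, -0.5, 0.8]))

    def test_exactly_one_change_and_size_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            out = propose_move(self._model(), self.POOL, MoveConfig(), rng)
            assert out.n == 3 and len(set(out.descriptor_names)) == 3
            changed = sum(
                1
                for a, b, wa, wb in zip(
                    self._model().descriptor_names, out.descriptor_names,
                    self._model().weights, out.weights,
                )
                if a != b or wa != wb
            )
            assert changed == 1

    def test_untouched_weights_bit_identical(self):
        rng = np.random.default_rng(1)
        model = self._model()
        out = propose_move(model, self.POOL, MoveConfig(swap_probability=0.0), rng)
        same = [j for j in range(3) if out.weights[j] == model.weights[j]]
        assert len(same) == 2

    def test_replay_equality(self):
        def run(seed):
            rng = np.random.default_rng(seed)
            model = self._model()
            seq = []
            for _ in range(1000):
                model = propose_move(model, self.POOL, MoveConfig(), rng)
                seq.append((tuple(model.descriptor_names), model.weights.tobytes()))
            return seq

        assert run(42) == run(42)

    def test_pool_smaller_than_model_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            propose_move(self._model(), ["d0", "d1"], MoveConfig(), np.random.default_rng(0))


@pytest.fixture(scope="module")
def planted_run():
    """Planted-signal training set and one full optimizer run.

    5 informative descriptors out of 30 at effect size 3.0: a separating
    linear rule exists by construction.
    """
    ds, gt = generate_benchmark(
        BenchmarkParams(
            n_active=50, n_decoy=500, n_descriptors=30, n_informative=5,
            effect_size=3.0, n_redundant=0, n_constant=0, seed=1,
        )
    )
    z, _ = zscore_normalize(ds)
    model, trace = optimize(
        z, 7, schedule=AnnealingSchedule(total_steps=50_000), seed=1
    )
    return z, gt, model, trace


class TestOptimize:
    def test_model_shape_and_finiteness(self, planted_run):
        _, _, model, _ = planted_run
        assert model.n == 7
        assert len(set(model.descriptor_names)) == 7
        assert np.isfinite(model.weights).all()

    def test_perfect_topL_recovery_on_separable_data(self, planted_run):
        z, _, model, _ = planted_run
        # independent oracle: logistic regression confirms a separating
        # linear rule places all actives in the top L
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(max_iter=2000).fit(z.values, z.labels)
        lr_rank = np.argsort(-(z.values @ lr.coef_[0]), kind="stable")
        assert z.labels[lr_rank][: z.n_active].all(), "oracle says separable"
        assert model.metadata["objective"]["primary"] == z.n_active

    def test_recovers_planted_informative_descriptors(self, planted_run):
        z, gt, model, _ = planted_run
        # univariate-AUC oracle: the informative columns are exactly the
        # top-5 single-descriptor rankers
        uni = {
            nm: auc(z.labels, z.values[:, j]) for j, nm in enumerate(z.descriptor_names)
        }
        top5 = sorted(uni, key=lambda nm: -uni[nm])[:5]
        assert set(top5) == set(gt.informative)
        assert len(set(model.descriptor_names) & set(gt.informative)) >= 4

    def test_best_so_far_is_non_decreasing(self, planted_run):
        _, _, _, trace = planted_run
        assert (np.diff(trace.best_total) >= 0).all()
        assert ((trace.acceptance_rate >= 0) & (trace.acceptance_rate <= 1)).all()

    def test_identical_seed_identical_model(self):
        ds, _ = generate_benchmark(
            BenchmarkParams(n_active=20, n_decoy=80, n_descriptors=15,
                            n_redundant=0, n_constant=0, seed=3)
        )
        z, _ = zscore_normalize(ds)
        sched = AnnealingSchedule(total_steps=4000)
        m1, _ = optimize(z, 5, schedule=sched, seed=9)
        m2, _ = optimize(z, 5, schedule=sched, seed=9)
        assert json.dumps(m1.to_dict(), sort_keys=True) == json.dumps(m2.to_dict(), sort_keys=True)
        m3, _ = optimize(z, 5, schedule=sched, seed=10)
        assert m3.to_dict() != m1.to_dict()

    def test_restricted_pool_respected(self):
        ds, _ = generate_benchmark(
            BenchmarkParams(n_active=20, n_decoy=80, n_descriptors=15,
                            n_redundant=0, n_constant=0, seed=3)
        )
        z, _ = zscore_normalize(ds)
        pool = ["D000", "D001", "D002", "D003", "D004", "D005", "D006"]
        model, _ = optimize(
            z, 3, schedule=AnnealingSchedule(total_steps=2000), seed=1,
            allowed_descriptors=pool,
        )
        assert set(model.descriptor_names) <= set(pool)

    def test_infeasible_sizes_rejected(self):
        ds, _ = generate_benchmark(
            BenchmarkParams(n_active=5, n_decoy=10, n_descriptors=4, n_informative=2,
                            n_redundant=0, n_constant=0, seed=0)
        )
        with pytest.raises(ValueError, match="infeasible"):
            optimize(ds, 5, schedule=AnnealingSchedule(total_steps=10))


def test_model_file_round_trip(tmp_path):
    model = EoaModel(["a", "b"], np.array([0.25, -1.5]), metadata={"seed": 1})
    path = tmp_path / "model.json"
    model.save(path)
    back = EoaModel.load(path)
    assert back.descriptor_names == model.descriptor_names
    np.testing.assert_array_equal(back.weights, model.weights)
    assert back.metadata["seed"] == 1
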