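import math

import numpy as np
import pytest

from sirna_boundary.data_io import Dataset, SiRNARecord
from sirna_boundary.i_iteration import (
    BetaParams,
    IterationEngine,
    compute_beta,
    removal_predicate,
    run_iteration,
)


def agg(pairs):
    return np.array(pairs, dtype=np.int64)


class TestBeta:
    def test_min_rule_for_mg(self):
        a = agg([(0, 5), (2, 9), (3, 1)])
        b = compute_beta(a, np.ones(3, bool), t=1)
        assert b.beta1 == 0
        assert b.beta2 == 9

    def test_conditional_max_for_icc(self):
        a = agg([(0, 4), (0, 11), (7, 30)])
        b = compute_beta(a, np.ones(3, bool), t=3)
        assert b.beta1 == 11  # max c2 among potent with c1 == 0
        assert b.beta2 == 30

    def test_infinite_sentinel_without_zero_c1(self):
        a = agg([(2, 4), (5, 11)])
        b = compute_beta(a, np.ones(2, bool), t=3)
        assert math.isinf(b.beta1)

    def test_no_potent_training_is_an_error(self):
        with pytest.raises(ValueError):
            compute_beta(agg([(1, 1)]), np.zeros(1, bool), t=1)


class TestRemovalPredicate:
    def _betas(self, b1_mg=0, b2=31, b1_icc=math.inf):
        return {
            1: BetaParams(b1_mg, b2, 1),
            2: BetaParams(b1_mg, b2, 2),
            3: BetaParams(b1_icc, b2, 3),
            4: BetaParams(b1_icc, b2, 4),
        }

    def test_zero_first_aggregate_removed_via_mg(self):
        pairs = {1: (0, 5), 2: (9, 1), 3: (5, 0), 4: (5, 0)}
        flag, cond = removal_predicate(pairs, self._betas(), s=1)
        assert flag and cond == "t1:c1<=beta1"

    def test_icc_route_with_infinite_beta1(self):
        # min(inf, 16 + 1) = 17 <= 18 triggers the Icc condition
        pairs = {1: (9, 1), 2: (9, 1), 3: (0, 18), 4: (9, 0)}
        flag, cond = removal_predicate(pairs, self._betas(), s=1)
        assert flag and cond.startswith("t3:c1=0")

    def test_second_aggregate_at_threshold_removed(self):
        pairs = {1: (9, 31), 2: (9, 1), 3: (5, 0), 4: (5, 0)}
        flag, cond = removal_predicate(pairs, self._betas(b2=31), s=1)
        assert flag and cond == "t1:c2>=beta2"

    def test_safe_record_not_removed(self):
        pairs = {1: (5, 1), 2: (6, 2), 3: (3, 0), 4: (4, 0)}
        flag, cond = removal_predicate(pairs, self._betas(), s=1)
        assert not flag and cond is None

    def test_potent_direction_dominance_is_safe(self, rng):
        # aggregates strictly dominating every potent training record in the
        # potent direction can never satisfy any removal condition
        for _ in range(50):
            b2 = int(rng.integers(1, 32))
            b1_icc = float(rng.integers(1, 32))
            betas = self._betas(b1_mg=0, b2=b2, b1_icc=b1_icc)
            pairs = {
                1: (int(rng.integers(1, 32)), int(rng.integers(0, b2))),
                2: (int(rng.integers(1, 32)), int(rng.integers(0, b2))),
                3: (int(rng.integers(1, 32)), int(rng.integers(0, b2))),
                4: (int(rng.integers(1, 32)), int(rng.integers(0, b2))),
            }
            flag, _ = removal_predicate(pairs, betas, s=int(rng.integers(1, 11)))
            assert not flag


class TestIterationRuns:
    def test_conservation_and_monotone_removals(self, default_run):
        ds, engine, state = default_run
        assert len(state.p_cluster) + len(state.i_cluster) == len(ds.test)
        cum = list(state.cumulative_removals_by_stage().values())
        assert cum == sorted(cum)

    def test_pass_budget(self, default_run):
        ds, _, state = default_run
        # each non-final pass removes at least one record
        assert state.n_passes <= len(ds.test) + 11

    def test_aggregate_bound_holds_over_full_run(self, default_run):
        _, engine, state = default_run
        assert 0 <= state.max_aggregate <= 31

    def test_removed_records_never_return(self, default_run):
        ds, _, state = default_run
        assert len(set(ev.id for ev in state.removal_log)) == len(state.removal_log)
        assert set(state.i_cluster) == {ev.id for ev in state.removal_log}

    def test_deterministic_rerun(self, small_run):
        ds, _, state = small_run
        _, state2 = run_iteration(ds)
        assert [(e.id, e.alpha, e.pass_no, e.t, e.condition) for e in state.removal_log] == [
            (e.id, e.alpha, e.pass_no, e.t, e.condition) for e in state2.removal_log
        ]
        assert state.p_cluster == state2.p_cluster

    def test_beta_trace_is_logged_per_pass_and_t(self, default_run):
        _, _, state = default_run
        assert len(state.beta_trace) == 4 * state.n_passes
        for row in state.beta_trace:
            assert row["beta2"] <= 31
            if row["t"] in (1, 2):
                assert row["beta1"] <= 31

    def test_roles_required(self):
        seq = "ACGTACGTACGTACGTACG"
        ds = Dataset([SiRNARecord("a", seq, 90.0), SiRNARecord("b", seq, 10.0)])
        with pytest.raises(ValueError):
            IterationEngine(ds)

    def test_hand_traced_inner_pass(self):
        """Replays the first pass against an independent per-record evaluation."""
        from sirna_boundary.synthetic_fixtures import FixtureConfig, generate_fixture

        ds = generate_fixture(
            FixtureConfig(n_potent=10, n_ineffective=30, n_motif_families=2,
                          n_decoy_potent=2, seed=3)
        )
        engine = IterationEngine(ds)
        removed = np.zeros(engine.n, bool)
        e = engine.e_labels(20, removed)
        parts = engine.partitions_for(int(engine.orig_train.sum()))
        aggs = engine.aggregates(e, parts)
        potent_train = engine.orig_train & engine.potent
        betas = {t: compute_beta(aggs[t], potent_train, t) for t in (1, 2, 3, 4)}
        expected = set()
        for i in np.flatnonzero(~engine.orig_train):
            pairs = {t: (int(aggs[t][i, 0]), int(aggs[t][i, 1])) for t in (1, 2, 3, 4)}
            hit = (
                pairs[1][0] <= betas[1].beta1
                or pairs[2][0] <= betas[2].beta1
                or any(pairs[t][1] >= betas[t].beta2 for t in (1, 2, 3, 4))
                or any(
                    pairs[t][0] == 0 and pairs[t][1] >= min(betas[t].beta1, 17)
                    for t in (3, 4)
                )
            )
            if hit:
                expected.add(engine.ids[i])
        _, state = run_iteration(ds)
        first_pass = {
            ev.id for ev in state.removal_log if ev.alpha == 20 and ev.pass_no == 1
        }
        assert first_pass == expected
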