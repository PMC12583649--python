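import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coregflow as cf
from coregflow.inference import (
    collective_state,
    discretize,
    mine_candidates,
    predict_target,
)


def _dataset(values, genes=None, samples=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return cf.ExpressionDataset(pd.DataFrame(arr, index=genes, columns=samples))


def _disc(values, genes=None, samples=None):
    arr = np.asarray(values, dtype=int)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return cf.DiscreteMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestDiscretize:
    def test_hand_computed_z_scores(self):
        # values 1..5: mean 3, unbiased SD sqrt(2.5); z(5)=1.2649, z(1)=-1.2649
        d = discretize(_dataset([[1, 2, 3, 4, 5]]), z_threshold=1.0)
        assert list(d.values.iloc[0]) == [-1, 0, 0, 0, 1]

    def test_constant_gene_is_all_zero(self):
        d = discretize(_dataset([[2, 2, 2, 2]]))
        assert (d.values.iloc[0] == 0).all()

    def test_zero_threshold_leaves_no_zeros_off_mean(self):
        d = discretize(_dataset([[1, 2, 4, 5]]), z_threshold=0.0)
        assert (d.values.iloc[0] != 0).all()

    def test_single_sample_rejected(self):
        with pytest.raises(cf.CoregflowError):
            discretize(_dataset([[1.0]]))


class TestLocalRules:
    def test_collective_state_median(self):
        d = _disc([[1], [1], [-1]], genes=["a", "b", "c"])
        assert collective_state({"a", "b", "c"}, d, "s0") == 1

    def test_collective_state_even_split_is_zero(self):
        d = _disc([[1], [-1]], genes=["a", "b"])
        assert collective_state({"a", "b"}, d, "s0") == 0

    def test_collective_state_empty_set_is_zero(self):
        d = _disc([[1]], genes=["a"])
        assert collective_state(set(), d, "s0") == 0

    @pytest.mark.parametrize(
        "sa,si,expected",
        [(1, -1, 1), (1, 1, 0), (0, -1, 1), (-1, 1, -1), (0, 0, 0), (-1, -1, 0)],
    )
    def test_predict_target_sign_rule(self, sa, si, expected):
        assert predict_target(sa, si) == expected


class TestScoreProgram:
    def test_perfect_fit_scores_zero(self):
        d = _disc([[1, -1, 0, 1], [1, -1, 0, 1]], genes=["r1", "t"])
        prog = cf.LocalProgram("t", frozenset({"r1"}), frozenset())
        assert cf.score_program(prog, d) == 0.0

    def test_worst_case_scores_two(self):
        d = _disc([[1, 1], [-1, -1]], genes=["r1", "t"])
        prog = cf.LocalProgram("t", frozenset({"r1"}), frozenset())
        assert cf.score_program(prog, d) == 2.0

    def test_partial_mismatch_arithmetic(self):
        # 10 samples, 3 unit mismatches, 7 exact -> 0.3
        reg = [1] * 10
        obs = [1] * 7 + [0] * 3
        d = _disc([reg, obs], genes=["r1", "t"])
        prog = cf.LocalProgram("t", frozenset({"r1"}), frozenset())
        assert cf.score_program(prog, d) == pytest.approx(0.3)


class TestMineCandidates:
    def test_pair_support_counted(self):
        r1 = [1] * 6 + [0] * 4
        r2 = [1] * 6 + [-1] * 4
        d = _disc([r1, r2], genes=["r1", "r2"])
        cat = cf.RegulatorCatalog(frozenset({"r1", "r2"}))
        found = {
            tuple(sorted(c.members)): c.support
            for c in mine_candidates(d, cat, min_support=0.5, max_set_size=2)
        }
        assert found[("r1", "r2")] == pytest.approx(0.6)

    def test_unreachable_support_keeps_only_singletons(self):
        r1 = [1, 0, 0, 0]
        r2 = [0, 1, 0, 0]
        d = _disc([r1, r2], genes=["r1", "r2"])
        cat = cf.RegulatorCatalog(frozenset({"r1", "r2"}))
        out = mine_candidates(d, cat, min_support=0.25)
        assert all(len(c.members) == 1 for c in out)

    @given(seed=st.integers(0, 5_000))
    @settings(max_examples=20, deadline=None)
    def test_anti_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(-1, 2, size=(6, 30))
        d = _disc(arr, genes=[f"r{i}" for i in range(6)])
        cat = cf.RegulatorCatalog(frozenset(d.gene_ids))
        out = mine_candidates(d, cat, min_support=0.15, max_set_size=4)
        supports = {frozenset(c.members): c.support for c in out}
        for members, supp in supports.items():
            for r in members:
                if len(members) > 1:
                    sub = members - {r}
                    assert sub in supports
                    assert supports[sub] >= supp

    def test_deterministic_ordering(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(-1, 2, size=(5, 20))
        d = _disc(arr, genes=[f"r{i}" for i in range(5)])
        cat = cf.RegulatorCatalog(frozenset(d.gene_ids))
        a = mine_candidates(d, cat)
        b = mine_candidates(d, cat)
        assert a == b
        assert all(
            a[i].support >= a[i + 1].support for i in range(len(a) - 1)
        )


class TestInferNetwork:
    def test_noiseless_activator_repressor_pair_recovered(self):
        # target driven by one activator and one repressor, no noise; the
        # exact program wins, with a near-perfect discrete fit (samples
        # where both regulators are extreme predict 0 while the weighted
        # difference can still cross the threshold, so the fit need not be
        # exactly zero)
        cfg = cf.SimulationConfig(
            n_regulators=2,
            n_targets=1,
            planted_node_size=1,
            planted_block_size=0,
            activators_per_target=(1, 1),
            repressors_per_target=(1, 1),
            sigma=0.0,
            edge_weight_range=(1.0, 1.0),
            seed=2,
        )
        ds, _, truth = cf.simulate_dataset(cfg)
        cat = cf.RegulatorCatalog(frozenset(truth.true_activity.index))
        net = cf.infer_network(ds, cat, min_coexpression=0.0)
        prog = net.programs["G000"]
        true_prog = truth.true_network.programs["G000"]
        assert prog.activators == true_prog.activators
        assert prog.repressors == true_prog.repressors
        assert prog.fit_score <= 0.4

    def test_unrelated_gene_omitted_under_strict_cutoff(self, rng):
        reg = rng.normal(size=40)
        indep = rng.normal(size=40)
        ds = _dataset(np.vstack([reg, indep]), genes=["r1", "t"])
        cat = cf.RegulatorCatalog(frozenset({"r1"}))
        net = cf.infer_network(ds, cat, fit_cutoff=0.05, min_coexpression=0.0)
        assert "t" not in net.programs
        assert "t" in net.omitted_targets

    def test_noiseless_single_activator_f1_is_one(self):
        cfg = cf.SimulationConfig(
            n_regulators=10,
            n_targets=40,
            planted_node_size=1,
            planted_block_size=0,
            activators_per_target=(1, 1),
            repressors_per_target=(0, 0),
            sigma=0.0,
            seed=4,
        )
        ds, _, truth = cf.simulate_dataset(cfg)
        cat = cf.RegulatorCatalog(frozenset(truth.true_activity.index))
        net = cf.infer_network(ds, cat)
        f1, _, _ = cf.edge_f1(net, truth.true_network)
        assert f1 == 1.0

    def test_inference_is_deterministic(self):
        ds, _, truth = cf.simulate_dataset(cf.SimulationConfig(seed=6, n_targets=50))
        cat = cf.RegulatorCatalog(frozenset(truth.true_activity.index))
        n1 = cf.infer_network(ds, cat)
        n2 = cf.infer_network(ds, cat)
        assert n1.programs == n2.programs

    def test_fit_scores_within_range(self):
        ds, _, truth = cf.simulate_dataset(cf.SimulationConfig(seed=6, n_targets=50))
        cat = cf.RegulatorCatalog(frozenset(truth.true_activity.index))
        cands = cf.infer_candidate_programs(ds, cat)
        for progs in cands.values():
            for p in progs:
                assert 0.0 <= p.fit_score <= 2.0
            fits = [p.fit_score for p in progs]
            assert fits == sorted(fits)
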