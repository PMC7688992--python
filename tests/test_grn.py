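"""Preprocessing, role assignment, the greedy-BIC learner and the consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vigornet import synthetic
from vigornet.config import ConsensusParams
from vigornet.errors import ConfigError, InferenceError, InputError
from vigornet.grn import (
    RoleAssignment,
    apply_consensus_threshold,
    assign_roles,
    consensus_network,
    draw_subsets,
    fpkm_to_tpm,
    learn_subnetwork,
    preprocess,
    recovery_metrics,
    retention_filter,
    zero_mean,
)


def _frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestTpm:
    def test_forced_normalization(self):
        out = fpkm_to_tpm(_frame([[2], [3], [5]]))
        np.testing.assert_allclose(out.to_numpy().ravel(), [2e5, 3e5, 5e5])

    def test_identity_when_already_normalized(self):
        m = _frame([[4e5], [6e5]])
        pd.testing.assert_frame_equal(fpkm_to_tpm(m), m)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_column_sums_conserved(self, seed):
        rng = np.random.default_rng(seed)
        m = _frame(rng.uniform(0.1, 100, size=(6, 4)))
        np.testing.assert_allclose(fpkm_to_tpm(m).sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_sum_column_named(self):
        m = _frame([[1, 0], [2, 0]], samples=["good", "bad"])
        with pytest.raises(InputError, match="bad"):
            fpkm_to_tpm(m)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            fpkm_to_tpm(_frame([[-1, 2]]))


class TestZeroMean:
    def test_constant_row_zeroed(self):
        out = zero_mean(_frame([[5, 5, 5]]))
        np.testing.assert_allclose(out.to_numpy(), 0)

    def test_simple_row(self):
        out = zero_mean(_frame([[1, 2, 3]]))
        np.testing.assert_allclose(out.to_numpy().ravel(), [-1, 0, 1])

    def test_idempotent(self):
        m = _frame(np.random.default_rng(0).normal(size=(4, 5)))
        once = zero_mean(m)
        pd.testing.assert_frame_equal(zero_mean(once), once)


class TestRetention:
    def _matrix(self, n_hot):
        # one gene with |value| >= 1 in exactly n_hot of 8 samples
        row = [1.0] * n_hot + [0.1] * (8 - n_hot)
        return _frame([row], genes=["g"])

    def test_boundary_five_samples_kept(self):
        assert retention_filter(self._matrix(5), {"g"}) == {"g"}

    def test_four_samples_dropped(self):
        assert retention_filter(self._matrix(4), {"g"}) == set()

    def test_not_in_de_union_dropped(self):
        assert retention_filter(self._matrix(6), {"other"}) == set()

    def test_empty_matrix(self):
        assert retention_filter(pd.DataFrame(), {"g"}) == set()

    def test_bad_params(self):
        with pytest.raises(ConfigError):
            retention_filter(self._matrix(5), {"g"}, delta=0)


class TestRoles:
    def test_disjoint_union(self):
        roles = assign_roles({"a"}, {"b"}, {"c"}, {"d"})
        assert roles.targets == {"a", "b", "d"}
        assert roles.factors == {"b", "c", "d"}

    def test_idempotent_union(self):
        roles = assign_roles({"a", "m"}, set(), {"r"}, {"m"})
        assert roles.targets == {"a", "m"}

    def test_regulators_only(self):
        roles = assign_roles(set(), set(), {"r1", "r2"}, set())
        assert roles.factors == {"r1", "r2"} and roles.targets == set()

    def test_empty_factors_raise(self):
        with pytest.raises(InferenceError):
            assign_roles({"a"}, set(), set(), set(), retained={"a"})


class TestLearner:
    def test_noiseless_single_regulator(self):
        rng = np.random.default_rng(1)
        f1, f2 = rng.normal(size=20), rng.normal(size=20)
        t = 1.5 * f1
        zm = _frame([f1, f2, t], genes=["f1", "f2", "t"])
        roles = RoleAssignment(factors=frozenset({"f1", "f2"}), targets=frozenset({"t"}))
        edges = learn_subnetwork(zm, roles)
        assert set(edges) == {("f1", "t")}
        assert edges[("f1", "t")] == pytest.approx(1.5)

    def test_identical_factors_lexicographic_tie(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=20)
        t = 2.0 * f + rng.normal(0, 0.01, size=20)
        zm = _frame([f, f.copy(), t], genes=["fb", "fa", "t"])
        roles = RoleAssignment(factors=frozenset({"fa", "fb"}), targets=frozenset({"t"}))
        edges = learn_subnetwork(zm, roles)
        assert ("fa", "t") in edges and ("fb", "t") not in edges

    def test_target_never_regulates_itself(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        zm = _frame([x, 0.9 * x], genes=["a", "b"])
        roles = RoleAssignment(factors=frozenset({"a", "b"}), targets=frozenset({"a", "b"}))
        edges = learn_subnetwork(zm, roles)
        assert all(f != t for f, t in edges)

    def test_too_few_samples(self):
        zm = _frame(np.zeros((2, 7)))
        roles = RoleAssignment(factors=frozenset({"g0"}), targets=frozenset({"g1"}))
        with pytest.raises(InputError):
            learn_subnetwork(zm, roles)


class TestConsensus:
    def test_min_count_derivation(self):
        assert ConsensusParams(n_subsets=30, confidence=0.6).min_count == 18

    def test_occurrence_threshold_boundary(self):
        params = ConsensusParams(n_subsets=30, confidence=0.6)
        counts = {("f", "t17"): 17, ("f", "t18"): 18, ("f", "t30"): 30}
        kept = apply_consensus_threshold(counts, None, params)
        assert set(kept) == {("f", "t18"), ("f", "t30")}

    def test_subsets_seeded_and_sized(self):
        params = ConsensusParams(seed=9)
        a = draw_subsets(60, params)
        b = draw_subsets(60, params)
        assert all((x == y).all() for x, y in zip(a, b))
        assert all(len(s) == 30 and len(set(s)) == 30 for s in a)

    def test_subset_too_small(self):
        with pytest.raises(ConfigError):
            draw_subsets(10, ConsensusParams())

    def test_noiseless_world_all_planted_at_full_count(self, noiseless_cfg):
        expr, planted = synthetic.generate_compendium(noiseless_cfg)
        zm = preprocess(expr)
        roles = RoleAssignment(
            factors=frozenset(synthetic.factor_ids(noiseless_cfg)),
            targets=frozenset(expr.index),
        )
        params = ConsensusParams(seed=noiseless_cfg.seed)
        net = consensus_network(zm, roles, params)
        for edge in planted.edges:
            assert net.edges[edge]["count"] == params.n_subsets
        metrics = recovery_metrics(net, planted.edges)
        assert metrics["recall"] == 1.0

    def test_determinism(self, noiseless_cfg):
        expr, _ = synthetic.generate_compendium(noiseless_cfg)
        zm = preprocess(expr)
        roles = RoleAssignment(
            factors=frozenset(synthetic.factor_ids(noiseless_cfg)),
            targets=frozenset(expr.index),
        )
        n1 = consensus_network(zm, roles, ConsensusParams(seed=4))
        n2 = consensus_network(zm, roles, ConsensusParams(seed=4))
        assert n1.edges == n2.edges
        assert n1.subsets == n2.subsets

    def test_counts_bounded_by_n_subsets(self, noiseless_cfg):
        expr, _ = synthetic.generate_compendium(noiseless_cfg)
        zm = preprocess(expr)
        roles = RoleAssignment(
            factors=frozenset(synthetic.factor_ids(noiseless_cfg)),
            targets=frozenset(expr.index),
        )
        net = consensus_network(zm, roles, ConsensusParams(seed=4))
        assert all(rec["count"] <= 30 for rec in net.edges.values())

    def test_no_structure_world_consensus_culls_spurious_edges(self):
        """Factors with no planted targets: single subsets pick many spurious
        regulators (max-over-candidates beats the BIC penalty), but the
        18-of-30 recurrence rule culls most of them."""
        cfg = synthetic.SimConfig(
            n_samples=40, n_genes=100, n_factors=6, targets_per_factor=0,
            ppi_edges=50, planted_category_counts={}, seed=13,
        )
        expr, planted = synthetic.generate_compendium(cfg)
        assert len(planted) == 0
        zm = preprocess(expr)
        roles = RoleAssignment(
            factors=frozenset(synthetic.factor_ids(cfg)), targets=frozenset(expr.index)
        )
        params = ConsensusParams(seed=13)
        net = consensus_network(zm, roles, params)
        subsets = draw_subsets(cfg.n_samples, params)
        one_subset = learn_subnetwork(
            zm.iloc[:, subsets[0]], roles, params.max_regulators_per_target
        )
        # every consensus edge recurred; most single-subset picks did not
        assert all(rec["count"] >= params.min_count for rec in net.edges.values())
        assert len(net) < 0.5 * len(one_subset)
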