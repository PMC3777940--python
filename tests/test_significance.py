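"""Permutation null, empirical P-values, module calling and overlap tests."""

import numpy as np
import pytest

import rcanet as rc
from rcanet.errors import ValidationError

from conftest import brute_force_overlap_tail
from test_decomposition import random_problem


def make_null(pools: dict[str, list[float]], B: int = 1) -> rc.NullDistribution:
    return rc.NullDistribution(
        per_regulator_null={k: np.asarray(v, float) for k, v in pools.items()},
        B=B, seeds=list(range(B)),
    )


def make_Y(values, genes=None, regs=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    regs = regs or [f"r{j + 1}" for j in range(values.shape[1])]
    return rc.CoefficientMatrix(values, genes, regs)


class TestEmpiricalPvalues:
    def test_enumerated_counts(self):
        null = make_null({"r1": [1.0, 2.0, 3.0, 4.0]})
        Y = make_Y([[2.5], [5.0], [0.5]], regs=["r1"])
        p = rc.empirical_pvalues(Y, null, ties="conservative")
        np.testing.assert_allclose(
            p.values[:, 0], [(1 + 2) / 5, 1 / 5, (1 + 4) / 5]
        )

    def test_extremes_bounded(self):
        K = 10
        null = make_null({"r1": list(np.arange(1.0, K + 1))})
        Y = make_Y([[99.0], [-99.0]], regs=["r1"])
        p = rc.empirical_pvalues(Y, null, ties="conservative")
        assert p.values[0, 0] == pytest.approx(1 / (K + 1))
        assert p.values[1, 0] == 1.0

    def test_monotone_in_score(self):
        rng = np.random.default_rng(4)
        null = make_null({"r1": list(rng.normal(0, 1, 200))})
        obs = np.sort(rng.normal(0, 1, 50))[:, None]
        p = rc.empirical_pvalues(make_Y(obs, regs=["r1"]), null,
                                 ties="conservative")
        assert (np.diff(p.values[:, 0]) <= 1e-15).all()

    def test_randomized_ties_stay_valid_and_deterministic(self):
        null = make_null({"r1": [0.0] * 50 + [1.0] * 50})
        Y = make_Y(np.zeros((30, 1)), regs=["r1"])
        a = rc.empirical_pvalues(Y, null, seed=3)
        b = rc.empirical_pvalues(Y, null, seed=3)
        np.testing.assert_array_equal(a.values, b.values)
        assert (a.values > 0).all() and (a.values <= 1).all()
        # ties at zero spread over the atom's rank range instead of piling at 1
        assert a.values.std() > 0

    def test_missing_regulator(self):
        null = make_null({"r1": [1.0]})
        with pytest.raises(KeyError):
            rc.empirical_pvalues(make_Y([[1.0]], regs=["rX"]), null)


class TestExtractModules:
    def test_toy_calling_rule(self):
        Y = make_Y([[0.9], [0.0], [0.5]], genes=["g1", "g2", "g3"], regs=["r1"])
        p = rc.PValueMatrix(np.array([[0.001], [0.9], [0.01]]),
                            ["g1", "g2", "g3"], ["r1"])
        mods = rc.extract_modules(Y, p, p_cutoff=0.05, min_score=0.0)
        assert mods[0].gene_ids == ["g1", "g3"]

    def test_no_filter_keeps_every_nonzero(self):
        Y = make_Y([[0.9], [0.0], [0.5]], regs=["r1"])
        p = rc.PValueMatrix(np.full((3, 1), 0.5), Y.gene_ids, ["r1"])
        mods = rc.extract_modules(Y, p, p_cutoff=1.0, min_score=0.0)
        assert set(mods[0].gene_ids) == {"g1", "g3"}

    def test_all_p_one_gives_empty_module(self):
        Y = make_Y([[0.9], [0.5]], regs=["r1"])
        p = rc.PValueMatrix(np.ones((2, 1)), Y.gene_ids, ["r1"])
        assert rc.extract_modules(Y, p)[0].members == []

    def test_gene_order_invariance_and_tie_break(self):
        genes = ["gb", "ga", "gc"]
        Y = make_Y([[0.5], [0.5], [0.9]], genes=genes, regs=["r1"])
        p = rc.PValueMatrix(np.full((3, 1), 0.01), genes, ["r1"])
        mods = rc.extract_modules(Y, p)
        assert mods[0].gene_ids == ["gc", "ga", "gb"]  # |Y| desc, id asc on tie
        perm = [2, 0, 1]
        Y2 = make_Y(Y.values[perm], genes=[genes[i] for i in perm], regs=["r1"])
        p2 = rc.PValueMatrix(p.values[perm], [genes[i] for i in perm], ["r1"])
        assert rc.extract_modules(Y2, p2)[0].gene_ids == mods[0].gene_ids

    def test_top_k_truncation(self):
        Y = make_Y(np.arange(1.0, 6.0)[:, None], regs=["r1"])
        p = rc.PValueMatrix(np.full((5, 1), 0.01), Y.gene_ids, ["r1"])
        mods = rc.extract_modules(Y, p, top_k=2)
        assert mods[0].gene_ids == ["g5", "g4"]


class TestOverlapSignificance:
    def test_complete_overlap_small_universe(self):
        A = {f"g{i}" for i in range(5)}
        p, r = rc.overlap_significance(A, A, 10)
        assert p == pytest.approx(1 / 252)  # 1 / C(10,5)
        assert r == pytest.approx(2.0)

    def test_ratio_at_expectation(self):
        A = {f"a{i}" for i in range(20)}
        B = {f"a{i}" for i in range(6)} | {f"b{i}" for i in range(24)}
        p, r = rc.overlap_significance(A, B, 100)
        assert r == pytest.approx(1.0)

    def test_ratio_double_expectation(self):
        A = {f"a{i}" for i in range(20)}
        B = {f"a{i}" for i in range(12)} | {f"b{i}" for i in range(18)}
        _, r = rc.overlap_significance(A, B, 100)
        assert r == pytest.approx(2.0)

    def test_universe_too_small(self):
        with pytest.raises(ValidationError):
            rc.overlap_significance({"a", "b"}, {"c"}, 2)

    @pytest.mark.parametrize(
        "universe, na, nb, k",
        [(8, 3, 4, 2), (10, 5, 5, 3), (12, 6, 4, 1), (12, 7, 7, 5), (9, 2, 8, 2)],
    )
    def test_agrees_with_exhaustive_enumeration(self, universe, na, nb, k):
        A = {f"u{i}" for i in range(na)}
        B = {f"u{i}" for i in range(na - k, na - k + nb)}
        assert len(A & B) == k
        p, _ = rc.overlap_significance(A, B, universe)
        assert p == pytest.approx(brute_force_overlap_tail(universe, na, nb, k),
                                  rel=1e-12)


class TestPermutationNull:
    def test_seed_determinism(self):
        X, C = random_problem(2, n=30, m=5, l=2, n_targets=5)
        cfg = rc.DecompositionConfig(seed=1, max_iters=50, restarts=1)
        a = rc.permutation_null(X, C, cfg, B=2, seed=99)
        b = rc.permutation_null(X, C, cfg, B=2, seed=99)
        for reg in C.regulator_ids:
            np.testing.assert_array_equal(
                a.per_regulator_null[reg], b.per_regulator_null[reg]
            )
        assert a.seeds == b.seeds

    def test_null_pool_sizes(self):
        X, C = random_problem(2, n=30, m=5, l=2, n_targets=5)
        cfg = rc.DecompositionConfig(seed=1, max_iters=20, restarts=1)
        null = rc.permutation_null(X, C, cfg, B=3, seed=0)
        for reg in C.regulator_ids:
            assert null.per_regulator_null[reg].size == 3 * X.n_genes

    def test_per_gene_mode(self):
        X, C = random_problem(2, n=25, m=5, l=2, n_targets=5)
        cfg = rc.DecompositionConfig(seed=1, max_iters=20, restarts=1)
        null = rc.permutation_null(X, C, cfg, B=4, seed=0, keep_per_gene=True)
        assert null.per_gene.shape == (4, 25, 2)
        res = rc.fit(X, C, cfg)
        p = rc.empirical_pvalues(res.Y, null, Z=res.Z, pool="per-gene")
        assert p.values.shape == (25, 2)
        assert (p.values >= 1 / 5).all() and (p.values <= 1).all()


class TestCallingPower:
    def test_true_targets_called_on_synthetic_signal(self):
        """On synthetic data with real regulator-target structure the
        contribution-score permutation test must call the bulk of the
        true targets at p < 0.05 with high precision."""
        d = rc.generate(rc.SyntheticParams(
            n_genes=300, n_samples=10, n_regulators=4, seed=11))
        sup = d.true_support()
        cfg = rc.DecompositionConfig(sparseness=0.8, seed=5, restarts=1,
                                     max_iters=500)
        res = rc.fit(d.X, d.C, cfg)
        null = rc.permutation_null(d.X, d.C, cfg, B=60, seed=9)
        p = rc.empirical_pvalues(res.Y, null, Z=res.Z)
        mods = rc.extract_modules(res.Y, p, p_cutoff=0.05)
        idx = {g: i for i, g in enumerate(res.Y.gene_ids)}
        called = sum(len(m.members) for m in mods)
        tp = sum(
            sup[idx[g], l] for l, m in enumerate(mods) for g in m.gene_ids
        )
        assert called > 0
        assert tp / called >= 0.9            # precision
        assert tp / sup.sum() >= 0.8         # recall


class TestCoTargets:
    def _mods(self):
        return [
            rc.RegulatoryModule("rela", [("g1", 1.0, 0.01, "over"),
                                         ("g2", 0.5, 0.02, "over")]),
            rc.RegulatoryModule("p53", [("g2", 0.8, 0.01, "under"),
                                        ("g3", 0.4, 0.03, "under")]),
        ]

    def test_shared_gene_flagged_for_both(self):
        df = rc.intersect_regulator_targets(self._mods())
        assert bool(df.loc["g2", "rela"]) and bool(df.loc["g2", "p53"])
        assert df.loc["g2", "n_regulators"] == 2
        assert df.loc["g1", "n_regulators"] == 1

    def test_group_union_semantics(self):
        df = rc.intersect_regulator_targets(
            self._mods(), {"nfkb": ["rela"]}
        )
        assert bool(df.loc["g1", "nfkb"])
        assert not bool(df.loc["g3", "nfkb"])

    def test_unknown_group_member(self):
        with pytest.raises(KeyError):
            rc.intersect_regulator_targets(self._mods(), {"x": ["nope"]})

    def test_disjoint_modules(self):
        mods = [
            rc.RegulatoryModule("a", [("g1", 1.0, 0.01, "over")]),
            rc.RegulatoryModule("b", [("g2", 1.0, 0.01, "over")]),
        ]
        df = rc.intersect_regulator_targets(mods)
        assert (df["n_regulators"] == 1).all()


def test_bh_adjustment_is_per_regulator_and_monotone():
    rng = np.random.default_rng(0)
    p = rc.PValueMatrix(rng.uniform(0.001, 1, (40, 2)),
                        [f"g{i}" for i in range(40)], ["r1", "r2"])
    adj = rc.bh_adjust(p)
    assert (adj.values >= p.values - 1e-12).all()
    assert (adj.values <= 1.0).all()
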