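import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icaqtl import (
    assign_module,
    fit_empirical_null,
    geneset_enrichment,
    hypergeom_tail,
    module_overlap,
)
from icaqtl.containers import GeneModule


def gene_ids(n):
    return [f"g{i}" for i in range(n)]


class TestEmpiricalNull:
    def test_standard_normal_recovered(self):
        # the truncated-window MLE of the null scale has sampling sd ~3%
        # at 1e4 points; check per-seed and in aggregate
        sigmas, centers, etas = [], [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fit = fit_empirical_null(rng.standard_normal(10_000))
            sigmas.append(fit.sigma0)
            centers.append(fit.center)
            etas.append(fit.eta0)
        assert max(abs(c) for c in centers) < 0.05
        assert all(abs(s - 1.0) < 0.10 for s in sigmas)
        assert np.mean(sigmas) == pytest.approx(1.0, abs=0.03)
        assert min(etas) >= 0.95

    def test_center_tracks_median(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10_000)
        assert fit_empirical_null(x + 5.0).center == pytest.approx(
            fit_empirical_null(x).center + 5.0, abs=1e-9
        )

    def test_robust_to_contaminating_tail(self):
        rng = np.random.default_rng(2)
        x = np.concatenate(
            [rng.standard_normal(9_500), rng.standard_normal(500) * 10.0]
        )
        fit = fit_empirical_null(x)
        assert fit.sigma0 == pytest.approx(1.0, rel=0.10)

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError, match="100"):
            fit_empirical_null(np.zeros(50))
        with pytest.raises(ValueError, match="degenerate"):
            fit_empirical_null(np.zeros(200))


class TestAssignModule:
    def test_null_loadings_give_near_empty_modules(self):
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(5000)
            fit = fit_empirical_null(x)
            sizes.append(assign_module(x, gene_ids(5000), fit).size)
        assert np.mean(sizes) <= 1.0

    def test_planted_block_recovered_exactly(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(5000)
        x[:50] = 8.0
        fit = fit_empirical_null(x)
        mod = assign_module(x, gene_ids(5000), fit)
        assert mod.members == set(gene_ids(50))

    def test_two_sided_and_affine_invariant(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(2000)
        x[:30] = 7.0
        x[30:60] = -7.0
        members = assign_module(x, gene_ids(2000), fit_empirical_null(x)).members
        neg = assign_module(-x, gene_ids(2000), fit_empirical_null(-x)).members
        scaled = assign_module(
            3.0 * x + 11.0, gene_ids(2000), fit_empirical_null(3.0 * x + 11.0)
        ).members
        assert members == neg == scaled
        assert set(gene_ids(60)) <= members

    def test_qvalues_monotone_in_abs_z(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(1000)
        x[:20] += 6.0
        fit = fit_empirical_null(x)
        mod = assign_module(x, gene_ids(1000), fit, fdr_max=1.1)  # keep everything
        z = np.abs(np.array(mod.loadings) - fit.center) / fit.sigma0
        order = np.argsort(z)
        q_sorted = np.array(mod.qvalues)[order]
        assert (np.diff(q_sorted) <= 1e-12).all()

    def test_null_p_rule_option(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(1000)
        x[0] = 50.0
        fit = fit_empirical_null(x)
        mod = assign_module(x, gene_ids(1000), fit, rule="null_p")
        assert "g0" in mod.members


class TestModuleOverlap:
    def make(self, genes):
        return GeneModule("c", list(genes), np.ones(len(genes)), np.zeros(len(genes)))

    def test_identity_disjoint_and_partial(self):
        a = self.make([f"g{i}" for i in range(1, 11)])
        b = self.make([f"g{i}" for i in range(6, 16)])
        assert module_overlap(a, a) == 1.0
        assert module_overlap(a, self.make(["x1", "x2"])) == 0.0
        assert module_overlap(a, b) == pytest.approx(5 / 15)

    def test_both_empty_is_zero(self):
        assert module_overlap(set(), set()) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
    )
    def test_bounds_and_symmetry(self, a, b):
        sa = {f"g{i}" for i in a}
        sb = {f"g{i}" for i in b}
        v = module_overlap(sa, sb)
        assert 0.0 <= v <= 1.0
        assert v == module_overlap(sb, sa)
        if sa == sb and sa:
            assert v == 1.0


def brute_force_hypergeom_tail(N, K, n, k):
    """Oracle: enumerate all size-n draws from a universe with K marked."""
    marked = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestEnrichment:
    def test_fully_overlapping_small_set(self):
        universe = gene_ids(20)
        sets = {"S": set(universe[:5])}
        mod = GeneModule("c", universe[:5], np.ones(5), np.zeros(5))
        df = geneset_enrichment(mod, sets, universe)
        assert df["p"].iloc[0] == pytest.approx(1 / math.comb(20, 5))

    def test_zero_overlap_p_one(self):
        universe = gene_ids(30)
        sets = {"S": set(universe[20:30])}
        mod = GeneModule("c", universe[:5], np.ones(5), np.zeros(5))
        assert geneset_enrichment(mod, sets, universe)["p"].iloc[0] == 1.0

    def test_matches_brute_force_enumeration(self):
        for N in (8, 10, 12):
            for K in (2, 4, N // 2):
                for n in (1, 3, 5):
                    for k in range(0, min(K, n) + 1):
                        assert hypergeom_tail(N, K, n, k) == pytest.approx(
                            brute_force_hypergeom_tail(N, K, n, k), abs=1e-12
                        )

    def test_min_set_excluded_from_family(self):
        universe = gene_ids(100)
        sets = {"big": set(universe[:10]), "tiny": set(universe[:2])}
        mod = GeneModule("c", universe[:5], np.ones(5), np.zeros(5))
        df = geneset_enrichment(mod, sets, universe, min_set=5)
        assert list(df["set"]) == ["big"]
        assert df["threshold"].iloc[0] == pytest.approx(0.05)

    def test_module_outside_universe_fails(self):
        mod = GeneModule("c", ["zz"], np.ones(1), np.zeros(1))
        with pytest.raises(ValueError, match="universe"):
            geneset_enrichment(mod, {"S": {"g0"}}, gene_ids(10))
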