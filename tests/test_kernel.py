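"""Running-sum kernel tests: closed forms, oracle agreement, null
distribution contracts, p/NES/FDR estimators, leading edge, determinism."""

import numpy as np
import pytest
from oracles import naive_running_es

import gseatk.kernel as kernel_mod
from gseatk.io_formats import GeneSet, GeneSetLibrary, RankedList
from gseatk.kernel import (
    EnrichmentParams,
    RunningSum,
    build_null,
    empirical_pvalue,
    fdr_qvalues,
    leading_edge,
    normalize_es,
    run_gsea,
    run_prerank,
    running_enrichment,
)
from gseatk.synthetic import PlantSpec, make_expression, make_library, make_ranked


def _random_instance(rng, n_max=100, m_max=20):
    n = int(rng.integers(4, n_max + 1))
    m = int(rng.integers(1, min(n - 1, m_max) + 1))
    scores = rng.normal(size=n)
    rl = RankedList([f"G{i:03d}" for i in range(n)], scores)
    members = list(rng.choice(rl.genes, size=m, replace=False))
    return rl, members


class TestRunningEnrichment:
    def test_unweighted_top2_of_4(self):
        rl = RankedList(["A", "B", "C", "D"], [4.0, 3.0, 2.0, 1.0])
        run = running_enrichment(rl, ["A", "B"], weight_exponent=0.0)
        np.testing.assert_allclose(run.curve, [0.5, 1.0, 0.5, 0.0])
        assert run.es == 1.0
        assert run.peak_position == 2

    def test_unweighted_bottom2_of_4(self):
        rl = RankedList(["A", "B", "C", "D"], [4.0, 3.0, 2.0, 1.0])
        run = running_enrichment(rl, ["C", "D"], weight_exponent=0.0)
        assert run.es == -1.0
        assert run.peak_position == 2

    def test_weight_zero_treats_zero_scores_as_one(self):
        rl = RankedList(["A", "B", "C"], [1.0, 0.0, -1.0])
        run = running_enrichment(rl, ["B"], weight_exponent=0.0)
        # member at position 2 contributes full weight despite score 0
        np.testing.assert_allclose(run.curve, [-0.5, 0.5, 0.0])

    def test_matches_naive_oracle_weighted(self, rng):
        for _ in range(100):
            rl, members = _random_instance(rng, n_max=50, m_max=8)
            for w in (0.0, 1.0, 1.5):
                run = running_enrichment(rl, members, w)
                curve, es, peak = naive_running_es(rl.genes, rl.scores, members, w)
                assert abs(run.es - es) <= 1e-12
                assert run.peak_position == peak
                np.testing.assert_allclose(run.curve, curve, atol=1e-12)

    def test_curve_ends_at_zero(self, rng):
        for _ in range(50):
            rl, members = _random_instance(rng)
            run = running_enrichment(rl, members, 1.0)
            assert abs(run.curve[-1]) < 1e-9
            assert -1.0 - 1e-12 <= run.es <= 1.0 + 1e-12

    def test_antisymmetry_negated_reversed_list(self, rng):
        for _ in range(50):
            rl, members = _random_instance(rng)
            neg = RankedList(rl.genes, -rl.scores)
            es_fwd = running_enrichment(rl, members, 1.0).es
            es_rev = running_enrichment(neg, members, 1.0).es
            assert es_fwd == pytest.approx(-es_rev, abs=1e-9)

    def test_empty_intersection_error(self):
        rl = RankedList(["A", "B", "C", "D"], [3.0, 2.0, 1.0, 0.5])
        with pytest.raises(ValueError, match="not represented"):
            running_enrichment(rl, ["X", "Y"])

    def test_full_coverage_error(self):
        rl = RankedList(["A", "B"], [1.0, 0.0])
        with pytest.raises(ValueError, match="every ranked gene"):
            running_enrichment(rl, ["A", "B"])

    def test_all_zero_member_scores_falls_back_uniform(self):
        rl = RankedList(["A", "B", "C", "D"], [1.0, 0.0, 0.0, -1.0])
        with pytest.warns(RuntimeWarning, match="uniform"):
            run = running_enrichment(rl, ["B", "C"], weight_exponent=1.0)
        np.testing.assert_allclose(run.curve, [-0.5, 0.0, 0.5, 0.0])


class TestBuildNull:
    def test_default_vector_length_is_1000(self):
        rl = RankedList([f"G{i}" for i in range(60)], np.linspace(3, -3, 60))
        lib = GeneSetLibrary([GeneSet("S", "", tuple(f"G{i}" for i in range(0, 40, 2)))])
        null = build_null(rl, lib, EnrichmentParams(seed=1))
        assert null.per_set_es["S"].shape == (1000,)

    def test_same_seed_reproduces_bit_for_bit(self, rng):
        rl, members = _random_instance(rng, n_max=80, m_max=15)
        lib = GeneSetLibrary([GeneSet("S", "", tuple(members))])
        params = EnrichmentParams(n_permutations=200, seed=7)
        a = build_null(rl, lib, params).per_set_es["S"]
        b = build_null(rl, lib, params).per_set_es["S"]
        assert np.array_equal(a, b)

    def test_null_invariant_to_library_order(self, rng):
        rl, _ = _random_instance(rng, n_max=80, m_max=15)
        sets = [
            GeneSet(name, "", tuple(rng.choice(rl.genes, size=10, replace=False)))
            for name in ("S1", "S2", "S3")
        ]
        params = EnrichmentParams(n_permutations=100, seed=3)
        fwd = build_null(rl, GeneSetLibrary(sets), params)
        rev = build_null(rl, GeneSetLibrary(sets[::-1]), params)
        for name in ("S1", "S2", "S3"):
            assert np.array_equal(fwd.per_set_es[name], rev.per_set_es[name])

    def test_gene_set_null_mean_matches_subset_simulation(self):
        # independent Monte-Carlo oracle: ES of random same-size subsets
        # against i.i.d. standard-normal scores, coded from the definition
        rng = np.random.default_rng(99)
        n, m = 200, 20
        scores = np.sort(rng.standard_normal(n))[::-1]
        rl = RankedList([f"G{i:03d}" for i in range(n)], scores)
        oracle = []
        for _ in range(10_000):
            members = rng.choice(rl.genes, size=m, replace=False)
            _, es, _ = naive_running_es(rl.genes, rl.scores, members, 1.0)
            oracle.append(es)
        oracle = np.asarray(oracle)
        lib = GeneSetLibrary([GeneSet("S", "", tuple(rl.genes[:m]))])
        null = build_null(rl, lib, EnrichmentParams(n_permutations=1000, seed=5))
        kernel_mean = null.per_set_es["S"].mean()
        se = oracle.std(ddof=1) * np.sqrt(1 / 1000 + 1 / 10_000)
        assert abs(kernel_mean - oracle.mean()) < 3 * se

    def test_phenotype_null_preserves_class_sizes(self, monkeypatch):
        spec = PlantSpec(universe_size=80, n_sets=3, set_size_range=(10, 20),
                         effect_size=0.0, n_samples_per_class=5, seed=11)
        lib = make_library(spec)
        dataset, _ = make_expression(spec, lib)
        seen = []
        real = kernel_mod.metric_scores

        def spy(matrix, mask_a, spec_):
            seen.append(int(mask_a.sum()))
            return real(matrix, mask_a, spec_)

        monkeypatch.setattr(kernel_mod, "metric_scores", spy)
        params = EnrichmentParams(n_permutations=25, permutation_type="phenotype",
                                  min_set_size=1, seed=2)
        build_null(dataset, lib, params)
        assert seen and all(s == 5 for s in seen)

    def test_phenotype_mode_requires_phenotypes(self, rng):
        rl, members = _random_instance(rng)
        lib = GeneSetLibrary([GeneSet("S", "", tuple(members))])
        with pytest.raises(ValueError, match="phenotype"):
            build_null(rl, lib, EnrichmentParams(permutation_type="phenotype"))


class TestEmpiricalPvalue:
    def test_all_null_below_observed(self, rng):
        null = rng.uniform(0.01, 0.79, size=100)  # 100 positive values < 0.8
        assert empirical_pvalue(0.8, null) == pytest.approx(1 / 101)

    def test_tie_counts_as_greater_equal(self, rng):
        null = np.concatenate([rng.uniform(0.01, 0.79, size=99), [0.8]])
        assert empirical_pvalue(0.8, null) == pytest.approx(2 / 101)

    def test_es_zero_gives_p_one(self):
        assert empirical_pvalue(0.0, np.array([0.1, -0.2])) == 1.0

    def test_empty_same_sign_null_gives_p_one(self):
        assert empirical_pvalue(0.5, np.array([-0.1, -0.2])) == 1.0

    def test_negative_es_uses_negative_tail(self):
        null = np.array([-0.9, -0.1, 0.5, 0.7])
        # S = {-0.9, -0.1}; |x| >= 0.8 only for -0.9
        assert empirical_pvalue(-0.8, null) == pytest.approx(2 / 3)


class TestNormalizeEs:
    def test_positive_closed_form(self):
        null = np.array([0.3, 0.3, 0.3, -0.5])
        assert normalize_es(0.6, null) == pytest.approx(2.0)

    def test_negative_closed_form(self):
        null = np.array([-0.2, -0.2, 0.9])
        assert normalize_es(-0.4, null) == pytest.approx(-2.0)

    def test_self_normalization_identity(self, rng):
        null = rng.normal(scale=0.3, size=5000)
        pos = null[null > 0]
        nes = np.array([normalize_es(float(x), null) for x in pos])
        assert nes.mean() == pytest.approx(1.0, abs=1e-12)

    def test_no_same_sign_null_gives_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert np.isnan(normalize_es(0.5, np.array([-0.4, -0.2])))


class TestFdrQvalues:
    def test_direct_evaluation_of_ratio(self):
        null = np.array([1.0, 2.0, 3.0, 4.0])
        qs = fdr_qvalues(np.array([2.5, 3.5]), null)
        # raw q(3.5) = (1/4)/(1/2) = 0.5 ; raw q(2.5) = (2/4)/(2/2) = 0.5
        np.testing.assert_allclose(qs, [0.5, 0.5])

    def test_observed_less_extreme_than_all_null_clips_to_one(self):
        assert fdr_qvalues(np.array([0.5]), np.array([1.0, 2.0, 3.0]))[0] == 1.0

    def test_all_null_less_extreme_gives_zero(self):
        qs = fdr_qvalues(np.array([5.0, 6.0]), np.array([1.0, 2.0]))
        np.testing.assert_array_equal(qs, [0.0, 0.0])

    def test_monotone_in_extremity(self, rng):
        obs = rng.normal(size=40) * 2
        null = rng.normal(size=4000)
        qs = fdr_qvalues(obs, null)
        pos = obs >= 0
        order = np.argsort(-obs[pos])
        assert np.all(np.diff(qs[pos][order]) >= 0)
        neg = ~pos
        order = np.argsort(obs[neg])
        assert np.all(np.diff(qs[neg][order]) >= 0)

    def test_negative_side_mirrors_positive(self):
        qs = fdr_qvalues(np.array([-2.5, -3.5]), np.array([-1.0, -2.0, -3.0, -4.0]))
        np.testing.assert_allclose(qs, [0.5, 0.5])


class TestLeadingEdge:
    def _running(self, es, peak, hits):
        return RunningSum(curve=np.zeros(10), hit_positions=np.asarray(hits),
                          es=es, peak_position=peak)

    def test_positive_es_members_at_or_before_peak(self):
        rl = RankedList([f"G{i}" for i in range(10)], np.linspace(5, -4, 10))
        genes = leading_edge(self._running(0.5, 5, [2, 5, 9]), rl)
        assert genes == (rl.genes[1], rl.genes[4])

    def test_negative_es_members_at_or_after_peak(self):
        rl = RankedList([f"G{i}" for i in range(10)], np.linspace(5, -4, 10))
        genes = leading_edge(self._running(-0.5, 5, [2, 5, 9]), rl)
        assert genes == (rl.genes[4], rl.genes[8])

    def test_all_hits_before_positive_peak(self):
        rl = RankedList([f"G{i}" for i in range(10)], np.linspace(5, -4, 10))
        genes = leading_edge(self._running(0.7, 9, [1, 2, 3]), rl)
        assert genes == (rl.genes[0], rl.genes[1], rl.genes[2])


class TestRunPrerank:
    def test_small_set_skipped_not_scored(self, rng):
        rl = RankedList([f"G{i:02d}" for i in range(60)], rng.normal(size=60))
        lib = GeneSetLibrary([
            GeneSet("TINY", "", tuple(rl.genes[:3])),
            GeneSet("OK", "", tuple(rng.choice(rl.genes, size=20, replace=False))),
        ])
        res = run_prerank(rl, lib, EnrichmentParams(n_permutations=50, seed=1))
        assert [r.set_name for r in res.records] == ["OK"]
        assert len(res.skipped) == 1 and res.skipped[0][0] == "TINY"

    def test_all_sets_filtered_is_error(self, rng):
        rl = RankedList([f"G{i:02d}" for i in range(30)], rng.normal(size=30))
        lib = GeneSetLibrary([GeneSet("TINY", "", tuple(rl.genes[:3]))])
        with pytest.raises(ValueError, match="min_set_size"):
            run_prerank(rl, lib, EnrichmentParams(n_permutations=10))

    def test_same_seed_identical_results(self, rng):
        spec = PlantSpec(universe_size=300, n_sets=8, set_size_range=(15, 30),
                         effect_size=1.0, seed=4)
        lib = make_library(spec)
        rl = make_ranked(spec, lib)
        params = EnrichmentParams(n_permutations=100, seed=9)
        r1 = run_prerank(rl, lib, params)
        r2 = run_prerank(rl, lib, params)
        assert r1.to_frame().equals(r2.to_frame())

    def test_record_invariants(self, rng):
        spec = PlantSpec(universe_size=300, n_sets=8, effect_size=1.5, seed=6)
        lib = make_library(spec)
        rl = make_ranked(spec, lib)
        res = run_prerank(rl, lib, EnrichmentParams(n_permutations=100, seed=2))
        for rec in res.records:
            assert -1 - 1e-12 <= rec.es <= 1 + 1e-12
            if np.isfinite(rec.nes) and rec.nes != 0:
                assert np.sign(rec.nes) == np.sign(rec.es)
            assert 0 < rec.p_empirical <= 1
            assert 0 <= rec.fdr_q <= 1
            member_and_ranked = set(lib[rec.set_name].members) & set(rl.genes)
            assert set(rec.leading_edge) <= member_and_ranked


class TestRunGsea:
    def test_planted_set_recovered_with_phenotype_null(self):
        hits_top, hits_q = 0, 0
        n_rep = 6
        for rep in range(n_rep):
            spec = PlantSpec(universe_size=500, n_sets=12, set_size_range=(15, 40),
                             planted_set_size=25, effect_size=1.0,
                             n_samples_per_class=10, seed=100 + rep)
            lib = make_library(spec)
            dataset, _ = make_expression(spec, lib)
            params = EnrichmentParams(n_permutations=200,
                                      permutation_type="phenotype", seed=rep)
            res = run_gsea(dataset, lib, params)
            frame = res.to_frame()
            if frame.iloc[0]["Term"] == "SET0000":
                hits_top += 1
            if res["SET0000"].fdr_q < 0.05:
                hits_q += 1
        assert hits_top >= n_rep - 1
        assert hits_q >= n_rep - 1

    def test_gene_set_mode_delegates_to_prerank_null(self):
        spec = PlantSpec(universe_size=300, n_sets=6, effect_size=1.0, seed=3)
        lib = make_library(spec)
        dataset, _ = make_expression(spec, lib)
        params = EnrichmentParams(n_permutations=50, permutation_type="gene_set",
                                  seed=1)
        res = run_gsea(dataset, lib, params)
        assert res.null.permutation_type == "gene_set"
        assert len(res.records) > 0


class TestCrossCheckGseapy:
    """Agreement with an independently developed implementation."""

    def test_prerank_es_matches_gseapy(self, rng):
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        n = 400
        scores = rng.normal(size=n)
        rl = RankedList([f"G{i:04d}" for i in range(n)], scores)
        sets = {f"S{k}": list(rng.choice(rl.genes, 25, replace=False))
                for k in range(6)}
        res = gseapy.prerank(
            rnk=pd.Series(rl.scores, index=rl.genes), gene_sets=sets,
            permutation_num=10, outdir=None, seed=1, min_size=5, max_size=100,
            weight=1.0, threads=1,
        )
        for name, es in res.res2d.set_index("Term")["ES"].items():
            ours = running_enrichment(rl, sets[name], 1.0).es
            assert abs(float(es) - ours) <= 1e-12
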