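import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coexmap import (
    CorrelationTable,
    SyntheticSpec,
    benjamini_hochberg,
    build_correlation_table,
    gene_scan_for_set,
    generate_expression_condition,
    generate_gene_sets,
    module_genes,
    pathway_scan,
    permutation_null,
    rank_by_correlation,
    running_score,
    set_p_value,
)
from coexmap.enrichment import RankedList, _es_at_sorted_positions, _weights
from coexmap.errors import DegenerateInputError


def brute_force_running_sum(features, scores, members, weight_exponent=1.0):
    """Plain prefix loop over the ranked list; independent of the package path."""
    members = set(members)
    n = len(features)
    nh = sum(f in members for f in features)
    tot_w = sum(abs(s) ** weight_exponent for f, s in zip(features, scores)
                if f in members)
    cum_hit = cum_miss = 0.0
    values = []
    for f, s in zip(features, scores):
        if f in members:
            cum_hit += 1.0 / nh if tot_w == 0 else abs(s) ** weight_exponent / tot_w
        else:
            cum_miss += 1.0 / (n - nh)
        values.append(cum_hit - cum_miss)
    return max(values), min(values), values


def _ranked(scores, features=None):
    n = len(scores)
    features = features or [f"g{i:03d}" for i in range(n)]
    return RankedList(np.array(features, dtype=object), np.asarray(scores, float))


class TestRankByCorrelation:
    def test_sorted_table_order_preserved(self):
        frame = pd.DataFrame({"feature": ["a", "b", "c"], "r": [0.9, 0.5, -0.2],
                              "p": 0.1, "n": 10})
        t = CorrelationTable("T", frame, "unsorted")
        ranked = rank_by_correlation(t, "r_desc")
        assert list(ranked.features) == ["a", "b", "c"]

    def test_abs_direction_reorders(self):
        frame = pd.DataFrame({"feature": ["a", "b", "c"], "r": [0.5, -0.9, 0.2],
                              "p": 0.1, "n": 10})
        t = CorrelationTable("T", frame, "unsorted")
        assert list(rank_by_correlation(t, "abs_r_desc").features) == ["b", "a", "c"]

    def test_deterministic_across_runs(self, small_spec):
        m = generate_expression_condition(small_spec, "normal")
        t = build_correlation_table(m, small_spec.target_gene, sort="unsorted")
        a = rank_by_correlation(t)
        b = rank_by_correlation(t)
        assert list(a.features) == list(b.features)


class TestRunningScore:
    def test_all_hits_on_top_gives_es_one(self, rng):
        scores = np.sort(rng.uniform(0.1, 1, 20))[::-1]
        ranked = _ranked(scores)
        for w in (0.0, 1.0):
            sc = running_score(ranked, set(ranked.features[:5]), weight_exponent=w)
            assert sc.es == pytest.approx(1.0)

    def test_all_hits_at_bottom_gives_es_zero(self, rng):
        scores = np.sort(rng.uniform(0.1, 1, 20))[::-1]
        ranked = _ranked(scores)
        sc = running_score(ranked, set(ranked.features[-5:]), weight_exponent=0.0)
        assert sc.es == pytest.approx(0.0, abs=1e-12)
        assert sc.min_deficit == pytest.approx(-1.0)

    def test_running_sum_ends_at_zero(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            scores = rng.uniform(-1, 1, n)
            ranked = _ranked(np.sort(scores)[::-1])
            k = int(rng.integers(1, n))
            members = set(rng.choice(ranked.features, size=k, replace=False))
            for w in (0.0, 1.0, 2.0):
                sc = running_score(ranked, members, weight_exponent=w)
                assert sc.values[-1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 51))
            scores = np.sort(rng.uniform(-1, 1, n))[::-1]
            ranked = _ranked(scores)
            k = int(rng.integers(1, n))
            members = set(rng.choice(ranked.features, size=k, replace=False))
            w = float(rng.choice([0.0, 1.0]))
            sc = running_score(ranked, members, weight_exponent=w)
            es, mn, vals = brute_force_running_sum(
                ranked.features, ranked.scores, members, w
            )
            assert sc.es == pytest.approx(es, abs=1e-12)
            assert sc.min_deficit == pytest.approx(mn, abs=1e-12)

    def test_empty_and_full_sets_raise(self):
        ranked = _ranked([0.5, 0.4, 0.3])
        with pytest.raises(DegenerateInputError):
            running_score(ranked, {"absent"})
        with pytest.raises(DegenerateInputError):
            running_score(ranked, set(ranked.features))

    def test_fast_hit_position_path_agrees_with_full_path(self, rng):
        # the permutation helper evaluates ES only at hit positions
        for _ in range(100):
            n = int(rng.integers(10, 80))
            scores = np.sort(rng.uniform(-1, 1, n))[::-1]
            ranked = _ranked(scores)
            nh = int(rng.integers(1, n))
            pos = np.sort(rng.choice(n, size=nh, replace=False))
            members = set(ranked.features[pos])
            sc = running_score(ranked, members, weight_exponent=1.0)
            fast = _es_at_sorted_positions(
                pos[None, :], _weights(ranked.scores, 1.0), n, nh
            )[0]
            assert fast == pytest.approx(sc.es, abs=1e-12)


class TestPermutationNull:
    def test_same_seed_same_null(self, rng):
        ranked = _ranked(np.sort(rng.uniform(-1, 1, 100))[::-1])
        m1, s1, v1 = permutation_null(ranked, 10, n_perm=50, seed=5)
        m2, s2, v2 = permutation_null(ranked, 10, n_perm=50, seed=5)
        assert m1 == m2 and s1 == s2
        np.testing.assert_array_equal(v1, v2)

    def test_null_mean_strictly_positive(self, rng):
        # ES is the max of a walk ending at zero, so its mean is positive
        for _ in range(100):
            n = int(rng.integers(10, 120))
            ranked = _ranked(np.sort(rng.uniform(-1, 1, n))[::-1])
            nh = int(rng.integers(1, n))
            mean, _, _ = permutation_null(ranked, nh, n_perm=30, seed=rng)
            assert mean > 0

    def test_nearly_saturated_boundary_smoke(self, rng):
        # nh = N-1: a single miss per draw; the null must stay well defined
        ranked = _ranked(np.sort(rng.uniform(0.1, 1, 30))[::-1])
        mean, sd, samples = permutation_null(ranked, 29, n_perm=100, seed=0)
        assert 0 < mean <= 1 and sd >= 0
        assert ((samples >= 0) & (samples <= 1)).all()

    def test_restricted_pool_draws_stay_in_pool(self, rng):
        ranked = _ranked(np.sort(rng.uniform(-1, 1, 50))[::-1])
        pool = np.arange(30, 50)
        # with all hits confined to the bottom 20 ranks, ES stays small
        mean, _, samples = permutation_null(ranked, 5, n_perm=200, seed=1,
                                            pool_positions=pool)
        assert samples.max() <= 1.0 and mean < 0.5


class TestSetPValue:
    def test_es_at_null_mean_gives_half(self):
        assert set_p_value(0.3, 0.3, 0.1) == pytest.approx(0.5)

    def test_empirical_floor_when_es_beats_all(self):
        nulls = np.linspace(0, 0.5, 200)
        p = set_p_value(0.9, 0.2, 0.1, "empirical", nulls)
        assert p == pytest.approx(1 / 201)

    def test_degenerate_null_raises(self):
        with pytest.raises(DegenerateInputError):
            set_p_value(0.5, 0.3, 0.0)

    def test_modes_agree_for_moderate_z_on_gaussian_null(self, rng):
        nulls = rng.normal(0.3, 0.05, size=4000)
        for es in (0.32, 0.36, 0.40):
            pn = set_p_value(es, nulls.mean(), nulls.std(ddof=1))
            pe = set_p_value(es, nulls.mean(), nulls.std(ddof=1), "empirical", nulls)
            assert abs(pn - pe) < 0.02


class TestBenjaminiHochberg:
    @staticmethod
    def bh_oracle(p):
        """Independent step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q[i] = min(running, 1.0)
        return q

    def test_matches_independent_step_up_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(benjamini_hochberg(p), self.bh_oracle(p),
                                       atol=1e-12)

    def test_q_dominates_p_and_single_p_unchanged(self, rng):
        p = rng.uniform(size=25)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        assert benjamini_hochberg([0.037])[0] == pytest.approx(0.037)


class TestScans:
    def test_planted_set_ranks_first_on_normal_data(self):
        spec = SyntheticSpec(seed=29)
        m = generate_expression_condition(spec, "normal")
        table = build_correlation_table(m, spec.target_gene)
        sets = generate_gene_sets(spec)
        out = pathway_scan(table, sets, n_perm=200, seed=2)
        assert out.iloc[0]["set_id"] == spec.planted_set_id
        assert len(out) <= len(sets)

    def test_scan_q_is_bh_of_scan_p(self):
        spec = SyntheticSpec(seed=30, n_genes=400, n_chromosomes=2,
                             cis_block_size=0, n_decoy_sets=15)
        m = generate_expression_condition(spec, "normal")
        table = build_correlation_table(m, spec.target_gene)
        out = pathway_scan(table, generate_gene_sets(spec), n_perm=100, seed=4)
        np.testing.assert_allclose(
            out["q"], TestBenjaminiHochberg.bh_oracle(out["p"]), atol=1e-12
        )

    def test_empirical_p_uniform_under_no_signal(self, rng):
        # random member sets on a null ranking: empirical p is uniform
        ranked_scores = np.sort(rng.uniform(-0.3, 0.3, 300))[::-1]
        ps = []
        for _ in range(200):
            perm = rng.permutation(300)
            ranked = _ranked(ranked_scores)
            members = set(ranked.features[perm[:15]])
            sc = running_score(ranked, members)
            m, s, samp = permutation_null(ranked, 15, n_perm=200, seed=rng)
            ps.append(set_p_value(sc.es, m, s, "empirical", samp))
        stat = stats.kstest(ps, "uniform").statistic
        # add-one discreteness keeps D modest at n_perm=200
        assert stat < 0.12

    def test_gene_scan_member_probes_beat_random_probes(self):
        spec = SyntheticSpec(seed=33, n_genes=400, n_chromosomes=2,
                             cis_block_size=0)
        m = generate_expression_condition(spec, "normal")
        members = {spec.target_gene, *module_genes(spec)}
        others = [g for g in m.feature_ids if g not in members][:9]
        out = gene_scan_for_set(m, members, [*module_genes(spec), *others],
                                n_perm=100, seed=6)
        es = out.set_index("probe")["es"]
        assert (np.median(es[module_genes(spec)])
                > np.median(es[others]))

    def test_gene_scan_single_probe_q_equals_p(self, small_spec):
        m = generate_expression_condition(small_spec, "normal")
        members = set(module_genes(small_spec))
        out = gene_scan_for_set(m, members, [small_spec.target_gene],
                                n_perm=100, seed=1)
        assert out.iloc[0]["q"] == pytest.approx(out.iloc[0]["p"])

    def test_gene_scan_deterministic_under_fixed_seed(self, small_spec):
        m = generate_expression_condition(small_spec, "normal")
        members = set(module_genes(small_spec))
        a = gene_scan_for_set(m, members, [small_spec.target_gene], n_perm=50, seed=9)
        b = gene_scan_for_set(m, members, [small_spec.target_gene], n_perm=50, seed=9)
        pd.testing.assert_frame_equal(a, b)
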