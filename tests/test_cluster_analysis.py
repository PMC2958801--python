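import numpy as np
import pytest
from scipy import stats

from trustmix.cluster_analysis import (
    MembershipProfile,
    adjusted_rand,
    classify_new,
    cluster_profiles,
    membership_profiles,
    overrep_table,
    overrep_test,
    overrep_z,
    severity_correlation,
)
from trustmix.design import build_design


def _profile(dyad_id, freqs):
    freqs = np.asarray(freqs, float)
    return MembershipProfile(dyad_id, freqs, int(freqs.argmax()))


class TestMembershipProfiles:
    def test_matches_brute_force_counting(self, fitted_chain):
        chain, _, records = fitted_chain
        profiles = membership_profiles(chain, [r.dyad_id for r in records])
        K = chain.spec.K
        for n in (0, 17, 100, 286):
            counts = np.bincount(chain.z[:, n], minlength=K)
            np.testing.assert_allclose(
                profiles[n].frequencies, counts / counts.sum()
            )
            assert profiles[n].modal == counts.argmax()

    def test_frequencies_sum_to_one(self, fitted_chain):
        chain, _, records = fitted_chain
        for p in membership_profiles(chain):
            assert abs(p.frequencies.sum() - 1.0) < 1e-12

    def test_modal_tie_breaks_low(self):
        p = _profile("d", [0.4, 0.4, 0.2])
        assert p.modal == 0


class TestClassifyNew:
    def test_k1_always_cluster_one(self, small_population):
        from trustmix.design import ModelSpec, build_designs
        from trustmix.mixture_gibbs import run_chain

        cfg, records = small_population
        spec = ModelSpec(K=1, P=1, D=2)
        data = build_designs(records, spec)
        chain = run_chain(data, spec, n_draws=50, burn_in=20, seed=0)
        prof = classify_new(data[0], chain, seed=1)
        np.testing.assert_array_equal(prof.frequencies, [1.0])
        assert prof.modal == 0

    def test_same_seed_identical(self, fitted_chain):
        chain, data, _ = fitted_chain
        a = classify_new(data[5], chain, seed=42)
        b = classify_new(data[5], chain, seed=42)
        np.testing.assert_array_equal(a.frequencies, b.frequencies)

    def test_consistent_with_training_membership(self, fitted_chain):
        # reclassifying a training dyad reproduces its membership profile
        # up to resampling noise
        chain, data, records = fitted_chain
        profiles = membership_profiles(chain, [r.dyad_id for r in records])
        strong = [n for n, p in enumerate(profiles)
                  if p.frequencies.max() > 0.99][:10]
        assert strong, "expected some decisively assigned dyads"
        for n in strong:
            prof = classify_new(data[n], chain, seed=n)
            assert prof.modal == profiles[n].modal

    def test_dimension_mismatch_rejected(self, fitted_chain):
        chain, _, records = fitted_chain
        from trustmix.design import ModelSpec

        wrong = build_design(records[0], ModelSpec(K=1, P=2, D=2))
        with pytest.raises(ValueError, match="columns"):
            classify_new(wrong, chain)


class TestOverrepZ:
    @pytest.mark.parametrize("n_c,n_gc,p_g,expected", [
        (100, 20, 0.2, 0.0),
        (100, 30, 0.2, 2.5),            # (30-20)/sqrt(16)
        (50, 0, 0.5, -50 * 0.5 / np.sqrt(12.5)),  # -7.071...
    ])
    def test_direct_formula(self, n_c, n_gc, p_g, expected):
        assert overrep_z(n_c, n_gc, p_g) == pytest.approx(expected)

    @pytest.mark.parametrize("p_g", [0.0, 1.0])
    def test_degenerate_share_rejected(self, p_g):
        with pytest.raises(ValueError):
            overrep_z(10, 5, p_g)

    def test_complement_antisymmetry(self):
        # swapping the group for its complement flips the sign
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_c = int(rng.integers(5, 200))
            n_gc = int(rng.integers(0, n_c + 1))
            p_g = float(rng.uniform(0.05, 0.95))
            z = overrep_z(n_c, n_gc, p_g)
            z_c = overrep_z(n_c, n_c - n_gc, 1.0 - p_g)
            assert z == pytest.approx(-z_c)


class TestOverrepTest:
    def test_null_zeros(self):
        out = overrep_test([0.0, 0.0, 0.0, 0.0])
        assert out["chi2"] == 0.0 and not out["significant"]
        assert out["df"] == 4

    def test_per_term_threshold_k4(self):
        out = overrep_test([0.0] * 4)
        assert out["per_term_threshold"] == pytest.approx(1.5401, abs=1e-3)
        assert round(out["per_term_threshold"], 1) == 1.5

    def test_single_large_term_significant(self):
        out = overrep_test([3.1, 0.0, 0.0, 0.0])
        assert out["significant"]          # 3.1^2 = 9.61 > 9.488
        assert out["single_term_threshold"] == pytest.approx(
            np.sqrt(stats.chi2.ppf(0.95, 4))
        )
        assert not overrep_test([3.0, 0.0, 0.0, 0.0])["significant"]

    def test_k1_reduces_to_squared_z(self):
        z = 1.7
        out = overrep_test([z])
        assert out["chi2"] == pytest.approx(z**2)
        assert out["p"] == pytest.approx(stats.chi2.sf(z**2, 1))


class TestOverrepTable:
    def _toy(self):
        # 8 dyads, 2 clusters, 2 groups; counts known by hand
        profiles = [
            _profile("a1", [1, 0]), _profile("a2", [1, 0]),
            _profile("a3", [1, 0]), _profile("b1", [1, 0]),
            _profile("a4", [0, 1]), _profile("b2", [0, 1]),
            _profile("b3", [0, 1]), _profile("b4", [0, 1]),
        ]
        groups = {p.dyad_id: p.dyad_id[0].upper() for p in profiles}
        return profiles, groups

    def test_hand_computed_z(self):
        profiles, groups = self._toy()
        table = overrep_table(profiles, groups)
        # cluster 1: n_c=4, A members 3, p_A=0.5 -> z = (3-2)/1 = 1
        cell = table.cells.query("group == 'A' and cluster == 1").iloc[0]
        assert cell["n_c"] == 4 and cell["n_gc"] == 3
        assert cell["z"] == pytest.approx(1.0)
        cell = table.cells.query("group == 'B' and cluster == 2").iloc[0]
        assert cell["z"] == pytest.approx(1.0)

    def test_count_conservation(self, fitted_chain):
        chain, _, records = fitted_chain
        profiles = membership_profiles(chain, [r.dyad_id for r in records])
        table = overrep_table(profiles,
                              {r.dyad_id: r.group for r in records})
        # per cluster, group counts sum to the cluster size
        for c, sub in table.cells.groupby("cluster"):
            assert sub["n_gc"].sum() == sub["n_c"].iloc[0]
        # per group, counts over clusters sum to the group size
        for g, sub in table.cells.groupby("group"):
            n_g = sum(r.group == g for r in records)
            assert sub["n_gc"].sum() == n_g

    def test_single_group_flagged_inapplicable(self):
        profiles = [_profile(f"d{i}", [1, 0]) for i in range(4)]
        groups = {p.dyad_id: "Healthy" for p in profiles}
        with pytest.warns(UserWarning, match="untestable"):
            table = overrep_table(profiles, groups)
        assert not table.group_tests["applicable"].iloc[0]

    def test_missing_group_raises(self):
        profiles = [_profile("d0", [1, 0])]
        with pytest.raises(KeyError):
            overrep_table(profiles, {})

    def test_enriched_group_detected(self, fitted_chain):
        # generator enriches ADHD threefold in one cluster; the fitted
        # partition should show z above the printed 1.5 calibration
        chain, _, records = fitted_chain
        profiles = membership_profiles(chain, [r.dyad_id for r in records])
        table = overrep_table(profiles,
                              {r.dyad_id: r.group for r in records})
        adhd = table.cells.query("group == 'ADHD'")
        assert adhd["z"].max() > 1.54


class TestSeverityCorrelation:
    def test_perfectly_proportional_scores(self):
        profiles = [_profile(f"d{i}", [f, 1 - f])
                    for i, f in enumerate([0.55, 0.7, 0.9, 0.8])]
        scores = {f"d{i}": 10 * f
                  for i, f in enumerate([0.55, 0.7, 0.9, 0.8])}
        r, p, n = severity_correlation(profiles, scores, cluster=0)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_hand_computed_r(self):
        freqs = [0.2, 0.5, 0.9]
        scores = [6.0, 4.0, 5.0]
        profiles = [_profile(f"d{i}", [f, 1 - f])
                    for i, f in enumerate(freqs)]
        r, p, n = severity_correlation(
            profiles, {f"d{i}": s for i, s in enumerate(scores)},
            cluster=0, restrict_to_modal=False,
        )
        expected, _ = stats.pearsonr(freqs, scores)
        assert r == pytest.approx(expected)

    def test_restriction_to_modal_members(self):
        profiles = [
            _profile("in1", [0.9, 0.1]), _profile("in2", [0.7, 0.3]),
            _profile("in3", [0.6, 0.4]), _profile("out", [0.2, 0.8]),
        ]
        scores = {"in1": 3.0, "in2": 2.0, "in3": 1.0, "out": 99.0}
        r, p, n = severity_correlation(profiles, scores, cluster=0)
        assert n == 3  # "out" excluded

    def test_constant_scores_raise(self):
        profiles = [_profile(f"d{i}", [f, 1 - f])
                    for i, f in enumerate([0.6, 0.7, 0.8])]
        with pytest.raises(ValueError, match="variance"):
            severity_correlation(
                profiles, {f"d{i}": 5.0 for i in range(3)}, cluster=0,
                restrict_to_modal=False,
            )

    def test_recovers_generator_link(self, fitted_chain):
        # ASD severity was generated higher inside the enriched cluster, so
        # membership frequency and score correlate positively
        chain, _, records = fitted_chain
        profiles = membership_profiles(chain, [r.dyad_id for r in records])
        table = overrep_table(profiles,
                              {r.dyad_id: r.group for r in records})
        asd_cluster = int(
            table.cells.query("group == 'ASD'")
            .sort_values("z")["cluster"].iloc[-1] - 1
        )
        scores = {r.dyad_id: r.severity["ADI-R-repetitive"]
                  for r in records if r.group == "ASD" and r.severity}
        asd_ids = set(scores)
        asd_profiles = [p for p in profiles if p.dyad_id in asd_ids]
        r, p, n = severity_correlation(
            asd_profiles, scores, cluster=asd_cluster,
            restrict_to_modal=False,
        )
        assert r > 0.3 and p < 0.05


class TestClusterProfiles:
    def test_member_counts_sum(self, fitted_chain):
        chain, _, records = fitted_chain
        profiles = cluster_profiles(chain, records)
        assert sum(p.n_members for p in profiles) == len(records)

    def test_identical_members_mean_is_common_trajectory(self):
        from trustmix.design import ModelSpec, build_designs
        from trustmix.game_core import DyadRecord
        from trustmix.mixture_gibbs import run_chain

        inv = np.linspace(0.3, 0.7, 10)
        rep = np.full(10, 0.5)
        records = [DyadRecord(f"d{i}", "Healthy", inv.copy(), rep.copy())
                   for i in range(6)]
        spec = ModelSpec(K=1, P=1, D=2)
        chain = run_chain(build_designs(records, spec), spec, n_draws=40,
                          burn_in=10, seed=0)
        prof = cluster_profiles(chain, records)[0]
        np.testing.assert_allclose(prof.mean_investments, inv)
        np.testing.assert_allclose(prof.mean_repayments, rep)

    def test_mean_beta_near_generating_values(self, fitted_chain):
        chain, _, records = fitted_chain
        from trustmix.synthetic_data import DEFAULT_BETAS

        profiles = cluster_profiles(chain, records)
        # match fitted clusters to generating clusters by modal overlap
        truth = np.array([r.true_cluster for r in records])
        member_modal = {p.cluster: p for p in profiles}
        from trustmix.mixture_gibbs import modal_allocation

        zm = modal_allocation(chain)
        for p in profiles:
            members = zm == p.cluster
            true_k = np.bincount(truth[members], minlength=4).argmax()
            np.testing.assert_allclose(
                p.mean_beta, DEFAULT_BETAS[true_k], atol=0.12
            )


def _brute_force_ari(a, b):
    """Contingency-table ARI from first principles (comb arithmetic)."""
    from math import comb

    a, b = np.asarray(a), np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    nij = np.array([[(np.logical_and(a == x, b == y)).sum() for y in ub]
                    for x in ua])
    sum_ij = sum(comb(int(v), 2) for v in nij.ravel())
    sum_a = sum(comb(int(v), 2) for v in nij.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in nij.sum(axis=0))
    total = comb(a.size, 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    return (sum_ij - expected) / (max_index - expected)


class TestAdjustedRand:
    def test_identical_partitions(self):
        assert adjusted_rand([0, 0, 1, 1, 2], [0, 0, 1, 1, 2]) == 1.0

    def test_crossed_partitions_minus_half(self):
        assert adjusted_rand([1, 1, 2, 2], [1, 2, 1, 2]) == \
            pytest.approx(-0.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.integers(0, 4, 60)
            b = rng.integers(0, 3, 60)
            assert adjusted_rand(a, b) == pytest.approx(
                _brute_force_ari(a, b)
            )

    def test_independent_partitions_near_zero(self):
        rng = np.random.default_rng(2)
        values = [
            adjusted_rand(rng.integers(0, 4, 500), rng.integers(0, 4, 500))
            for _ in range(50)
        ]
        assert abs(np.mean(values)) < 0.01

    def test_mismatched_sizes_raise(self):
        with pytest.raises(ValueError):
            adjusted_rand([0, 1], [0, 1, 2])

    def test_singleton_raises(self):
        with pytest.raises(ValueError):
            adjusted_rand([0], [0])
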