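import math

import numpy as np
import pandas as pd
import pytest

from rcclnc import signatures
from rcclnc.synthetic import SimConfig, generate_expression_study
from rcclnc.signatures import (
    choose_s0,
    finalize_consensus,
    golub_select,
    leave_one_out_signature,
    sam_d_statistic,
    sam_select,
    signed_fold_change,
    survival_signature,
)


def brute_force_one_class_d(X, s0):
    """Direct per-row computation with scalar arithmetic only."""
    out = []
    for row in X:
        n = len(row)
        mean = sum(row) / n
        var = sum((v - mean) ** 2 for v in row) / (n - 1)
        s = math.sqrt(var) / math.sqrt(n)
        out.append(mean / (s + s0))
    return np.array(out)


class TestDStatistic:
    def test_matches_direct_formula_to_1e12(self, rng):
        X = rng.normal(size=(5, 6))
        for s0 in (0.0, 0.3, 1.7):
            d = sam_d_statistic(X, "one_class", s0=s0)
            assert np.allclose(d, brute_force_one_class_d(X, s0), atol=1e-12, rtol=0)

    def test_constant_row_with_fudge(self):
        # values {1,1,1}: r=1, s=0, d = 1 / (0 + 0.5) = 2
        d = sam_d_statistic(np.array([[1.0, 1.0, 1.0]]), "one_class", s0=0.5)
        assert d[0] == pytest.approx(2.0)

    def test_zero_numerator_gives_zero(self):
        d = sam_d_statistic(np.zeros((1, 5)), "one_class", s0=0.4)
        assert d[0] == 0.0

    def test_scale_equivariance_at_zero_fudge(self, rng):
        X = rng.normal(1, 1, size=(10, 7))
        d1 = sam_d_statistic(X, "one_class", s0=0.0)
        d2 = sam_d_statistic(3.0 * X, "one_class", s0=0.0)
        assert np.allclose(d1, d2)

    def test_two_class_pooled_standard_error(self, rng):
        X = rng.normal(size=(4, 9))
        labels = np.array([True] * 4 + [False] * 5)
        d = sam_d_statistic(X, "two_class", labels=labels, s0=0.1)
        xa, xb = X[:, :4], X[:, 4:]
        for i in range(4):
            ss = ((xa[i] - xa[i].mean()) ** 2).sum() + ((xb[i] - xb[i].mean()) ** 2).sum()
            s = math.sqrt(ss / 7 * (1 / 4 + 1 / 5))
            expect = (xa[i].mean() - xb[i].mean()) / (s + 0.1)
            assert d[i] == pytest.approx(expect, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            sam_d_statistic(np.ones((3, 4)), "two_class", labels=[True, False, False, False])


class TestChooseS0:
    def test_matches_independent_grid_search(self, rng):
        # heteroscedastic rows: per-row noise scale spans two decades
        scales = np.exp(rng.uniform(-2, 2, size=120))
        X = rng.normal(0, 1, size=(120, 8)) * scales[:, None]
        r = X.mean(axis=1)
        s = X.std(axis=1, ddof=1) / math.sqrt(8)
        candidates = np.percentile(s, np.arange(0, 101, 5))
        order = np.argsort(s, kind="stable")
        windows = np.array_split(order, min(100, len(s) // 5))
        best, best_cv = None, np.inf
        for cand in candidates:
            d = r / (s + cand)
            spreads = np.array(
                [np.median(np.abs(d[w] - np.median(d[w]))) / 0.64 for w in windows]
            )
            cv = spreads.std(ddof=1) / spreads.mean()
            if cv < best_cv:
                best_cv, best = cv, float(cand)
        assert choose_s0(X, "one_class") == pytest.approx(best)

    def test_all_equal_spreads_return_zeroth_percentile(self):
        X = np.tile([1.0, 2.0, 3.0, 4.0], (6, 1))
        assert choose_s0(X, "one_class") == pytest.approx(X.std(ddof=1, axis=1)[0] / 2)

    def test_all_zero_spread_floor(self):
        s0 = choose_s0(np.ones((5, 4)), "one_class")
        assert s0 > 0


class TestSamSelect:
    def test_deterministic_given_seed(self, small_ratios):
        a = sam_select(small_ratios, "one_class", n_perm=200, seed=5)
        b = sam_select(small_ratios, "one_class", n_perm=200, seed=5)
        assert a.table.equals(b.table)
        assert a.delta == b.delta and a.fdr == b.fdr

    def test_requires_enough_permutations(self, small_ratios):
        with pytest.raises(ValueError, match="n_perm"):
            sam_select(small_ratios, "one_class", n_perm=50)

    def test_empirical_fdr_control_on_planted_data(self):
        # average realized false-discovery proportion at nominal 5% stays
        # below 15% over seeded replicates
        fdps = []
        for seed in range(20):
            cfg = SimConfig(
                seed=seed,
                n_probes_by_class={
                    "intronic_antisense": 300, "lincRNA": 100,
                    "protein_coding": 0, "negative_control": 10,
                },
                frac_de=0.1, frac_survival=0.0, planted_log2fc=1.0,
            )
            study, truth = generate_expression_study(cfg)
            lnc = study.probes.index[
                study.probes["probe_class"].isin(["intronic_antisense", "lincRNA"])
            ]
            ratios = np.log2(study.intensities.loc[lnc])
            ratios = pd.DataFrame(
                ratios.iloc[:, :11].to_numpy() - ratios.iloc[:, 11:].to_numpy(),
                index=lnc,
            )
            res = sam_select(ratios, "one_class", n_perm=500, fdr_cut=0.05, seed=seed)
            sel = set(res.selected)
            if sel:
                fdps.append(len(sel - set(truth.de_probes)) / len(sel))
        assert np.mean(fdps) < 0.15


class TestConsensusRule:
    def test_presence_below_unity_fails(self):
        assert not finalize_consensus([10 / 11], [10.0])[0]

    def test_fold_change_below_threshold_fails(self):
        assert not finalize_consensus([1.0], [1.4])[0]

    def test_both_criteria_pass(self):
        assert finalize_consensus([1.0], [-1.6])[0]

    def test_signed_fold_change_convention(self):
        fc = signed_fold_change([1.0, -1.0, 0.0, math.log2(1.5)])
        assert fc == pytest.approx([2.0, -2.0, 1.0, 1.5])


class TestLeaveOneOut:
    def test_final_subset_of_every_loo_selection(self, small_ratios):
        loo = leave_one_out_signature(small_ratios, n_perm=200, seed=3)
        final = set(loo.final)
        for res in loo.loo_results:
            assert final <= set(res.selected)

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError):
            leave_one_out_signature(pd.DataFrame(np.ones((5, 2))))

    def test_recovers_planted_signature(self, small_study, small_ratios):
        _, truth = small_study
        loo = leave_one_out_signature(small_ratios, n_perm=300, seed=11)
        final = set(loo.final)
        planted = set(truth.de_probes)
        assert len(final & planted) / len(planted) > 0.6
        # planted effect 1.0 -> 2-fold; directions must match the truth
        for pid, direction in truth.de_probes.items():
            if pid in final:
                assert np.sign(loo.table.loc[pid, "mean_fc"]) == direction


class TestGolub:
    def test_three_gene_hand_oracle(self):
        X = pd.DataFrame(
            [[1.0, 2.0, 5.0, 6.0], [3.0, 3.0, 3.0, 4.0], [10.0, 8.0, 2.0, 1.0]],
            index=["g1", "g2", "g3"],
        )
        labels = [True, True, False, False]
        res = golub_select(X, labels, n_perm=200, seed=0)
        for i in range(3):
            a, b = X.iloc[i, :2], X.iloc[i, 2:]
            expect = (a.mean() - b.mean()) / (a.std(ddof=1) + b.std(ddof=1))
            assert res.table["score"].iloc[i] == pytest.approx(expect, abs=1e-12)

    def test_identical_group_means_null(self, rng):
        base = rng.normal(size=6)
        X = pd.DataFrame([np.concatenate([base, base])])
        res = golub_select(X, [True] * 6 + [False] * 6, n_perm=300, seed=1)
        assert res.table["score"].iloc[0] == pytest.approx(0.0)
        assert res.table["p"].iloc[0] > 0.5

    def test_perfect_separator_attains_minimum_p(self, rng):
        sep = np.array([0.0, 0.01, 1.0, 1.01])
        noise = rng.normal(size=(5, 4))
        X = pd.DataFrame(np.vstack([sep, noise]))
        res = golub_select(X, [True, True, False, False], n_perm=500, seed=2)
        # add-one smoothing: minimum attainable p = (b+1)/(m+1) with b the
        # count of permutations tying the observed separation
        assert res.table["p"].iloc[0] == res.table["p"].min()
        assert res.table["p"].iloc[0] < 0.5

    def test_zero_denominator_excluded(self):
        X = pd.DataFrame([[1.0, 1.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0]])
        res = golub_select(X, [True, True, False, False], n_perm=200, seed=3)
        assert bool(res.table["excluded"].iloc[0])
        assert not bool(res.table["selected"].iloc[0])

    def test_p_values_in_unit_interval(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 8)))
        res = golub_select(X, [True] * 4 + [False] * 4, n_perm=200, seed=4)
        p = res.table["p"]
        assert ((p > 0) & (p <= 1)).all()


@pytest.fixture(scope="module")
def surv_setup():
    cfg = SimConfig(
        seed=5, n_pairs=16,
        n_probes_by_class={
            "intronic_antisense": 300, "lincRNA": 0,
            "protein_coding": 0, "negative_control": 10,
        },
        frac_de=0.0, frac_survival=0.1, planted_log2fc=1.5,
    )
    study, truth = generate_expression_study(cfg)
    lnc = study.probes.index[study.probes["probe_class"] == "intronic_antisense"]
    X = np.log2(study.intensities.loc[lnc, study.tumor_samples])
    outcome = study.samples.loc[study.tumor_samples, "survival_status"]
    return X, outcome, truth


class TestSurvivalSignature:
    def test_intersection_subset_of_parents(self, surv_setup):
        X, outcome, _ = surv_setup
        res = survival_signature(X, outcome, n_perm=300, seed=1)
        genes = set(res.genes)
        assert genes <= set(res.sam.selected)
        assert genes <= set(res.golub.selected)

    def test_recovers_planted_survival_probes(self, surv_setup):
        X, outcome, truth = surv_setup
        res = survival_signature(X, outcome, n_perm=1000, seed=2)
        planted = set(truth.survival_probes)
        assert len(set(res.genes) & planted) / len(planted) >= 0.8

    def test_sample_matching_dead_mean_orders_first(self, surv_setup):
        X, outcome, _ = surv_setup
        res = survival_signature(X, outcome, n_perm=300, seed=3)
        dead_cols = outcome.index[outcome == "dead"]
        X2 = X.copy()
        # a sample equal to the old dead-group mean leaves the enlarged
        # group's mean unchanged, so it correlates at exactly r = 1
        X2["Tsynth"] = X.loc[:, dead_cols].mean(axis=1)
        outcome2 = pd.concat([outcome, pd.Series({"Tsynth": "dead"})])
        res2 = survival_signature(X2, outcome2, n_perm=300, seed=3)
        assert len(res2.genes) >= 2
        assert res2.sample_correlations["Tsynth"] == pytest.approx(1.0)
        assert res2.ordered_samples[0] == "Tsynth"
        del res
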