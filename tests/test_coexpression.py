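import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rcclnc.coexpression import (
    cis_correlation,
    go_module_map,
    mean_partners_per_lnc,
    select_top_abundant,
    spearman,
    spearman_matrix,
    t_approx_p,
    trans_correlation,
)
from rcclnc.synthetic import SimConfig, generate_all


def explicit_average_ranks(values):
    """Brute-force average ranks, independent of scipy."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2)
    return ranks


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


class TestSpearman:
    def test_tie_corrected_value_matches_rank_definition(self):
        x, y = (1, 2, 2, 4), (1, 3, 2, 4)
        rho, _ = spearman(x, y)
        oracle = pearson(explicit_average_ranks(x), explicit_average_ranks(y))
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_monotone_map_is_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        rho, _ = spearman(x, 2 * x + 1)
        assert rho == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        x = np.arange(6.0)
        rho, _ = spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert spearman(x, y) == spearman(y, x)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_matrix_matches_pairwise_scipy_with_ties(self, rng):
        A = np.round(rng.normal(size=(6, 12)), 1)  # rounding plants ties
        B = np.round(rng.normal(size=(5, 12)), 1)
        M = spearman_matrix(A, B)
        for i in range(6):
            for j in range(5):
                expect, _ = sps.spearmanr(A[i], B[j])
                assert M[i, j] == pytest.approx(expect, abs=1e-9)

    def test_t_approximation_matches_scipy_p(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        rho, p = sps.spearmanr(x, y)
        assert t_approx_p(np.array([rho]), 15)[0] == pytest.approx(p, abs=1e-9)


class TestCutoffConventions:
    def exact_rho_frames(self, y_ranks, n_cols=5):
        # a rank permutation with a chosen sum of squared rank differences
        # gives an exact tie-free rho = 1 - 6*S/(n*(n^2-1))
        lnc = pd.DataFrame([np.arange(1.0, n_cols + 1)], index=["L1"])
        mrna = pd.DataFrame([np.array(y_ranks, dtype=float)], index=["M1"])
        return lnc, mrna

    def test_trans_inclusive_at_exact_0p7(self):
        # ranks (1,2,5,3,4): S = 6 -> rho = 1 - 36/120 = 0.7 exactly
        lnc, mrna = self.exact_rho_frames([1, 2, 5, 3, 4])
        records, _ = trans_correlation(lnc, mrna, rho_cut=0.7, p_cut=1.0)
        assert len(records) == 1
        assert records["rho"].iloc[0] == pytest.approx(0.7)

    def test_cis_strict_at_exact_0p5(self):
        # ranks (2,4,1,3,5): S = 10 -> rho = 1 - 60/120 = 0.5 exactly
        lnc, mrna = self.exact_rho_frames([2, 4, 1, 3, 5])
        records, summary = cis_correlation(
            lnc, mrna, {"L1": "M1"}, rho_cut=0.5, p_cut=1.0
        )
        assert summary["n_tested"] == 1
        assert len(records) == 0

    def test_cis_and_trans_records_disjoint_by_locus(self, rng):
        lnc = pd.DataFrame(rng.normal(size=(4, 10)), index=[f"L{i}" for i in range(4)])
        mrna = pd.DataFrame(rng.normal(size=(4, 10)), index=[f"M{i}" for i in range(4)])
        locus = {f"L{i}": f"M{i}" for i in range(4)}
        cis, _ = cis_correlation(lnc, mrna, locus, rho_cut=0.0, p_cut=1.0)
        trans, _ = trans_correlation(lnc, mrna, locus, rho_cut=0.0, p_cut=1.0)
        cis_pairs = set(zip(cis["lnc_id"], cis["partner_id"]))
        trans_pairs = set(zip(trans["lnc_id"], trans["partner_id"]))
        assert cis_pairs and trans_pairs
        assert not cis_pairs & trans_pairs

    def test_missing_locus_skipped(self, rng):
        lnc = pd.DataFrame(rng.normal(size=(2, 8)), index=["L0", "L1"])
        mrna = pd.DataFrame(rng.normal(size=(1, 8)), index=["M0"])
        _, summary = cis_correlation(lnc, mrna, {"L0": "M0"})
        assert summary["n_tested"] == 1


class TestTopAbundant:
    def test_exact_division(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 3)))
        assert len(select_top_abundant(expr, 0.2)) == 2

    def test_floor_of_fraction(self, rng):
        expr = pd.DataFrame(rng.normal(size=(13, 2)))
        assert len(select_top_abundant(expr, 0.2)) == 2  # floor(2.6)

    def test_all_equal_ties_are_id_ordered_and_stable(self):
        expr = pd.DataFrame(np.ones((6, 2)), index=list("fedcba"))
        first = select_top_abundant(expr, 0.5)
        second = select_top_abundant(expr, 0.5)
        assert list(first) == ["a", "b", "c"]
        assert list(first) == list(second)

    def test_invalid_fraction(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            select_top_abundant(expr, 0.0)

    def test_selects_highest_mean(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 4)))
        top = select_top_abundant(expr, 0.25)
        means = expr.mean(axis=1)
        assert means[top].min() >= means.drop(top).max()


def hypergeom_tail_enumeration(k, N, K, n):
    """P(X >= k) by explicit combinatorial enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


class TestModuleMap:
    def records(self, pairs):
        return pd.DataFrame(
            [{"lnc_id": l, "partner_id": m, "rho": r, "p": 0.01, "mode": "trans",
              "direction": "direct" if r > 0 else "inverse"}
             for l, m, r in pairs]
        )

    def test_hypergeometric_matches_enumeration_on_toy_universe(self):
        background = {f"g{i}" for i in range(20)}
        term_genes = {f"g{i}" for i in range(6)}
        annotation = {g: ({"T"} if g in term_genes else set()) for g in background}
        correlated = [f"g{i}" for i in range(5)]  # 5 of 6 term genes
        recs = self.records([("L1", g, 0.9) for g in correlated])
        cells = go_module_map(recs, annotation, background, alpha=0.05)
        p_adj = cells["enrichment_p"].iloc[0]
        oracle = hypergeom_tail_enumeration(5, 20, 6, 5)  # one term tested
        assert p_adj == pytest.approx(oracle, abs=1e-9)
        assert cells["sign"].iloc[0] == 1

    def test_degenerate_universe_not_enriched(self):
        background = {"a", "b", "c"}
        annotation = {g: {"T"} for g in background}
        recs = self.records([("L1", g, 0.5) for g in background])
        cells = go_module_map(recs, annotation, background)
        assert cells["enrichment_p"].iloc[0] == pytest.approx(1.0)
        assert cells["sign"].iloc[0] == 0

    def test_majority_inverse_sign(self):
        background = {f"g{i}" for i in range(30)}
        annotation = {g: ({"T"} if int(g[1:]) < 6 else set()) for g in background}
        recs = self.records(
            [("L1", f"g{i}", -0.9) for i in range(4)] + [("L1", "g4", 0.9)]
        )
        cells = go_module_map(recs, annotation, background)
        enriched = cells[cells["sign"] != 0]
        assert len(enriched) == 1
        assert enriched["sign"].iloc[0] == -1

    def test_bonferroni_never_below_raw_and_capped(self, rng):
        background = {f"g{i}" for i in range(40)}
        annotation = {}
        for g in background:
            terms = {f"T{j}" for j in range(5) if rng.random() < 0.3}
            annotation[g] = terms
        recs = self.records(
            [("L1", f"g{i}", 0.8) for i in range(10)]
        )
        cells = go_module_map(recs, annotation, background)
        n_terms = len({t for ts in annotation.values() for t in ts})
        for _, row in cells.iterrows():
            assert row["enrichment_p"] <= 1.0
            # adjusted p equals min(1, raw * n_terms) => raw <= adjusted
            assert row["enrichment_p"] >= row["enrichment_p"] / n_terms

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            go_module_map(self.records([("L1", "g1", 0.9)]), {}, {"g1"})

    def test_planted_module_recovery(self):
        cfg = SimConfig(
            seed=21,
            n_probes_by_class={"intronic_antisense": 120, "lincRNA": 0,
                               "protein_coding": 0, "negative_control": 10},
            frac_cis=0.0, n_trans_modules=3, trans_module_size=10,
            genome_length_bp=20_000_000,
        )
        data = generate_all(cfg)
        panel = data.tissue
        records, _ = trans_correlation(
            panel.lnc_expr, panel.mrna_expr, panel.locus_map
        )
        cells = go_module_map(records, panel.go_annotation, set(panel.mrna_expr.index))
        planted_terms = {f"GO:module_{k:02d}" for k in range(3)}
        enriched = set(cells.loc[cells["sign"] != 0, "go_term"])
        assert planted_terms <= enriched


def test_mean_partners_rounding():
    assert mean_partners_per_lnc(5293, 693) == 7.6
    assert mean_partners_per_lnc(15, 2) == 7.5
    with pytest.raises(ValueError):
        mean_partners_per_lnc(5, 0)


def test_planted_cis_recovery():
    cfg = SimConfig(
        seed=9,
        n_probes_by_class={"intronic_antisense": 150, "lincRNA": 0,
                           "protein_coding": 0, "negative_control": 10},
        frac_cis=0.3, genome_length_bp=20_000_000,
    )
    data = generate_all(cfg)
    panel = data.tissue
    records, _ = cis_correlation(panel.lnc_expr, panel.mrna_expr, panel.locus_map)
    hits = set(records["lnc_id"]) & set(data.truth.cis_pairs)
    assert len(hits) / len(data.truth.cis_pairs) >= 0.8
    # planted signs must be recovered too
    by_lnc = dict(zip(records["lnc_id"], records["rho"]))
    for lnc, (host, sign) in data.truth.cis_pairs.items():
        if lnc in by_lnc:
            assert np.sign(by_lnc[lnc]) == sign
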