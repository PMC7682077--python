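"""EMT/hallmark scoring and the weighted-KS enrichment engine."""

import numpy as np
import pandas as pd
import pytest

from hspnet.io import ExpressionMatrix, GeneSet
from hspnet.signatures import (EmtSignature, emt_score, gsea_es,
                               gsea_significance, median_split, rank_metric,
                               score_correlation_scan, signature_score)


def _em(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples),
                            condition="tumor", cohort="X")


class TestEmtScore:
    def test_arithmetic(self):
        # log2(x+1) values: M genes (2, 4), E genes (1, 3) -> 3 - 2 = 1
        arr = 2.0 ** np.array([[2.0], [4.0], [1.0], [3.0]]) - 1.0
        em = _em(arr, genes=["M1", "M2", "E1", "E2"])
        sig = EmtSignature(frozenset(["E1", "E2"]), frozenset(["M1", "M2"]))
        assert emt_score(em, sig).iloc[0] == pytest.approx(1.0)

    def test_all_genes_equal_gives_zero(self):
        em = _em(np.full((4, 3), 7.0), genes=["M1", "M2", "E1", "E2"])
        sig = EmtSignature(frozenset(["E1", "E2"]), frozenset(["M1", "M2"]))
        assert np.allclose(emt_score(em, sig), 0.0)

    def test_swapping_sets_negates(self):
        rng = np.random.default_rng(0)
        em = _em(rng.uniform(1, 50, (6, 10)),
                 genes=["M1", "M2", "M3", "E1", "E2", "E3"])
        sig = EmtSignature(frozenset(["E1", "E2", "E3"]),
                           frozenset(["M1", "M2", "M3"]))
        flipped = EmtSignature(frozenset(["M1", "M2", "M3"]),
                               frozenset(["E1", "E2", "E3"]))
        np.testing.assert_allclose(emt_score(em, sig),
                                   -emt_score(em, flipped))

    def test_shift_on_mesenchymal_only_adds_constant(self):
        rng = np.random.default_rng(1)
        logx = rng.uniform(1, 6, (4, 5))
        em1 = _em(2.0 ** logx - 1, genes=["M1", "M2", "E1", "E2"])
        logx2 = logx.copy()
        logx2[:2] += 1.5
        em2 = _em(2.0 ** logx2 - 1, genes=["M1", "M2", "E1", "E2"])
        sig = EmtSignature(frozenset(["E1", "E2"]), frozenset(["M1", "M2"]))
        np.testing.assert_allclose(emt_score(em2, sig),
                                   emt_score(em1, sig) + 1.5)

    def test_absent_set_rejected(self):
        em = _em(np.ones((2, 3)), genes=["M1", "M2"])
        sig = EmtSignature(frozenset(["E1"]), frozenset(["M1", "M2"]))
        with pytest.raises(ValueError):
            emt_score(em, sig)

    def test_recovers_generating_factor(self, reference_cohort, reference_sets):
        # the score must track the latent EMT factor via the subtype proxy
        sig = EmtSignature.from_sets(reference_sets["EPITHELIAL"],
                                     reference_sets["MESENCHYMAL"])
        scores = emt_score(reference_cohort.tumor, sig)
        sub = reference_cohort.clinical["subtype"]
        mes = scores[sub == "mesenchymal"]
        epi = scores[sub == "epithelial"]
        assert mes.median() > epi.median() + 1.0


class TestMedianSplit:
    def test_even_split(self):
        x = pd.Series(np.arange(1.0, 11.0), index=[f"S{i}" for i in range(10)])
        labels = median_split(x)
        assert (labels == "high").sum() == 5 and (labels == "low").sum() == 5

    def test_tie_rule_sends_median_to_low(self):
        x = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"), name="g")
        labels = median_split(x)
        assert list(labels[labels == "high"].index) == ["d"]
        assert set(labels[labels == "low"].index) == {"a", "b", "c"}

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            median_split(pd.Series([2.0, 2.0, 2.0, 2.0], name="g"))


class TestRankMetric:
    def test_signal_direction(self):
        arr = np.array([[5, 6, 7, 1, 2, 3], [1, 1, 2, 5, 5, 6.0]])
        em = _em(arr)
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=em.samples)
        m = rank_metric(em.values, groups)
        assert m["G0"] > 0 > m["G1"]
        assert list(m.index) == ["G0", "G1"]  # sorted descending

    def test_hand_formula(self):
        h = np.array([4.0, 5.0, 6.0])
        l = np.array([1.0, 2.0, 3.0])
        em = _em(np.concatenate([h, l])[None, :])
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=em.samples)
        sd_h = max(h.std(ddof=1), 0.2 * abs(h.mean()), 0.2)
        sd_l = max(l.std(ddof=1), 0.2 * abs(l.mean()), 0.2)
        expected = (h.mean() - l.mean()) / (sd_h + sd_l)
        assert rank_metric(em.values, groups)["G0"] == pytest.approx(expected)

    def test_identical_groups_zero_metric(self):
        arr = np.tile(np.array([1.0, 2.0, 3.0]), (2, 2))
        em = _em(arr)
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=em.samples)
        assert np.allclose(rank_metric(em.values, groups), 0.0)

    def test_small_group_rejected(self):
        em = _em(np.arange(8.0)[None, :])
        groups = pd.Series(["high"] * 2 + ["low"] * 6, index=em.samples)
        with pytest.raises(ValueError):
            rank_metric(em.values, groups)


def es_bruteforce(metric_values, hit_mask, weight=1.0):
    """Literal running-sum enumeration of the enrichment score."""
    n = len(metric_values)
    n_h = sum(hit_mask)
    denom = sum(abs(m) ** weight for m, h in zip(metric_values, hit_mask) if h)
    running = 0.0
    max_pos, min_neg = 0.0, 0.0
    for m, h in zip(metric_values, hit_mask):
        if h:
            running += (abs(m) ** weight / denom) if denom > 0 else 1.0 / n_h
        else:
            running -= 1.0 / (n - n_h)
        max_pos = max(max_pos, running)
        min_neg = min(min_neg, running)
    # same tie rule as the engine: equal magnitudes resolve positive
    return max_pos if max_pos + min_neg >= -1e-12 else min_neg


class TestGseaEs:
    def _ranked(self, values, genes=None):
        genes = genes or [f"G{i}" for i in range(len(values))]
        return pd.Series(values, index=genes)

    def test_top_gene_extreme(self):
        ranked = self._ranked(np.linspace(5, 0.5, 10))
        assert gsea_es(ranked, {"G0"}, weight=0.0) == pytest.approx(1.0)

    def test_bottom_gene_extreme(self):
        ranked = self._ranked(np.linspace(5, 0.5, 10))
        assert gsea_es(ranked, {"G9"}, weight=0.0) == pytest.approx(-1.0)

    def test_worked_five_gene_example(self):
        ranked = self._ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        expected = es_bruteforce([5, 4, 3, 2, 1], [1, 0, 1, 0, 0])
        assert gsea_es(ranked, {"G0", "G2"}) == pytest.approx(expected)

    def test_matches_bruteforce_on_all_subsets(self):
        # exhaustive: every proper non-empty subset of a 10-gene list
        rng = np.random.default_rng(2)
        values = np.sort(rng.normal(size=10))[::-1]
        ranked = self._ranked(values)
        genes = list(ranked.index)
        for bits in range(1, 2 ** 10 - 1):
            mask = [(bits >> i) & 1 for i in range(10)]
            subset = {g for g, b in zip(genes, mask) if b}
            assert gsea_es(ranked, subset) == pytest.approx(
                es_bruteforce(values, mask), abs=1e-12)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            gsea_es(self._ranked([3.0, 2.0, 1.0]), {"ZZ"})


class TestGseaSignificance:
    def _dataset(self, seed=0, shift=0.0, n_genes=60, n_per_group=20,
                 set_size=8):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(n_genes, 2 * n_per_group))
        arr[:set_size, :n_per_group] += shift
        vals = pd.DataFrame(arr, index=[f"G{i}" for i in range(n_genes)],
                            columns=[f"S{i}" for i in range(2 * n_per_group)])
        groups = pd.Series(["high"] * n_per_group + ["low"] * n_per_group,
                           index=vals.columns)
        gs = GeneSet("S", frozenset(f"G{i}" for i in range(set_size)))
        return vals, groups, gs

    def test_planted_shift_detected(self):
        vals, groups, gs = self._dataset(seed=3, shift=1.0)
        res = gsea_significance(vals, groups, gs, n_perm=300, seed=7)
        assert res.es > 0 and res.p <= 0.01

    def test_deterministic_given_seed(self):
        vals, groups, gs = self._dataset(seed=4, shift=0.5)
        a = gsea_significance(vals, groups, gs, n_perm=50, seed=9)
        b = gsea_significance(vals, groups, gs, n_perm=50, seed=9)
        assert (a.es, a.nes, a.p) == (b.es, b.nes, b.p)

    def test_gene_set_permutation_mode(self):
        vals, groups, gs = self._dataset(seed=5, shift=1.0)
        res = gsea_significance(vals, groups, gs, n_perm=100, seed=11,
                                perm_type="gene_set")
        assert res.es > 0 and res.p <= 0.05


class TestSignatureScore:
    def test_single_gene_set_is_zscore(self):
        rng = np.random.default_rng(6)
        arr = rng.uniform(1, 20, size=(3, 8))
        em = _em(arr)
        logx = np.log2(arr[0] + 1)
        expected = (logx - logx.mean()) / logx.std()
        np.testing.assert_allclose(signature_score(em, {"G0"}), expected,
                                   atol=1e-12)

    def test_identical_samples_all_zero(self):
        em = _em(np.tile([[3.0], [5.0]], (1, 6)))
        assert np.allclose(signature_score(em, {"G0", "G1"}), 0.0)

    def test_worked_mean_of_zscores(self):
        arr = np.array([[1.0, 3.0, 7.0, 15.0], [15.0, 7.0, 3.0, 1.0],
                        [2.0, 2.0, 2.0, 2.0]])
        em = _em(arr)
        logx = np.log2(arr + 1)
        z = (logx - logx.mean(axis=1, keepdims=True))
        sd = logx.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        expected = (z / sd)[:2].mean(axis=0)
        np.testing.assert_allclose(signature_score(em, {"G0", "G1"}), expected,
                                   atol=1e-12)


class TestScoreCorrelation:
    def test_planted_loadings_recovered(self, reference_cohort, reference_sets):
        truth = reference_cohort.truth
        sig = EmtSignature.from_sets(reference_sets["EPITHELIAL"],
                                     reference_sets["MESENCHYMAL"])
        scores = emt_score(reference_cohort.tumor, sig)
        planted = {g: q for g, q in truth.quadrant.items() if q != "none"}
        recs = score_correlation_scan(reference_cohort.tumor, scores,
                                      list(planted), endpoint="EMT_score")
        ok = sum(r.significant and r.direction == planted[r.gene][3]
                 for r in recs)
        assert ok >= 0.9 * len(planted)

    def test_mesenchymal_gene_positive_by_construction(self, reference_cohort,
                                                       reference_sets):
        sig = EmtSignature.from_sets(reference_sets["EPITHELIAL"],
                                     reference_sets["MESENCHYMAL"])
        scores = emt_score(reference_cohort.tumor, sig)
        gene = sorted(reference_sets["MESENCHYMAL"].genes)[0]
        recs = score_correlation_scan(reference_cohort.tumor, scores, [gene])
        assert recs[0].estimate > 0
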