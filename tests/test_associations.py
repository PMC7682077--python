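"""Differential expression, clinical, marker and dependency scans."""

import numpy as np
import pandas as pd
import pytest

from hspnet.associations import (AssociationRecord, clinical_group_association,
                                 dependency_background, dependency_difference,
                                 dependency_differences,
                                 differential_expression, family_summary,
                                 marker_correlation,
                                 paired_feature_correlation,
                                 signed_fold_change, survival_association,
                                 survival_scan)
from hspnet.io import ExpressionMatrix, GeneFamilyCatalog


def _em(arr, condition="tumor", cohort="X", genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"P{i:03d}-{condition[0].upper()}"
                          for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples),
                            condition=condition, cohort=cohort)


class TestSignedFoldChange:
    def test_equal_means_give_one(self):
        assert signed_fold_change(2.0, 2.0) == 1.0

    def test_antisymmetry(self):
        assert signed_fold_change(6.0, 2.0) == pytest.approx(
            -signed_fold_change(2.0, 6.0))

    @pytest.mark.parametrize("mt,mn,expected", [(4.0, 1.0, 4.0),
                                                (1.0, 4.0, -4.0),
                                                (3.0, 2.0, 1.5)])
    def test_values(self, mt, mn, expected):
        assert signed_fold_change(mt, mn) == pytest.approx(expected)


class TestDifferentialExpression:
    def test_identical_conditions_nothing_significant(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(1, 10, size=(5, 20))
        recs = differential_expression(_em(arr, "tumor"), _em(arr, "normal"))
        assert all(r.estimate == 1.0 and not r.significant for r in recs)

    def test_planted_fourfold_gene(self):
        rng = np.random.default_rng(1)
        normal = rng.uniform(4, 6, size=(6, 20))
        tumor = normal * 1.0
        tumor[0] *= 4.0
        recs = differential_expression(_em(tumor, "tumor"), _em(normal, "normal"))
        rec = next(r for r in recs if r.gene == "G0")
        assert rec.estimate == pytest.approx(4.0)
        assert rec.significant and rec.direction == "+"
        assert not any(r.significant for r in recs if r.gene != "G0")

    def test_fold_gate_blocks_small_changes(self):
        rng = np.random.default_rng(2)
        normal = rng.uniform(4, 6, size=(3, 40))
        tumor = normal * 1.0
        tumor[0] *= 1.4  # tiny p but FC below the 1.5 gate
        recs = differential_expression(_em(tumor, "tumor"), _em(normal, "normal"))
        rec = next(r for r in recs if r.gene == "G0")
        assert rec.p < 1e-6 and not rec.significant

    def test_min_pairs_gate(self):
        rng = np.random.default_rng(3)
        arr = rng.uniform(1, 10, size=(3, 4))
        assert differential_expression(_em(arr, "tumor"), _em(arr, "normal")) == []


class TestFamilySummary:
    def _records(self, fam_counts):
        records, catalog = [], {}
        i = 0
        for fam, (up, down) in fam_counts.items():
            for k in range(up + down):
                gene = f"{fam}_{k}"
                catalog[gene] = (fam, "")
                records.append(AssociationRecord(
                    gene, f"C{i}", "DE", 2.0 if k < up else -2.0, 1e-6,
                    fdr=1e-6, direction="+" if k < up else "-",
                    significant=True))
                i += 1
        return records, GeneFamilyCatalog(catalog)

    def test_reference_percentages(self):
        records, catalog = self._records({"HSP90": (19, 2), "HSP20": (14, 85)})
        fams = {f.family: f for f in family_summary(records, catalog)}
        assert fams["HSP90"].percent_up == 90.5  # 19/21
        assert fams["HSP20"].percent_down == 85.9  # 85/99

    def test_empty_records(self):
        assert family_summary([], GeneFamilyCatalog({"A": ("F", "")})) == []

    def test_unassigned_gene_bucket(self):
        recs = [AssociationRecord("ZZZ", "C", "DE", 2.0, 1e-6, fdr=1e-6,
                                  direction="+", significant=True)]
        fams = family_summary(recs, GeneFamilyCatalog({"A": ("F", "")}))
        assert fams[0].family == "unassigned"


class TestSurvival:
    def test_planted_hazard_detected(self, reference_cohort):
        spec = reference_cohort.truth.spec
        pos_gene = [g for g, c in spec.survival.coefficients.items() if c > 0][0]
        recs = survival_scan(reference_cohort.tumor, reference_cohort.clinical,
                             spec.family_genes, method="cox")
        rec = next(r for r in recs if r.gene == pos_gene)
        assert rec.significant and rec.direction == "+"
        assert rec.estimate > 1.0

    def test_logrank_median_split_agrees_in_direction(self, reference_cohort):
        spec = reference_cohort.truth.spec
        pos_gene = [g for g, c in spec.survival.coefficients.items() if c > 0][0]
        recs = survival_scan(reference_cohort.tumor, reference_cohort.clinical,
                             [pos_gene], method="logrank_median")
        assert recs[0].direction == "+" and recs[0].p < 0.05

    def test_all_censored_degenerate(self):
        clin = pd.DataFrame({"os_time": [10.0, 20, 30, 40],
                             "os_event": [0, 0, 0, 0]},
                            index=pd.Index(["S1", "S2", "S3", "S4"],
                                           name="sample"))
        expr = pd.Series([1.0, 2, 3, 4], index=clin.index, name="G")
        rec = survival_association(expr, clin)
        assert np.isnan(rec.p) and "events" in rec.note


class TestClinicalGroups:
    def test_small_group_dropped(self):
        x = pd.Series(np.arange(14.0), index=[f"S{i}" for i in range(14)],
                      name="G")
        labels = pd.Series(["a"] * 4 + ["b"] * 10, index=x.index)
        assert clinical_group_association(x, labels) is None

    def test_two_group_shift_detected(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
        x = pd.Series(vals, index=[f"S{i}" for i in range(60)], name="G")
        labels = pd.Series(["lo"] * 30 + ["hi"] * 30, index=x.index)
        rec = clinical_group_association(x, labels)
        assert rec.p < 1e-6

    def test_three_groups_use_anova(self):
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(size=30), index=[f"S{i}" for i in range(30)],
                      name="G")
        labels = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10, index=x.index)
        rec = clinical_group_association(x, labels)
        assert rec.direction == "none" and 0 <= rec.p <= 1


class TestMarkerCorrelation:
    def test_scaled_copy_of_marker(self):
        rng = np.random.default_rng(6)
        marker = rng.uniform(1, 10, 40)
        arr = np.vstack([marker, marker * 3.5, rng.uniform(1, 10, 40)])
        em = _em(arr, genes=["MKI67", "G1", "G2"])
        recs = marker_correlation(em, ["G1", "G2"])
        by = {r.gene: r for r in recs}
        assert by["G1"].estimate == pytest.approx(1.0)
        assert by["G1"].direction == "+" and by["G1"].significant

    def test_marker_excluded_from_targets(self):
        rng = np.random.default_rng(7)
        em = _em(rng.uniform(1, 10, (2, 20)), genes=["MKI67", "G1"])
        recs = marker_correlation(em, ["MKI67", "G1"])
        assert [r.gene for r in recs] == ["G1"]

    def test_missing_marker_raises(self):
        rng = np.random.default_rng(8)
        em = _em(rng.uniform(1, 10, (2, 20)))
        with pytest.raises(KeyError, match="MKI67"):
            marker_correlation(em, ["G0"])

    def test_planted_loading_recovered(self, reference_cohort):
        truth = reference_cohort.truth
        spec = truth.spec
        planted = {g: q for g, q in truth.quadrant.items() if q != "none"}
        recs = marker_correlation(reference_cohort.tumor, list(planted))
        ok = sum(r.significant
                 and r.direction == ("+" if planted[r.gene][1] == "+" else "-")
                 for r in recs)
        assert ok >= 0.9 * len(planted)


class TestDependency:
    def test_background_arithmetic(self):
        screen = pd.DataFrame({"CL1": [0.9, 1.1, 1.0]},
                              index=["A", "B", "C"])
        assert dependency_background(screen)["CL1"] == pytest.approx(1.0)

    def test_background_shift_invariance(self):
        rng = np.random.default_rng(9)
        screen = pd.DataFrame(rng.normal(1, 0.1, size=(20, 15)),
                              index=[f"G{i}" for i in range(20)])
        shifted = screen + 0.7  # per-line constant cancels in the difference
        a = {r.gene: r.estimate for r in dependency_differences(screen)}
        b = {r.gene: r.estimate for r in dependency_differences(shifted)}
        for g in a:
            assert a[g] == pytest.approx(b[g], abs=1e-9)

    def test_planted_essential_gene(self):
        rng = np.random.default_rng(10)
        base = rng.normal(1.0, 0.02, size=(40, 100))
        screen = pd.DataFrame(base, index=[f"G{i}" for i in range(40)])
        screen.loc["G0"] -= 0.6
        rec = dependency_difference(screen, "G0")
        assert rec.estimate == pytest.approx(0.6, abs=0.05)
        assert rec.significant

    def test_direction_gate_one_sided(self):
        rng = np.random.default_rng(11)
        base = rng.normal(1.0, 0.02, size=(40, 100))
        screen = pd.DataFrame(base, index=[f"G{i}" for i in range(40)])
        screen.loc["G0"] += 0.6  # knockout increases proliferation
        rec = dependency_difference(screen, "G0")
        assert rec.estimate < 0 and not rec.significant


class TestPairedFeatureCorrelation:
    def test_identical_matrices_fully_concordant(self):
        rng = np.random.default_rng(12)
        arr = rng.uniform(1, 10, size=(10, 30))
        samples = [f"S{i}" for i in range(30)]
        mrna = _em(arr, "tumor", samples=samples)
        protein = _em(arr, "tumor", samples=samples)
        recs, percent = paired_feature_correlation(mrna, protein)
        assert percent == 100.0
        assert all(r.estimate == pytest.approx(1.0) for r in recs)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(13)
        samples = [f"S{i}" for i in range(100)]
        mrna = _em(rng.uniform(1, 10, size=(50, 100)), samples=samples)
        protein = _em(rng.uniform(1, 10, size=(50, 100)), samples=samples)
        _, percent = paired_feature_correlation(mrna, protein)
        assert percent <= 4.0

    def test_no_shared_samples_rejected(self):
        rng = np.random.default_rng(14)
        mrna = _em(rng.uniform(1, 10, (3, 10)), samples=[f"A{i}" for i in range(10)])
        protein = _em(rng.uniform(1, 10, (3, 10)), samples=[f"B{i}" for i in range(10)])
        with pytest.raises(ValueError):
            paired_feature_correlation(mrna, protein)
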