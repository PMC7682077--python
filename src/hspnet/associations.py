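"""Differential expression, clinical, proliferation and dependency scans.

Every scan emits :class:`AssociationRecord` rows in a common long format
(gene x cohort x endpoint), with BH-FDR applied within each
(cohort, endpoint) stratum and endpoint-specific significance gates:

* DE: |signed fold change| > 1.5 and FDR < 0.05, paired t on log2(x+1)
* OS: log-rank on a median split and/or univariate Cox, FDR < 0.05
* stage/grade/subtype: t-test (2 groups) or one-way ANOVA, FDR < 0.05
* marker (ki67) correlation: |Rs| > 0.2 and FDR < 0.05
* dependency screens: background-minus-gene difference > 0.5, FDR < 0.05
* mRNA-protein concordance: Rs > 0.3 and FDR < 0.05
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneFamilyCatalog
from .stats import (anova_oneway, bh_adjust, cox_ph, logrank, spearman, t_test)

log = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "FamilySummary",
    "records_to_frame",
    "signed_fold_change",
    "differential_expression",
    "family_summary",
    "survival_association",
    "survival_scan",
    "clinical_group_association",
    "clinical_group_scan",
    "marker_correlation",
    "dependency_background",
    "dependency_differences",
    "dependency_difference",
    "paired_feature_correlation",
]


@dataclass
class AssociationRecord:
    """One gene x cohort x endpoint result."""

    gene: str
    cohort: str
    endpoint: str  # DE | OS | stage | grade | subtype | marker_corr | dependency | mrna_protein
    estimate: float  # FC, Rs, HR or score difference, per endpoint
    p: float
    fdr: float = np.nan
    direction: str = "none"  # "+", "-", "none"
    significant: bool = False
    note: str = ""


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Long-format table: gene, cohort, endpoint, estimate, p, fdr, ..."""
    cols = ["gene", "cohort", "endpoint", "estimate", "p", "fdr",
            "direction", "significant", "note"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(r) for r in records])[cols]


def _apply_bh(records: list[AssociationRecord]) -> None:
    """BH within this list (one cohort x endpoint stratum), in place."""
    testable = [r for r in records if not np.isnan(r.p)]
    if not testable:
        return
    fdrs = bh_adjust([r.p for r in testable])
    for r, q in zip(testable, fdrs):
        r.fdr = float(q)


# ---------------------------------------------------------------------------
# differential expression


def signed_fold_change(mean_tumor: float, mean_normal: float) -> float:
    """Ratio of linear-scale means, negated when tumor is lower.

    FC = mean_T/mean_N when the ratio is >= 1, else -mean_N/mean_T, so
    |FC| > 1.5 gates up- and downregulation symmetrically and
    FC(tumor, normal) = -FC(normal, tumor) away from FC = +-1.
    """
    if mean_normal <= 0 or mean_tumor <= 0:
        raise ValueError("fold change needs positive means")
    r = mean_tumor / mean_normal
    return r if r >= 1.0 else -1.0 / r


def _pair_samples(tumor: ExpressionMatrix, normal: ExpressionMatrix
                  ) -> tuple[list[str], list[str]]:
    """Match tumor/normal columns by shared sample-id prefix."""
    def prefix(s: str) -> str:
        return s.rsplit("-", 1)[0]

    t_by = {prefix(s): s for s in tumor.samples}
    n_by = {prefix(s): s for s in normal.samples}
    shared = [p for p in t_by if p in n_by]
    dropped = (len(tumor.samples) - len(shared)) + (len(normal.samples) - len(shared))
    if dropped:
        log.info("cohort %s: dropped %d unpaired samples", tumor.cohort, dropped)
    return [t_by[p] for p in shared], [n_by[p] for p in shared]


def differential_expression(tumor: ExpressionMatrix, normal: ExpressionMatrix,
                            paired: bool = True, fc_min: float = 1.5,
                            fdr_max: float = 0.05, min_pairs: int = 5,
                            genes: list[str] | None = None
                            ) -> list[AssociationRecord]:
    """Tumor vs normal DE: signed FC from linear means, t-test on log2(x+1).

    Cohorts with fewer than ``min_pairs`` paired samples are skipped
    (returns an empty list with a logged reason).  Genes with a zero mean
    in either condition are flagged and excluded from testing.
    """
    if genes is None:
        genes = [g for g in tumor.genes if g in set(normal.genes)]
    if paired:
        t_cols, n_cols = _pair_samples(tumor, normal)
        if len(t_cols) < min_pairs:
            log.warning("cohort %s skipped: %d pairs < min_pairs=%d",
                        tumor.cohort, len(t_cols), min_pairs)
            return []
        t_vals = tumor.values.loc[genes, t_cols]
        n_vals = normal.values.loc[genes, n_cols]
    else:
        if min(tumor.n_samples, normal.n_samples) < min_pairs:
            log.warning("cohort %s skipped: < %d samples per condition",
                        tumor.cohort, min_pairs)
            return []
        t_vals = tumor.values.loc[genes]
        n_vals = normal.values.loc[genes]

    t_log = np.log2(t_vals + 1.0)
    n_log = np.log2(n_vals + 1.0)
    records: list[AssociationRecord] = []
    for g in genes:
        mt, mn = float(t_vals.loc[g].mean()), float(n_vals.loc[g].mean())
        if mt <= 0 or mn <= 0:
            records.append(AssociationRecord(
                g, tumor.cohort, "DE", np.nan, np.nan,
                note="zero mean, excluded"))
            continue
        fc = signed_fold_change(mt, mn)
        res = t_test(t_log.loc[g].to_numpy(), n_log.loc[g].to_numpy(),
                     paired=paired)
        records.append(AssociationRecord(
            g, tumor.cohort, "DE", fc, res.p_value,
            direction="+" if fc > 0 else "-",
            note=res.note))
    _apply_bh(records)
    for r in records:
        r.significant = (not np.isnan(r.fdr) and abs(r.estimate) > fc_min
                         and r.fdr < fdr_max)
    return records


@dataclass
class FamilySummary:
    """Up/down tallies of significant DE instances within one family."""

    family: str
    n_up: int
    n_down: int

    @property
    def total(self) -> int:
        return self.n_up + self.n_down

    @property
    def percent_up(self) -> float:
        return round(100.0 * self.n_up / self.total, 1) if self.total else 0.0

    @property
    def percent_down(self) -> float:
        return round(100.0 * self.n_down / self.total, 1) if self.total else 0.0


def family_summary(records: list[AssociationRecord],
                   catalog: GeneFamilyCatalog) -> list[FamilySummary]:
    """Per-family counts of significant up/down instances over all cohorts."""
    tallies: dict[str, list[int]] = {}
    for r in records:
        if not r.significant:
            continue
        if r.gene in catalog:
            fam = catalog.label(r.gene)
        else:
            fam = "unassigned"
            log.warning("gene %s not in catalog; counted as unassigned", r.gene)
        up_down = tallies.setdefault(fam, [0, 0])
        up_down[0 if r.direction == "+" else 1] += 1
    return [FamilySummary(fam, up, down)
            for fam, (up, down) in sorted(tallies.items())]


# ---------------------------------------------------------------------------
# survival and clinical groups


def survival_association(expr_gene: pd.Series, clinical: pd.DataFrame,
                         method: str = "logrank_median",
                         cohort: str = "", endpoint: str = "OS"
                         ) -> AssociationRecord:
    """Association between one gene's expression and overall survival.

    ``logrank_median`` dichotomizes at the median (ties to the low group);
    ``cox`` fits univariate proportional hazards on the continuous value.
    Direction "+" means higher expression, higher hazard.
    """
    gene = str(expr_gene.name)
    shared = expr_gene.index.intersection(clinical.index)
    x = expr_gene.loc[shared].to_numpy(dtype=float)
    time = clinical.loc[shared, "os_time"].to_numpy(dtype=float)
    event = clinical.loc[shared, "os_event"].to_numpy(dtype=int)
    if event.sum() < 2:
        return AssociationRecord(gene, cohort, endpoint, np.nan, np.nan,
                                 note="fewer than 2 events")
    if method == "logrank_median":
        med = np.median(x)
        high = x > med
        if not high.any() or high.all():
            return AssociationRecord(gene, cohort, endpoint, np.nan, np.nan,
                                     note="constant expression, no split")
        res = logrank(time[high], event[high], time[~high], event[~high])
        if res.degenerate:
            return AssociationRecord(gene, cohort, endpoint, np.nan, 1.0,
                                     note=res.note)
        # direction from the sign of the high-group event-rate excess
        km_high = event[high].sum() / max(time[high].sum(), 1e-12)
        km_low = event[~high].sum() / max(time[~high].sum(), 1e-12)
        direction = "+" if km_high > km_low else "-"
        return AssociationRecord(gene, cohort, endpoint, res.statistic,
                                 res.p_value, direction=direction)
    if method == "cox":
        res = cox_ph(time, event, x)
        if res.degenerate:
            return AssociationRecord(gene, cohort, endpoint, np.nan, 1.0,
                                     note=res.note)
        return AssociationRecord(gene, cohort, endpoint, res.estimate,
                                 res.p_value,
                                 direction="+" if res.estimate > 1 else "-")
    raise ValueError(f"unknown survival method: {method}")


def survival_scan(expr: ExpressionMatrix, clinical: pd.DataFrame,
                  genes: list[str], method: str = "logrank_median",
                  fdr_max: float = 0.05) -> list[AssociationRecord]:
    """Survival associations for many genes with BH within the cohort."""
    logx = expr.log2p1()
    records = [
        survival_association(logx.loc[g], clinical, method=method,
                             cohort=expr.cohort)
        for g in genes if g in expr.genes
    ]
    _apply_bh(records)
    for r in records:
        r.significant = not np.isnan(r.fdr) and r.fdr < fdr_max
    return records


def clinical_group_association(expr_gene: pd.Series, labels: pd.Series,
                               min_group: int = 5, cohort: str = "",
                               endpoint: str = "group") -> AssociationRecord | None:
    """t-test (2 groups) or one-way ANOVA (>2) across a categorical label.

    Groups smaller than ``min_group`` are dropped before testing; if
    fewer than two eligible groups remain the gene is skipped (None).
    """
    gene = str(expr_gene.name)
    shared = expr_gene.index.intersection(labels.dropna().index)
    x = expr_gene.loc[shared]
    lab = labels.loc[shared]
    groups = [x[lab == lev].to_numpy(dtype=float)
              for lev in lab.unique()]
    groups = [g for g in groups if len(g) >= min_group]
    if len(groups) < 2:
        log.info("gene %s: fewer than 2 eligible groups, skipped", gene)
        return None
    if len(groups) == 2:
        res = t_test(groups[0], groups[1], paired=False)
        direction = "+" if res.estimate > 0 else "-"
    else:
        res = anova_oneway(groups)
        direction = "none"
    p = 1.0 if res.degenerate else res.p_value
    return AssociationRecord(gene, cohort, endpoint, res.statistic, p,
                             direction=direction, note=res.note)


def clinical_group_scan(expr: ExpressionMatrix, labels: pd.Series,
                        genes: list[str], endpoint: str,
                        min_group: int = 5, fdr_max: float = 0.05
                        ) -> list[AssociationRecord]:
    logx = expr.log2p1()
    records = []
    for g in genes:
        if g not in expr.genes:
            continue
        rec = clinical_group_association(logx.loc[g], labels,
                                         min_group=min_group,
                                         cohort=expr.cohort, endpoint=endpoint)
        if rec is not None:
            records.append(rec)
    _apply_bh(records)
    for r in records:
        r.significant = not np.isnan(r.fdr) and r.fdr < fdr_max
    return records


# ---------------------------------------------------------------------------
# proliferation marker and dependency screens


def marker_correlation(expr: ExpressionMatrix, target_genes: list[str],
                       marker_gene: str = "MKI67", rs_min: float = 0.2,
                       fdr_max: float = 0.05) -> list[AssociationRecord]:
    """Spearman of each target gene against the proliferation marker."""
    if marker_gene not in expr.genes:
        raise KeyError(f"marker gene {marker_gene!r} absent from matrix")
    marker = expr.values.loc[marker_gene].to_numpy(dtype=float)
    records = []
    for g in target_genes:
        if g == marker_gene or g not in expr.genes:
            continue
        res = spearman(expr.values.loc[g].to_numpy(dtype=float), marker)
        records.append(AssociationRecord(
            g, expr.cohort, "marker_corr", res.estimate,
            res.p_value if not res.degenerate else 1.0,
            direction="+" if res.estimate > 0 else "-",
            note=res.note))
    _apply_bh(records)
    for r in records:
        r.significant = (not np.isnan(r.fdr) and abs(r.estimate) > rs_min
                         and r.fdr < fdr_max)
    return records


def dependency_background(screen: pd.DataFrame) -> pd.Series:
    """Per-cell-line background: mean score over all assayed genes."""
    if screen.shape[0] < 2:
        raise ValueError("screen needs >= 2 genes per line")
    if screen.isna().any().any():
        raise ValueError("screen contains missing scores")
    return screen.mean(axis=0)


def dependency_differences(screen: pd.DataFrame, genes: list[str] | None = None,
                           diff_min: float = 0.5, fdr_max: float = 0.05,
                           cohort: str = "screen") -> list[AssociationRecord]:
    """Background-minus-gene proliferation differences with BH across genes.

    A positive difference means knockout of the gene lowers proliferation
    below the per-line background; the significance gate is one-sided in
    that direction (difference > diff_min), as the screens are insensitive
    to the opposite tail.
    """
    background = dependency_background(screen)
    if genes is None:
        genes = list(screen.index)
    records = []
    for g in genes:
        if g not in screen.index:
            continue
        s = screen.loc[g]
        ok = s.notna()
        if ok.sum() < 2:
            records.append(AssociationRecord(g, cohort, "dependency",
                                             np.nan, np.nan,
                                             note="gene in < 2 lines"))
            continue
        diff = float((background[ok] - s[ok]).mean())
        res = t_test(s[ok].to_numpy(dtype=float),
                     background[ok].to_numpy(dtype=float), paired=True)
        records.append(AssociationRecord(
            g, cohort, "dependency", diff,
            res.p_value if not res.degenerate else 1.0,
            direction="+" if diff > 0 else "-", note=res.note))
    _apply_bh(records)
    for r in records:
        r.significant = (not np.isnan(r.fdr) and r.estimate > diff_min
                         and r.fdr < fdr_max)
    return records


def dependency_difference(screen: pd.DataFrame, gene: str,
                          diff_min: float = 0.5, fdr_max: float = 0.05,
                          cohort: str = "screen") -> AssociationRecord:
    """Single-gene view of :func:`dependency_differences` (FDR across all genes)."""
    if gene not in screen.index:
        raise KeyError(f"gene {gene!r} absent from screen")
    records = dependency_differences(screen, diff_min=diff_min,
                                     fdr_max=fdr_max, cohort=cohort)
    return next(r for r in records if r.gene == gene)


# ---------------------------------------------------------------------------
# mRNA-protein concordance


def paired_feature_correlation(mrna: ExpressionMatrix, protein: ExpressionMatrix,
                               rs_min: float = 0.3, fdr_max: float = 0.05
                               ) -> tuple[list[AssociationRecord], float]:
    """Per-gene Spearman between mRNA and protein over shared samples.

    Returns the records plus the percent of tested genes that pass the
    Rs > rs_min and FDR < fdr_max concordance gate (1 d.p.).
    """
    shared = mrna.samples.intersection(protein.samples)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    genes = [g for g in mrna.genes if g in set(protein.genes)]
    records = []
    for g in genes:
        res = spearman(mrna.values.loc[g, shared].to_numpy(dtype=float),
                       protein.values.loc[g, shared].to_numpy(dtype=float))
        records.append(AssociationRecord(
            g, mrna.cohort, "mrna_protein", res.estimate,
            res.p_value if not res.degenerate else 1.0,
            direction="+" if res.estimate > 0 else "-", note=res.note))
    _apply_bh(records)
    for r in records:
        r.significant = (not np.isnan(r.fdr) and r.estimate > rs_min
                         and r.fdr < fdr_max)
    n_sig = sum(r.significant for r in records)
    percent = round(100.0 * n_sig / len(records), 1) if records else 0.0
    return records, percent
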