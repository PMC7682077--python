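"""Signature scores and a weighted-KS gene-set enrichment (GSEA) engine.

Three formula-defined sample scores:

* EMT score: mean log2 expression of the mesenchymal set minus mean of
  the epithelial set, per sample (higher = more mesenchymal).
* generic signature score: mean across set genes of per-gene z-scored
  log2 expression (used for hallmark programs whose scoring the source
  datasets do not pin down further).

The enrichment engine follows the classic weighted Kolmogorov-Smirnov
construction: rank genes by signal-to-noise between a high and a low
phenotype group (median split of one gene's expression), walk the ranked
list accumulating |metric|^p for set hits and a constant penalty for
misses, and take the maximum signed deviation as the enrichment score
(ES).  Significance comes from phenotype-label (or same-size random set)
permutations, with the conventional same-sign NES normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet
from .associations import AssociationRecord, _apply_bh
from .stats import bh_adjust, spearman

log = logging.getLogger(__name__)

__all__ = [
    "EmtSignature",
    "EnrichmentResult",
    "emt_score",
    "median_split",
    "rank_metric",
    "gsea_es",
    "gsea_significance",
    "signature_score",
    "score_correlation",
    "score_correlation_scan",
]


@dataclass(frozen=True)
class EmtSignature:
    """Disjoint epithelial and mesenchymal gene sets."""

    epithelial: frozenset[str]
    mesenchymal: frozenset[str]

    def __post_init__(self) -> None:
        if not self.epithelial or not self.mesenchymal:
            raise ValueError("both sets must be non-empty")
        if self.epithelial & self.mesenchymal:
            raise ValueError("epithelial and mesenchymal sets overlap")

    @classmethod
    def from_sets(cls, epithelial: GeneSet, mesenchymal: GeneSet) -> "EmtSignature":
        return cls(frozenset(epithelial.genes), frozenset(mesenchymal.genes))


def emt_score(expr: ExpressionMatrix, sig: EmtSignature) -> pd.Series:
    """Per-sample EMT score: mean(mesenchymal) - mean(epithelial) on log2(x+1).

    Genes missing from the matrix are logged and dropped; a signature set
    entirely absent is an error.
    """
    logx = expr.log2p1()
    mes = [g for g in sig.mesenchymal if g in expr.genes]
    epi = [g for g in sig.epithelial if g in expr.genes]
    n_missing = (len(sig.mesenchymal) - len(mes)) + (len(sig.epithelial) - len(epi))
    if n_missing:
        log.warning("cohort %s: %d EMT signature genes absent", expr.cohort,
                    n_missing)
    if not mes or not epi:
        raise ValueError("an EMT signature set is entirely absent from the matrix")
    score = logx.loc[mes].mean(axis=0) - logx.loc[epi].mean(axis=0)
    score.name = "EMT"
    return score


def median_split(expr_gene: pd.Series) -> pd.Series:
    """Split samples at the median of one gene: > median -> "high", else "low"."""
    x = expr_gene.to_numpy(dtype=float)
    if len(x) < 4:
        raise ValueError("median split needs >= 4 samples")
    if np.ptp(x) == 0:
        raise ValueError(f"constant expression for {expr_gene.name!r}: no split")
    med = np.median(x)
    labels = np.where(x > med, "high", "low")
    if (labels == "high").sum() == 0:
        # median equals the maximum (heavy ties): put strict max in high
        raise ValueError(f"degenerate split for {expr_gene.name!r}")
    return pd.Series(labels, index=expr_gene.index, name=expr_gene.name)


def rank_metric(values: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Signal-to-noise ranking metric, sorted descending.

    (mean_high - mean_low) / (sd_high + sd_low), with each sd floored at
    max(0.2 * |group mean|, 0.2) as in the classic GSEA implementation, so
    low-variance genes cannot dominate the ranking.
    """
    high = groups.index[groups == "high"]
    low = groups.index[groups == "low"]
    if len(high) < 3 or len(low) < 3:
        raise ValueError("each phenotype group needs >= 3 samples")
    h = values[high].to_numpy(dtype=float)
    l = values[low].to_numpy(dtype=float)
    mh, ml = h.mean(axis=1), l.mean(axis=1)
    sh = np.maximum(h.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mh), 0.2))
    sl = np.maximum(l.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(ml), 0.2))
    metric = pd.Series((mh - ml) / (sh + sl), index=values.index, name="s2n")
    return metric.sort_values(ascending=False, kind="mergesort")


def gsea_es(ranked: pd.Series, gene_set: GeneSet | frozenset[str] | set[str],
            weight: float = 1.0) -> float:
    """Enrichment score of a gene set on a ranked, descending metric.

    Running sum with hit increments |r_j|^weight / sum over hits of
    |r|^weight and miss increments 1/(N - N_H); the ES is the deviation of
    maximum magnitude (signed).  ES is always in [-1, 1].
    """
    members = gene_set.genes if isinstance(gene_set, GeneSet) else gene_set
    hits = ranked.index.isin(members)
    n_h = int(hits.sum())
    n = len(ranked)
    if n_h == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_h == n:
        raise ValueError("gene set covers the entire ranked list")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit metrics zero: fall back to unweighted steps
        hit_inc = hits / n_h
    else:
        hit_inc = hit_w / denom
    miss_inc = np.where(hits, 0.0, 1.0 / (n - n_h))
    running = np.cumsum(hit_inc - miss_inc)
    max_pos = float(running.max())
    min_neg = float(running.min())
    # equal-magnitude peaks are broken toward the positive deviation
    return max_pos if max_pos + min_neg >= -1e-12 else min_neg


@dataclass
class EnrichmentResult:
    """GSEA outcome for one phenotype gene x gene set."""

    phenotype_gene: str
    cohort: str
    gene_set: str
    es: float
    nes: float
    p: float
    fdr: float
    n_perm: int
    seed: int

    @property
    def direction(self) -> str:
        return "+" if self.es > 0 else "-"


def gsea_significance(values: pd.DataFrame, groups: pd.Series,
                      gene_set: GeneSet, n_perm: int = 1000,
                      perm_type: str = "phenotype", seed: int = 0,
                      weight: float = 1.0, phenotype_gene: str = "",
                      cohort: str = "") -> EnrichmentResult:
    """Observed ES with a permutation null.

    ``phenotype`` permutations relabel the high/low groups; ``gene_set``
    permutations draw random same-size sets from the ranked universe.
    Nominal p counts null ES at least as extreme with the same sign, with
    a +1 correction; NES divides by the mean |null ES| of the same sign.
    """
    if n_perm < 100:
        log.warning("n_perm=%d is low; permutation p-values will be coarse",
                    n_perm)
    ranked = rank_metric(values, groups)
    obs = gsea_es(ranked, gene_set, weight=weight)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    if perm_type == "phenotype":
        labels = groups.to_numpy().copy()
        for i in range(n_perm):
            rng.shuffle(labels)
            perm_groups = pd.Series(labels, index=groups.index)
            null[i] = gsea_es(rank_metric(values, perm_groups), gene_set,
                              weight=weight)
    elif perm_type == "gene_set":
        members = (gene_set.genes if isinstance(gene_set, GeneSet)
                   else frozenset(gene_set))
        size = len(ranked.index.intersection(list(members)))
        universe = np.asarray(ranked.index)
        for i in range(n_perm):
            pick = rng.choice(len(universe), size=size, replace=False)
            null[i] = gsea_es(ranked, frozenset(universe[pick]), weight=weight)
    else:
        raise ValueError(f"unknown perm_type: {perm_type}")

    same_sign = null[np.sign(null) == np.sign(obs)] if obs != 0 else null
    if len(same_sign) == 0:
        p = 1.0 / (1.0 + n_perm)
        nes = np.nan
    else:
        p = (1.0 + (np.abs(same_sign) >= abs(obs)).sum()) / (1.0 + len(same_sign))
        nes = obs / np.abs(same_sign).mean()
    name = gene_set.name if isinstance(gene_set, GeneSet) else "set"
    return EnrichmentResult(phenotype_gene=phenotype_gene, cohort=cohort,
                            gene_set=name, es=obs, nes=float(nes), p=float(p),
                            fdr=np.nan, n_perm=n_perm, seed=seed)


def adjust_enrichment(results: list[EnrichmentResult],
                      fdr_max: float = 0.05) -> list[EnrichmentResult]:
    """BH across phenotype genes within a cohort, in place."""
    if not results:
        return results
    fdrs = bh_adjust([r.p for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results


def signature_score(expr: ExpressionMatrix,
                    gene_set: GeneSet | frozenset[str] | set[str],
                    name: str = "") -> pd.Series:
    """Per-sample mean of z-scored (across samples) log2 expression of a set."""
    members = gene_set.genes if isinstance(gene_set, GeneSet) else gene_set
    present = [g for g in members if g in expr.genes]
    if not present:
        raise ValueError("signature set entirely absent from the matrix")
    if len(present) < len(members):
        log.warning("cohort %s: %d signature genes absent", expr.cohort,
                    len(members) - len(present))
    logx = expr.log2p1().loc[present]
    sd = logx.std(axis=1, ddof=0)
    centered = logx.sub(logx.mean(axis=1), axis=0)
    z = centered.div(sd.replace(0.0, 1.0), axis=0)
    score = z.mean(axis=0)
    score.name = name or (gene_set.name if isinstance(gene_set, GeneSet)
                          else "signature")
    return score


def score_correlation(expr_gene: pd.Series, scores: pd.Series,
                      rs_min: float = 0.3, fdr_max: float = 0.05,
                      cohort: str = "", endpoint: str = "score_corr"
                      ) -> AssociationRecord | None:
    """Spearman of one gene's expression against a per-sample score.

    Returns None (skipped) with fewer than 10 shared samples.  For a
    single test the BH-adjusted FDR equals the nominal p.
    """
    shared = expr_gene.index.intersection(scores.index)
    if len(shared) < 10:
        log.info("gene %s: %d shared samples < 10, skipped", expr_gene.name,
                 len(shared))
        return None
    res = spearman(expr_gene.loc[shared].to_numpy(dtype=float),
                   scores.loc[shared].to_numpy(dtype=float))
    rec = AssociationRecord(
        str(expr_gene.name), cohort, endpoint, res.estimate,
        res.p_value if not res.degenerate else 1.0,
        fdr=res.p_value if not res.degenerate else 1.0,
        direction="+" if res.estimate > 0 else "-", note=res.note)
    rec.significant = abs(rec.estimate) > rs_min and rec.fdr < fdr_max
    return rec


def score_correlation_scan(expr: ExpressionMatrix, scores: pd.Series,
                           genes: list[str], rs_min: float = 0.3,
                           fdr_max: float = 0.05,
                           endpoint: str = "score_corr"
                           ) -> list[AssociationRecord]:
    """Score correlations for many genes with BH within the cohort."""
    records = []
    for g in genes:
        if g not in expr.genes:
            continue
        rec = score_correlation(expr.values.loc[g], scores, rs_min=rs_min,
                                fdr_max=fdr_max, cohort=expr.cohort,
                                endpoint=endpoint)
        if rec is not None:
            rec.fdr = np.nan
            records.append(rec)
    _apply_bh(records)
    for r in records:
        r.significant = (not np.isnan(r.fdr) and abs(r.estimate) > rs_min
                         and r.fdr < fdr_max)
    return records
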