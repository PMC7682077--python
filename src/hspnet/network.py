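"""Per-cohort co-expression networks and tumor/normal disruption tests.

An edge is a gene pair whose Spearman correlation passes Rs > rs_min and
BH-FDR < fdr_max within one cohort (the signed, positive-Rs rule; an
absolute-value mode is available behind a flag).  Disruption of the tumor
network relative to normal is quantified as the edge-count fold decrease
and tested against a sample-size-matched subsampling null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, canonical_pair
from .stats import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "CoexpressionNetwork",
    "NetworkComparison",
    "ResamplingNull",
    "pairwise_spearman",
    "build_network",
    "compare_networks",
    "resampling_null",
    "ppi_overlap",
    "fold_decrease",
    "overlap_percent",
]


def pairwise_spearman(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman Rs and two-sided t-approximation p (genes x genes).

    Vectorized: midrank-transform each gene across samples, then Pearson
    on ranks; identical to the scalar routine in :mod:`hspnet.stats`.
    Zero-variance genes get Rs = 0, p = 1 against everything.
    """
    n = values.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples for correlation")
    ranks = sps.rankdata(values.to_numpy(), axis=1)
    sd = ranks.std(axis=1)
    ok = sd > 0
    ranks_c = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.where(ok, sd * n ** 0.5, 1.0)
    z = ranks_c / denom[:, None]
    rs = z @ z.T
    rs = np.clip(rs, -1.0, 1.0)
    rs[~ok, :] = 0.0
    rs[:, ~ok] = 0.0
    np.fill_diagonal(rs, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rs * np.sqrt((n - 2) / (1.0 - rs ** 2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(p)] = 0.0  # |rs| == 1 limit
    p[~ok, :] = 1.0
    p[:, ~ok] = 1.0
    genes = values.index
    return (pd.DataFrame(rs, index=genes, columns=genes),
            pd.DataFrame(p, index=genes, columns=genes))


@dataclass
class CoexpressionNetwork:
    """Significant co-expression edges for one cohort and condition."""

    cohort: str
    condition: str
    pairs: pd.DataFrame  # all tested pairs: gene_a, gene_b, rs, p, fdr, edge
    n_samples: int
    rs_min: float
    fdr_max: float

    @property
    def edges(self) -> pd.DataFrame:
        return self.pairs[self.pairs["edge"]]

    @property
    def n_edges(self) -> int:
        return int(self.pairs["edge"].sum())

    def edge_set(self) -> set[tuple[str, str]]:
        return {canonical_pair(a, b)
                for a, b in zip(self.edges["gene_a"], self.edges["gene_b"])}


def build_network(expr: ExpressionMatrix, genes: list[str] | None = None,
                  rs_min: float = 0.3, fdr_max: float = 0.05,
                  min_samples: int = 10, use_abs: bool = False
                  ) -> CoexpressionNetwork | None:
    """Test all gene pairs and keep those passing the Rs and FDR gates.

    BH adjustment runs over all tested pairs within this one cohort.
    Cohorts with fewer than ``min_samples`` samples are skipped (returns
    None with a logged reason).  Genes absent from the matrix are logged
    and dropped.
    """
    if expr.n_samples < min_samples:
        log.warning("cohort %s/%s skipped: %d samples < min_samples=%d",
                    expr.cohort, expr.condition, expr.n_samples, min_samples)
        return None
    if genes is None:
        keep = list(expr.genes)
    else:
        keep = [g for g in genes if g in expr.genes]
        missing = sorted(set(genes) - set(keep))
        if missing:
            log.warning("cohort %s/%s: %d catalog genes absent, skipped: %s...",
                        expr.cohort, expr.condition, len(missing), missing[:5])
    if len(keep) < 2:
        raise ValueError("need >= 2 genes present to build a network")
    sub = expr.values.loc[keep]
    rs, p = pairwise_spearman(sub)
    iu = np.triu_indices(len(keep), k=1)
    rs_flat = rs.to_numpy()[iu]
    p_flat = p.to_numpy()[iu]
    fdr = bh_adjust(p_flat)
    strength = np.abs(rs_flat) if use_abs else rs_flat
    edge = (strength > rs_min) & (fdr < fdr_max)
    ga = np.asarray(keep)[iu[0]]
    gb = np.asarray(keep)[iu[1]]
    swap = ga > gb  # canonical order
    ga2 = np.where(swap, gb, ga)
    gb2 = np.where(swap, ga, gb)
    pairs = pd.DataFrame({"gene_a": ga2, "gene_b": gb2, "rs": rs_flat,
                          "p": p_flat, "fdr": fdr, "edge": edge})
    return CoexpressionNetwork(cohort=expr.cohort, condition=expr.condition,
                               pairs=pairs, n_samples=expr.n_samples,
                               rs_min=rs_min, fdr_max=fdr_max)


def fold_decrease(n_normal_edges: int, n_tumor_edges: int) -> float:
    """Normal/tumor edge-count ratio, rounded to 2 d.p. for reporting."""
    if n_tumor_edges == 0:
        return float("inf")
    return round(n_normal_edges / n_tumor_edges, 2)


@dataclass
class NetworkComparison:
    """Per-pair tumor/normal edge classification and the disruption ratio."""

    cohort: str
    classes: pd.DataFrame  # gene_a, gene_b, class
    counts: dict[str, int]
    n_tumor_edges: int
    n_normal_edges: int
    fold_decrease: float

    @property
    def tumor_specific_pairs(self) -> set[tuple[str, str]]:
        sel = self.classes[self.classes["class"] == "tumor_only"]
        return {canonical_pair(a, b)
                for a, b in zip(sel["gene_a"], sel["gene_b"])}


def compare_networks(tumor_net: CoexpressionNetwork,
                     normal_net: CoexpressionNetwork) -> NetworkComparison:
    """Classify every tested pair as tumor_only/normal_only/shared/neither."""
    key = ["gene_a", "gene_b"]
    t = tumor_net.pairs.set_index(key)["edge"]
    n = normal_net.pairs.set_index(key)["edge"]
    if not t.index.equals(n.index):
        if set(t.index) != set(n.index):
            raise ValueError("networks were built on different gene universes")
        n = n.reindex(t.index)
    cls = np.select(
        [t & n, t & ~n, ~t & n],
        ["shared", "tumor_only", "normal_only"],
        default="neither",
    )
    classes = t.index.to_frame(index=False)
    classes["class"] = cls
    counts = classes["class"].value_counts().to_dict()
    for c in ("shared", "tumor_only", "normal_only", "neither"):
        counts.setdefault(c, 0)
    n_t, n_n = tumor_net.n_edges, normal_net.n_edges
    if n_t == 0:
        log.warning("cohort %s: zero tumor edges, fold decrease infinite",
                    tumor_net.cohort)
    return NetworkComparison(
        cohort=tumor_net.cohort, classes=classes, counts=counts,
        n_tumor_edges=n_t, n_normal_edges=n_n,
        fold_decrease=fold_decrease(n_n, n_t))


@dataclass
class ResamplingNull:
    """Size-matched subsampling null for the tumor/normal edge deficit.

    Each iteration subsamples the larger condition (without replacement)
    down to the smaller one's sample size, rebuilds both networks at that
    common size and records both edge counts.  The empirical p is the
    +1-corrected fraction of iterations in which the normal network is no
    larger than the tumor network.
    """

    n_iter: int
    seed: int
    subsample_size: int
    normal_counts: np.ndarray
    tumor_counts: np.ndarray
    empirical_p: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(1, self.n_iter + 1),
            "n_edges_normal_sub": self.normal_counts,
            "n_edges_tumor_sub": self.tumor_counts,
        })


def resampling_null(tumor_expr: ExpressionMatrix, normal_expr: ExpressionMatrix,
                    genes: list[str] | None = None, n_iter: int = 1000,
                    seed: int = 0, rs_min: float = 0.3, fdr_max: float = 0.05,
                    min_samples: int = 10, use_abs: bool = False
                    ) -> ResamplingNull:
    m = min(tumor_expr.n_samples, normal_expr.n_samples)
    if m < min_samples:
        raise ValueError(f"common sample size {m} < min_samples={min_samples}")

    def count_edges(expr: ExpressionMatrix, cols: np.ndarray) -> int:
        sub = ExpressionMatrix(expr.values.iloc[:, cols],
                               condition=expr.condition, cohort=expr.cohort)
        net = build_network(sub, genes=genes, rs_min=rs_min, fdr_max=fdr_max,
                            min_samples=min_samples, use_abs=use_abs)
        return net.n_edges

    n_counts = np.empty(n_iter, dtype=int)
    t_counts = np.empty(n_iter, dtype=int)
    for it in range(n_iter):
        rng = np.random.default_rng([seed, it])
        t_cols = (np.arange(tumor_expr.n_samples)
                  if tumor_expr.n_samples == m
                  else rng.choice(tumor_expr.n_samples, size=m, replace=False))
        n_cols = (np.arange(normal_expr.n_samples)
                  if normal_expr.n_samples == m
                  else rng.choice(normal_expr.n_samples, size=m, replace=False))
        t_counts[it] = count_edges(tumor_expr, t_cols)
        n_counts[it] = count_edges(normal_expr, n_cols)
    p = (1 + int((n_counts <= t_counts).sum())) / (1 + n_iter)
    return ResamplingNull(n_iter=n_iter, seed=seed, subsample_size=m,
                          normal_counts=n_counts, tumor_counts=t_counts,
                          empirical_p=p)


def overlap_percent(overlap: int, total: int) -> float:
    """100 * overlap / total, rounded to 1 d.p."""
    if total == 0:
        raise ValueError("total must be positive")
    return round(100.0 * overlap / total, 1)


def ppi_overlap(pairs: CoexpressionNetwork | set[tuple[str, str]],
                ppi: set[tuple[str, str]]) -> tuple[int, int, float]:
    """Fraction of co-expressed pairs backed by a known interaction."""
    if isinstance(pairs, CoexpressionNetwork):
        pair_set = pairs.edge_set()
    else:
        pair_set = {canonical_pair(*p) for p in pairs}
    if not pair_set:
        raise ValueError("empty co-expression pair set")
    ppi_canon = {canonical_pair(*p) for p in ppi}
    overlap = len(pair_set & ppi_canon)
    total = len(pair_set)
    return overlap, total, overlap_percent(overlap, total)
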