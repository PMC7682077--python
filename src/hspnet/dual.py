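"""Dual-function calls: joint direction of a gene's hallmark associations.

A gene that is significantly associated with two hallmark axes in the
same cohort gets a quadrant label, e.g. P+M- = promotes proliferation
while suppressing EMT/metastasis.  The module also tallies consistent vs
opposite instances (with a chi-square test against a configurable
expectation), builds the gene x hallmark x cohort direction matrix, and
applies the >= 5-hallmark consistent-direction filter used to shortlist
broad promoter/suppressor candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .associations import AssociationRecord
from .stats import TestResult, chi_square_gof

__all__ = [
    "DualFunctionCall",
    "ConsistencyTally",
    "classify_dual",
    "tally_consistency",
    "build_direction_matrix",
    "consistent_direction_filter",
]

QUADRANTS = ("P+M+", "P+M-", "P-M+", "P-M-")
CONSISTENT = {"P+M+", "P-M-"}
OPPOSITE = {"P+M-", "P-M+"}


@dataclass
class DualFunctionCall:
    gene: str
    cohort: str
    axis1: str
    dir1: str
    axis2: str
    dir2: str
    quadrant: str  # one of QUADRANTS or "none"


def _index_records(records: list[AssociationRecord]) -> dict[tuple[str, str],
                                                             AssociationRecord]:
    out: dict[tuple[str, str], AssociationRecord] = {}
    for r in records:
        key = (r.gene, r.cohort)
        if key in out:
            prev = out[key]
            if (prev.direction, prev.significant) != (r.direction, r.significant):
                raise ValueError(f"conflicting duplicate records for {key}")
        out[key] = r
    return out


def classify_dual(prolif: list[AssociationRecord],
                  emt: list[AssociationRecord],
                  axis1: str = "proliferation", axis2: str = "EMT"
                  ) -> list[DualFunctionCall]:
    """Quadrant per (gene, cohort) where both axes are significant."""
    p_idx = _index_records(prolif)
    e_idx = _index_records(emt)
    calls = []
    for key in sorted(set(p_idx) | set(e_idx)):
        gene, cohort = key
        pr, er = p_idx.get(key), e_idx.get(key)
        if pr is not None and er is not None and pr.significant and er.significant:
            quadrant = (f"P{'+' if pr.direction == '+' else '-'}"
                        f"M{'+' if er.direction == '+' else '-'}")
            calls.append(DualFunctionCall(gene, cohort, axis1, pr.direction,
                                          axis2, er.direction, quadrant))
        else:
            calls.append(DualFunctionCall(
                gene, cohort, axis1,
                pr.direction if pr is not None and pr.significant else "none",
                axis2,
                er.direction if er is not None and er.significant else "none",
                "none"))
    return calls


@dataclass
class ConsistencyTally:
    """Counts of consistent (P+M+/P-M-) vs opposite (P+M-/P-M+) instances."""

    n_consistent: int
    n_opposite: int
    per_quadrant: dict[str, int]
    per_gene_cohorts: dict[str, int]
    chi2: TestResult | None = None

    @property
    def total(self) -> int:
        return self.n_consistent + self.n_opposite


def tally_consistency(calls: list[DualFunctionCall],
                      expected_proportions=None) -> ConsistencyTally:
    """Tally called quadrants; chi-square GOF on (opposite, consistent).

    The default expectation is 1:1.  With no called instances the test is
    skipped and only zero tallies are returned.
    """
    per_q = {q: 0 for q in QUADRANTS}
    per_gene: dict[str, int] = {}
    for c in calls:
        if c.quadrant == "none":
            continue
        per_q[c.quadrant] += 1
        per_gene[c.gene] = per_gene.get(c.gene, 0) + 1
    n_cons = per_q["P+M+"] + per_q["P-M-"]
    n_opp = per_q["P+M-"] + per_q["P-M+"]
    chi2 = None
    if n_cons + n_opp > 0:
        chi2 = chi_square_gof([n_opp, n_cons], expected_proportions)
    return ConsistencyTally(n_consistent=n_cons, n_opposite=n_opp,
                            per_quadrant=per_q, per_gene_cohorts=per_gene,
                            chi2=chi2)


def build_direction_matrix(records_per_hallmark: dict[str, list[AssociationRecord]]
                           ) -> pd.DataFrame:
    """Gene x cohort x hallmark direction table ("+", "-", "none").

    Rows are indexed by (gene, cohort); direction comes from significant
    records only.  Duplicate (gene, hallmark, cohort) entries are errors.
    """
    cells: dict[tuple[str, str], dict[str, str]] = {}
    for hallmark, records in records_per_hallmark.items():
        seen: set[tuple[str, str]] = set()
        for r in records:
            key = (r.gene, r.cohort)
            if key in seen:
                raise ValueError(
                    f"duplicate record for {r.gene}/{hallmark}/{r.cohort}")
            seen.add(key)
            cells.setdefault(key, {})[hallmark] = (
                r.direction if r.significant else "none")
    hallmarks = list(records_per_hallmark)
    index = pd.MultiIndex.from_tuples(sorted(cells), names=["gene", "cohort"])
    mat = pd.DataFrame("none", index=index, columns=hallmarks)
    for (gene, cohort), row in cells.items():
        for hallmark, direction in row.items():
            mat.loc[(gene, cohort), hallmark] = direction
    return mat


def consistent_direction_filter(matrix: pd.DataFrame, min_hallmarks: int = 5,
                                strict: bool = False) -> pd.DataFrame:
    """Genes with a consistent direction of effect in >= min_hallmarks hallmarks.

    A hallmark counts toward a direction when the gene shows that
    direction in at least one cohort.  ``strict`` additionally requires no
    opposing cohort anywhere for that hallmark.  Output is ranked by
    (hallmark count, total cohort instances), one row per gene x direction.
    """
    rows = []
    for direction in ("+", "-"):
        opposite = "-" if direction == "+" else "+"
        for gene, sub in matrix.groupby(level="gene"):
            n_hallmarks = 0
            n_instances = 0
            for hallmark in matrix.columns:
                col = sub[hallmark]
                n_dir = int((col == direction).sum())
                n_opp = int((col == opposite).sum())
                if n_dir >= 1 and not (strict and n_opp > 0):
                    n_hallmarks += 1
                    n_instances += n_dir
            if n_hallmarks >= min_hallmarks:
                rows.append({"gene": gene, "direction": direction,
                             "n_hallmarks": n_hallmarks,
                             "n_instances": n_instances})
    out = pd.DataFrame(rows, columns=["gene", "direction", "n_hallmarks",
                                      "n_instances"])
    if len(out):
        out = out.sort_values(["direction", "n_hallmarks", "n_instances", "gene"],
                              ascending=[True, False, False, True],
                              kind="mergesort").reset_index(drop=True)
        out["rank"] = (out.groupby("direction").cumcount() + 1)
    else:
        out["rank"] = pd.Series(dtype=int)
    return out
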