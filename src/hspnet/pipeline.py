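"""End-to-end orchestration of the analysis stages from a JSON config.

Stage order: catalog -> co-expression networks -> DE/clinical ->
marker/dependency -> EMT scores/enrichment -> hallmarks -> dual-function.
All randomness fans out from one master seed through a per-stage counter
scheme, so any stage rerun in isolation sees identical randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations as assoc
from . import dual as dualmod
from . import network as net
from . import signatures as sig
from .io import (ExpressionMatrix, FormatError, load_catalog, read_clinical,
                 read_expression, read_gmt, read_ppi)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run", "stage_seed", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = {
    "rs_coexpr": 0.3,
    "rs_marker": 0.2,
    "rs_score": 0.3,
    "fc": 1.5,
    "fdr": 0.05,
    "diff": 0.5,
    "min_samples": 10,
    "min_pairs": 5,
    "min_group": 5,
}

STAGES = ("coexpr", "de", "clinical", "prolif", "emt", "hallmarks", "dual")
GROUP_ENDPOINTS = ("stage", "grade", "subtype")


@dataclass
class PipelineConfig:
    """Resolved run configuration (see ``PipelineConfig.from_json``)."""

    cohorts: dict[str, dict[str, str]]  # cohort -> {tumor, normal, clinical, dependency}
    out_dir: str
    catalog: str = "default"
    gene_sets: str | None = None  # GMT with EPITHELIAL/MESENCHYMAL [+ hallmarks]
    epithelial_set: str = "EPITHELIAL"
    mesenchymal_set: str = "MESENCHYMAL"
    ppi: str | None = None
    thresholds: dict = field(default_factory=dict)
    n_resample: int = 1000
    n_perm: int = 1000
    gsea_genes: list[str] | None = None  # phenotype genes for GSEA (None: skip)
    stratify_by: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for k, v in self.thresholds.items():
            if v <= 0:
                raise ValueError(f"threshold {k} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohorts" not in raw or "out_dir" not in raw:
            raise ValueError("config requires 'cohorts' and 'out_dir'")
        return cls(**raw)

    def resolved(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str, cohort: str = "") -> int:
    """Deterministic per-(stage, cohort) seed derived from the master seed."""
    digest = hashlib.sha256(f"{stage}:{cohort}".encode()).digest()
    counter = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence([master_seed, counter])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stage_rows: dict[str, int] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    wall_clock_s: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=1, sort_keys=True))


def _read_cohort(name: str, paths: dict[str, str], stage: str):
    try:
        tumor = (read_expression(paths["tumor"], "tumor", name)
                 if "tumor" in paths else None)
        normal = (read_expression(paths["normal"], "normal", name)
                  if "normal" in paths else None)
        clinical = read_clinical(paths["clinical"]) if "clinical" in paths else None
        dependency = (pd.read_csv(paths["dependency"], sep="\t", index_col=0)
                      if "dependency" in paths else None)
    except (FormatError, FileNotFoundError, OSError) as exc:
        raise FormatError(f"stage {stage}, cohort {name}: {exc}") from exc
    return tumor, normal, clinical, dependency


def run(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> RunReport:
    """Execute the configured stages; writes TSV outputs plus report.json."""
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)
    th = config.thresholds

    catalog = load_catalog(config.catalog)
    genes = catalog.genes
    gene_sets = {}
    if config.gene_sets:
        if not Path(config.gene_sets).exists():
            raise FormatError(f"gene set file not found: {config.gene_sets}")
        gene_sets = {s.name: s for s in read_gmt(config.gene_sets)}
    ppi = read_ppi(config.ppi) if config.ppi else None

    all_records: list[assoc.AssociationRecord] = []
    prolif_records: dict[str, list] = {}
    emt_records: dict[str, list] = {}
    hallmark_records: dict[str, list] = {}
    enrich_rows: list[dict] = []
    score_rows: list[pd.DataFrame] = []

    for cohort, paths in config.cohorts.items():
        tumor, normal, clinical, dependency = _read_cohort(cohort, paths, "load")

        if "coexpr" in stages and tumor is not None and normal is not None:
            _stage_coexpr(config, cohort, tumor, normal, genes, ppi, out, report)

        if "de" in stages and tumor is not None and normal is not None:
            recs = assoc.differential_expression(
                tumor, normal, fc_min=th["fc"], fdr_max=th["fdr"],
                min_pairs=th["min_pairs"], genes=[g for g in genes
                                                  if g in tumor.genes])
            if not recs:
                report.skipped.append(f"de:{cohort}: too few pairs")
            all_records.extend(recs)
            report.stage_rows["de"] = report.stage_rows.get("de", 0) + len(recs)

        if "clinical" in stages and tumor is not None and clinical is not None:
            for method, tag in (("logrank_median", "OS"), ("cox", "OS_cox")):
                recs = assoc.survival_scan(tumor, clinical, genes,
                                           method=method, fdr_max=th["fdr"])
                for r in recs:
                    r.endpoint = tag
                all_records.extend(recs)
                report.stage_rows["clinical"] = (
                    report.stage_rows.get("clinical", 0) + len(recs))
            for col in GROUP_ENDPOINTS:
                if col in clinical.columns:
                    recs = assoc.clinical_group_scan(
                        tumor, clinical[col], genes, endpoint=col,
                        min_group=th["min_group"], fdr_max=th["fdr"])
                    all_records.extend(recs)
                    report.stage_rows["clinical"] = (
                        report.stage_rows.get("clinical", 0) + len(recs))

        if "prolif" in stages and tumor is not None:
            recs = assoc.marker_correlation(tumor, genes,
                                            rs_min=th["rs_marker"],
                                            fdr_max=th["fdr"])
            prolif_records[cohort] = recs
            all_records.extend(recs)
            report.stage_rows["prolif"] = (
                report.stage_rows.get("prolif", 0) + len(recs))
            if dependency is not None:
                dep_recs = assoc.dependency_differences(
                    dependency, genes=[g for g in genes
                                       if g in dependency.index],
                    diff_min=th["diff"], fdr_max=th["fdr"], cohort=cohort)
                all_records.extend(dep_recs)
                report.stage_rows["prolif"] += len(dep_recs)

        if "emt" in stages and tumor is not None and gene_sets:
            _stage_emt(config, cohort, tumor, genes, gene_sets, emt_records,
                       all_records, enrich_rows, score_rows, report)

        if "hallmarks" in stages and tumor is not None and gene_sets:
            for set_name, gs in gene_sets.items():
                if set_name in (config.epithelial_set, config.mesenchymal_set):
                    continue
                scores = sig.signature_score(tumor, gs, name=set_name)
                score_rows.append(_score_frame(cohort, scores))
                recs = sig.score_correlation_scan(
                    tumor, scores, genes, rs_min=th["rs_score"],
                    fdr_max=th["fdr"], endpoint=f"hallmark:{set_name}")
                hallmark_records.setdefault(set_name, []).extend(recs)
                all_records.extend(recs)
                report.stage_rows["hallmarks"] = (
                    report.stage_rows.get("hallmarks", 0) + len(recs))

        if config.stratify_by and clinical is not None and tumor is not None:
            _stratified_runs(config, cohort, tumor, clinical, genes, gene_sets,
                             stages, all_records, report)

    if "dual" in stages:
        _stage_dual(config, prolif_records, emt_records, hallmark_records,
                    out, report)

    frame = assoc.records_to_frame(all_records)
    frame.to_csv(out / "associations.tsv", sep="\t", index=False)
    if "de" in stages:
        fams = assoc.family_summary(
            [r for r in all_records if r.endpoint == "DE"], catalog)
        pd.DataFrame([{"family": f.family, "n_up": f.n_up, "n_down": f.n_down,
                       "percent_up": f.percent_up, "percent_down": f.percent_down}
                      for f in fams]).to_csv(out / "family_summary.tsv",
                                             sep="\t", index=False)
    if enrich_rows:
        pd.DataFrame(enrich_rows).to_csv(out / "enrichment.tsv", sep="\t",
                                         index=False)
    if score_rows:
        pd.concat(score_rows).to_csv(out / "scores.tsv", sep="\t", index=False)

    report.wall_clock_s = round(time.monotonic() - t0, 2)
    report.to_json(out / "report.json")
    return report


def _score_frame(cohort: str, scores: pd.Series) -> pd.DataFrame:
    return pd.DataFrame({"cohort": cohort, "sample": scores.index,
                         "score_name": scores.name, "value": scores.values})


def _stage_coexpr(config, cohort, tumor, normal, genes, ppi, out, report):
    th = config.thresholds
    nets = {}
    for expr in (tumor, normal):
        network = net.build_network(expr, genes=genes, rs_min=th["rs_coexpr"],
                                    fdr_max=th["fdr"],
                                    min_samples=th["min_samples"])
        if network is None:
            report.skipped.append(
                f"coexpr:{cohort}/{expr.condition}: < min_samples")
            return
        nets[expr.condition] = network
        network.pairs.to_csv(out / f"network_{cohort}_{expr.condition}.tsv",
                             sep="\t", index=False)
    comparison = net.compare_networks(nets["tumor"], nets["normal"])
    comparison.classes.to_csv(out / f"network_classes_{cohort}.tsv",
                              sep="\t", index=False)
    null = net.resampling_null(
        tumor, normal, genes=genes, n_iter=config.n_resample,
        seed=stage_seed(config.seed, "coexpr", cohort),
        rs_min=th["rs_coexpr"], fdr_max=th["fdr"],
        min_samples=th["min_samples"])
    null.as_frame().to_csv(out / f"resampling_{cohort}.tsv", sep="\t",
                           index=False)
    summary = {
        "cohort": cohort,
        "n_edges_tumor": comparison.n_tumor_edges,
        "n_edges_normal": comparison.n_normal_edges,
        "fold_decrease": comparison.fold_decrease,
        "resampling_p": null.empirical_p,
        "counts": comparison.counts,
    }
    if ppi is not None and nets["normal"].n_edges > 0:
        ov, total, pct = net.ppi_overlap(nets["normal"], ppi)
        summary["ppi_overlap"] = {"overlap": ov, "total": total,
                                  "percent": pct}
    (out / f"network_summary_{cohort}.json").write_text(
        json.dumps(summary, indent=1))
    report.stage_rows["coexpr"] = (report.stage_rows.get("coexpr", 0)
                                   + len(comparison.classes))


def _stage_emt(config, cohort, tumor, genes, gene_sets, emt_records,
               all_records, enrich_rows, score_rows, report):
    th = config.thresholds
    try:
        emt_sig = sig.EmtSignature.from_sets(gene_sets[config.epithelial_set],
                                             gene_sets[config.mesenchymal_set])
    except KeyError as exc:
        raise FormatError(f"EMT gene set missing from GMT: {exc}") from exc
    scores = sig.emt_score(tumor, emt_sig)
    score_rows.append(_score_frame(cohort, scores))
    recs = sig.score_correlation_scan(tumor, scores, genes,
                                      rs_min=th["rs_score"],
                                      fdr_max=th["fdr"], endpoint="EMT_score")
    emt_records[cohort] = recs
    all_records.extend(recs)
    report.stage_rows["emt"] = report.stage_rows.get("emt", 0) + len(recs)

    if config.gsea_genes:
        mes_set = gene_sets[config.mesenchymal_set]
        results = []
        for g in config.gsea_genes:
            if g not in tumor.genes:
                continue
            try:
                groups = sig.median_split(tumor.values.loc[g])
            except ValueError:
                report.skipped.append(f"emt-gsea:{cohort}:{g}: no median split")
                continue
            res = sig.gsea_significance(
                tumor.log2p1(), groups, mes_set, n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"gsea:{g}", cohort),
                phenotype_gene=g, cohort=cohort)
            results.append(res)
        sig.adjust_enrichment(results, fdr_max=th["fdr"])
        enrich_rows.extend(vars(r) for r in results)
        report.stage_rows["emt_gsea"] = (
            report.stage_rows.get("emt_gsea", 0) + len(results))


def _stratified_runs(config, cohort, tumor, clinical, genes, gene_sets,
                     stages, all_records, report):
    """Per-stratum reruns of the association stages (subtype analog)."""
    th = config.thresholds
    col = config.stratify_by
    if col not in clinical.columns:
        report.skipped.append(f"stratify:{cohort}: no column {col!r}")
        return
    for stratum, members in clinical.groupby(col).groups.items():
        samples = [s for s in members if s in set(tumor.samples)]
        if len(samples) < th["min_samples"]:
            report.skipped.append(f"stratify:{cohort}:{stratum}: too small")
            continue
        sub = ExpressionMatrix(tumor.values[samples], condition="tumor",
                               cohort=f"{cohort}@{stratum}")
        if "prolif" in stages:
            recs = assoc.marker_correlation(sub, genes,
                                            rs_min=th["rs_marker"],
                                            fdr_max=th["fdr"])
            all_records.extend(recs)
        if "emt" in stages and gene_sets:
            emt_sig = sig.EmtSignature.from_sets(
                gene_sets[config.epithelial_set],
                gene_sets[config.mesenchymal_set])
            scores = sig.emt_score(sub, emt_sig)
            recs = sig.score_correlation_scan(sub, scores, genes,
                                              rs_min=th["rs_score"],
                                              fdr_max=th["fdr"],
                                              endpoint="EMT_score")
            all_records.extend(recs)
        report.stage_rows["stratified"] = (
            report.stage_rows.get("stratified", 0) + len(samples))


def _stage_dual(config, prolif_records, emt_records, hallmark_records, out,
                report):
    all_calls: list[dualmod.DualFunctionCall] = []
    for cohort in prolif_records:
        if cohort not in emt_records:
            continue
        all_calls.extend(dualmod.classify_dual(prolif_records[cohort],
                                               emt_records[cohort]))
    calls_frame = pd.DataFrame(
        [vars(c) for c in all_calls],
        columns=["gene", "cohort", "axis1", "dir1", "axis2", "dir2",
                 "quadrant"])
    calls_frame.to_csv(out / "dual_calls.tsv", sep="\t", index=False)
    tally = dualmod.tally_consistency(all_calls)
    tally_payload = {
        "n_consistent": tally.n_consistent,
        "n_opposite": tally.n_opposite,
        "per_quadrant": tally.per_quadrant,
        "chi2": (None if tally.chi2 is None
                 else {"statistic": tally.chi2.statistic,
                       "p": tally.chi2.p_value}),
    }
    (out / "dual_tally.json").write_text(json.dumps(tally_payload, indent=1))

    per_hallmark: dict[str, list] = {}
    prolif_all = [r for recs in prolif_records.values() for r in recs]
    emt_all = [r for recs in emt_records.values() for r in recs]
    if prolif_all:
        per_hallmark["proliferation"] = prolif_all
    if emt_all:
        per_hallmark["EMT"] = emt_all
    for name, recs in hallmark_records.items():
        per_hallmark[name] = recs
    if per_hallmark:
        matrix = dualmod.build_direction_matrix(per_hallmark)
        matrix.to_csv(out / "direction_matrix.tsv", sep="\t")
        candidates = dualmod.consistent_direction_filter(
            matrix, min_hallmarks=min(5, len(per_hallmark)))
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        report.stage_rows["dual"] = len(calls_frame)
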