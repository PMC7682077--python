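"""Synthetic paired tumor/normal cohorts with planted, recoverable structure.

The generator emulates the shape of the public inputs the pipeline is
designed for (paired expression matrices, clinical tables, knockout
dependency screens, signature gene sets) with a log-normal latent-factor
model:

    log2 x_gs = baseline_g + a_g * Fp_s + b_g * Fe_s + block_gs + eps_gs

where ``Fp`` (proliferation) and ``Fe`` (EMT) are standard-normal
per-sample factors, ``block_gs`` is an equicorrelated Gaussian module term
(one correlation per module per condition, so tumor-side disruption is a
single knob ``rho_tumor < rho_normal``), and ``eps`` is N(0, noise_sd^2).
Tumor samples additionally receive planted log2 fold changes.  Expression
is 2**(log-signal), hence nonnegative like RSEM/TPM.

Everything planted is emitted beside the data as a :class:`SyntheticTruth`
so every downstream stage can be scored for recovery.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    canonical_pair,
    load_catalog,
    write_clinical,
    write_expression,
    write_gmt,
)

__all__ = [
    "CoexprBlock",
    "SurvivalSpec",
    "DependencySpec",
    "SyntheticCohortSpec",
    "SyntheticTruth",
    "SyntheticCohort",
    "default_spec",
    "generate_cohort",
    "emit_fixture_bundle",
    "population_spearman",
]

MARKER_GENE = "MKI67"


class SpecError(ValueError):
    """Raised for invalid synthetic-cohort specifications."""


@dataclass
class CoexprBlock:
    """A planted co-expression module with per-condition equicorrelation."""

    members: list[str]
    rho_normal: float
    rho_tumor: float

    def __post_init__(self) -> None:
        for rho in (self.rho_normal, self.rho_tumor):
            if not 0.0 <= rho < 1.0:
                raise SpecError(f"block rho must be in [0, 1): {rho}")
        if len(self.members) < 2:
            raise SpecError("block needs >= 2 members")


@dataclass
class SurvivalSpec:
    """Exponential survival with expression-linked log-hazards.

    Hazard for sample s is baseline_hazard * exp(sum_g coeff_g * z_gs)
    with z the per-gene standardized log2 expression.  Censoring times are
    independent exponentials with rate chosen so each sample is censored
    with probability ``censoring_rate``.
    """

    baseline_hazard: float = 0.002  # events per day
    coefficients: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.3


@dataclass
class DependencySpec:
    """Knockout screen: score = 1 - essentiality_g + N(0, 0.1^2) per line.

    Higher score means more proliferation after knockout, so essential
    genes (positive essentiality effect) sit below the per-line background.
    """

    n_cell_lines: int = 100
    essentiality: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticCohortSpec:
    n_tumor: int
    n_normal: int
    family_genes: list[str]
    background_genes: list[str]
    epithelial_genes: list[str]
    mesenchymal_genes: list[str]
    coexpr_blocks: list[CoexprBlock] = field(default_factory=list)
    de_effects: dict[str, float] = field(default_factory=dict)  # log2 FC in tumor
    prolif_loadings: dict[str, float] = field(default_factory=dict)
    emt_loadings: dict[str, float] = field(default_factory=dict)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    dependency: DependencySpec = field(default_factory=DependencySpec)
    noise_sd: float = 1.0
    block_scale: float = 3.0  # marginal SD of the module term
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    marker_gene: str = MARKER_GENE
    marker_noise_sd: float = 0.0  # the marker reads the factor directly
    cohort: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be > 0")
        seen: set[str] = set()
        for blk in self.coexpr_blocks:
            overlap = seen.intersection(blk.members)
            if overlap:
                raise SpecError(f"blocks share members: {sorted(overlap)}")
            seen.update(blk.members)
        if set(self.epithelial_genes) & set(self.mesenchymal_genes):
            raise SpecError("epithelial and mesenchymal sets overlap")

    @property
    def genes(self) -> list[str]:
        """All generated genes, in a fixed deterministic order."""
        return (
            list(self.family_genes)
            + [self.marker_gene]
            + list(self.background_genes)
            + list(self.epithelial_genes)
            + list(self.mesenchymal_genes)
        )

    def loading_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(prolif, emt) loading vectors aligned with :attr:`genes`."""
        genes = self.genes
        a = np.array([self.prolif_loadings.get(g, 0.0) for g in genes])
        b = np.array([self.emt_loadings.get(g, 0.0) for g in genes])
        a[genes.index(self.marker_gene)] = 1.0
        for g in self.epithelial_genes:
            b[genes.index(g)] = -1.0
        for g in self.mesenchymal_genes:
            b[genes.index(g)] = +1.0
        return a, b


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted beside the simulated data."""

    spec: SyntheticCohortSpec
    edges: list[dict]  # within-block pairs with per-condition rho
    de_direction: dict[str, str]  # gene -> "+"/"-"
    quadrant: dict[str, str]  # family gene -> e.g. "P+M-" or "none"
    essential_genes: list[str]

    def planted_pairs(self, condition: str, rs_min: float = 0.3,
                      genes: list[str] | None = None) -> set[tuple[str, str]]:
        """Pairs whose generative population Spearman exceeds ``rs_min``.

        Includes both module pairs and latent-factor-induced pairs, so a
        recovered edge only counts as false when the generating model
        really puts its correlation at or below the threshold.
        """
        genes = genes if genes is not None else self.spec.family_genes
        rho = population_spearman(self.spec, condition, genes)
        pairs: set[tuple[str, str]] = set()
        for i, gi in enumerate(genes):
            for j in range(i + 1, len(genes)):
                if rho.iat[i, j] > rs_min:
                    pairs.add(canonical_pair(gi, genes[j]))
        return pairs

    def block_pairs(self, min_rho: float = 0.0, condition: str = "normal"
                    ) -> set[tuple[str, str]]:
        """Within-block pairs whose planted rho exceeds ``min_rho``."""
        key = f"rho_{condition}"
        return {
            canonical_pair(e["gene_a"], e["gene_b"])
            for e in self.edges if e[key] > min_rho
        }

    def to_jsonable(self) -> dict:
        return {
            "edges": self.edges,
            "de_direction": self.de_direction,
            "quadrant": self.quadrant,
            "essential_genes": self.essential_genes,
        }


@dataclass
class SyntheticCohort:
    tumor: ExpressionMatrix
    normal: ExpressionMatrix
    clinical: pd.DataFrame
    dependency: pd.DataFrame
    truth: SyntheticTruth


def default_spec(seed: int = 0, n_tumor: int = 350, n_normal: int = 400,
                 n_background: int = 500, n_signature: int = 50) -> SyntheticCohortSpec:
    """The package's reference study conditions.

    82 family genes (packaged catalog order) plus the proliferation marker,
    500 background genes and 50+50 epithelial/mesenchymal signature genes;
    three 10-gene co-expression modules, two of them disrupted in tumor;
    twenty dual-function genes (five per quadrant, |loading| = 0.5); ten
    up- and ten down-regulated genes at |log2 FC| = 1; survival linked to
    one up- and one down-regulated gene; five essential genes in a
    100-line knockout screen.
    """
    fam = load_catalog("default").genes
    bg = [f"BG{i:04d}" for i in range(1, n_background + 1)]
    epi = [f"EP{i:04d}" for i in range(1, n_signature + 1)]
    mes = [f"ME{i:04d}" for i in range(1, n_signature + 1)]

    blocks = [
        CoexprBlock(fam[0:10], rho_normal=0.7, rho_tumor=0.1),
        CoexprBlock(fam[10:20], rho_normal=0.6, rho_tumor=0.6),
        CoexprBlock(fam[20:30], rho_normal=0.6, rho_tumor=0.1),
    ]
    prolif: dict[str, float] = {}
    emt: dict[str, float] = {}
    quadrant_signs = [(+1, +1), (+1, -1), (-1, +1), (-1, -1)]
    for q, (sp, se) in enumerate(quadrant_signs):
        for g in fam[30 + 5 * q: 35 + 5 * q]:
            prolif[g] = 0.5 * sp
            emt[g] = 0.5 * se
    # 30 background genes carry the proliferation program (hallmark set)
    for g in bg[0:30]:
        prolif[g] = 0.5

    de = {g: +1.0 for g in fam[50:60]}
    de.update({g: -1.0 for g in fam[60:70]})

    surv = SurvivalSpec(coefficients={fam[50]: 0.8, fam[60]: -0.8})
    dep = DependencySpec(n_cell_lines=100,
                         essentiality={g: 0.8 for g in fam[70:75]})
    return SyntheticCohortSpec(
        n_tumor=n_tumor, n_normal=n_normal,
        family_genes=fam, background_genes=bg,
        epithelial_genes=epi, mesenchymal_genes=mes,
        coexpr_blocks=blocks, de_effects=de,
        prolif_loadings=prolif, emt_loadings=emt,
        survival=surv, dependency=dep, seed=seed,
    )


def hallmark_sets(spec: SyntheticCohortSpec) -> list[GeneSet]:
    """Signature sets shipped with a fixture bundle.

    PROLIFERATION collects the background genes carrying the proliferation
    program; STRESS is a size-matched null set of unloaded background
    genes (a negative control hallmark).
    """
    pr = [g for g in spec.background_genes if spec.prolif_loadings.get(g, 0.0) != 0]
    rest = [g for g in spec.background_genes if g not in set(pr)]
    sets = [
        GeneSet("EPITHELIAL", frozenset(spec.epithelial_genes), "planted epithelial"),
        GeneSet("MESENCHYMAL", frozenset(spec.mesenchymal_genes), "planted mesenchymal"),
    ]
    if pr:
        sets.append(GeneSet("PROLIFERATION", frozenset(pr), "planted proliferation"))
    if len(rest) >= len(pr) and pr:
        sets.append(GeneSet("STRESS", frozenset(rest[: len(pr)]), "null control set"))
    return sets


# ---------------------------------------------------------------------------
# generation


def _log2_signal(spec: SyntheticCohortSpec, n: int, condition: str,
                 baseline: np.ndarray, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log2-scale expression (genes x samples) plus the latent factors."""
    genes = spec.genes
    idx = {g: i for i, g in enumerate(genes)}
    a, b = spec.loading_vectors()
    fp = rng.standard_normal(n)
    fe = rng.standard_normal(n)
    sig = baseline[:, None] + np.outer(a, fp) + np.outer(b, fe)

    for blk in spec.coexpr_blocks:
        rho = blk.rho_normal if condition == "normal" else blk.rho_tumor
        shared = rng.standard_normal(n)
        idio = rng.standard_normal((len(blk.members), n))
        term = np.sqrt(rho) * shared[None, :] + np.sqrt(1.0 - rho) * idio
        rows = [idx[g] for g in blk.members]
        sig[rows, :] += spec.block_scale * term

    noise = rng.standard_normal(sig.shape) * spec.noise_sd
    noise[idx[spec.marker_gene], :] = (
        rng.standard_normal(n) * spec.marker_noise_sd)
    sig += noise
    if condition == "tumor":
        for g, lfc in spec.de_effects.items():
            sig[idx[g], :] += lfc
    return sig, fp, fe


def _truth_from_spec(spec: SyntheticCohortSpec) -> SyntheticTruth:
    edges = []
    for blk in spec.coexpr_blocks:
        for i, gi in enumerate(blk.members):
            for gj in blk.members[i + 1:]:
                ga, gb = canonical_pair(gi, gj)
                edges.append({"gene_a": ga, "gene_b": gb,
                              "rho_normal": blk.rho_normal,
                              "rho_tumor": blk.rho_tumor})
    de_dir = {g: ("+" if lfc > 0 else "-")
              for g, lfc in spec.de_effects.items() if lfc != 0}
    quadrant = {}
    for g in spec.family_genes:
        a = spec.prolif_loadings.get(g, 0.0)
        b = spec.emt_loadings.get(g, 0.0)
        if a != 0 and b != 0:
            quadrant[g] = f"P{'+' if a > 0 else '-'}M{'+' if b > 0 else '-'}"
        else:
            quadrant[g] = "none"
    essential = [g for g, e in spec.dependency.essentiality.items() if e > 0]
    return SyntheticTruth(spec=spec, edges=edges, de_direction=de_dir,
                          quadrant=quadrant, essential_genes=essential)


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate one paired cohort; a fixed seed gives identical outputs."""
    ss = np.random.SeedSequence(spec.seed)
    s_base, s_norm, s_tum, s_surv, s_dep = ss.spawn(5)
    genes = spec.genes

    baseline = (spec.baseline_mean
                + spec.baseline_sd
                * np.random.default_rng(s_base).standard_normal(len(genes)))

    sig_n, _, _ = _log2_signal(spec, spec.n_normal, "normal", baseline,
                               np.random.default_rng(s_norm))
    sig_t, _, _ = _log2_signal(spec, spec.n_tumor, "tumor", baseline,
                               np.random.default_rng(s_tum))

    normal_ids = [f"P{i:04d}-N" for i in range(1, spec.n_normal + 1)]
    tumor_ids = [f"P{i:04d}-T" for i in range(1, spec.n_tumor + 1)]
    normal = ExpressionMatrix(
        pd.DataFrame(np.exp2(sig_n), index=genes, columns=normal_ids),
        condition="normal", cohort=spec.cohort)
    tumor = ExpressionMatrix(
        pd.DataFrame(np.exp2(sig_t), index=genes, columns=tumor_ids),
        condition="tumor", cohort=spec.cohort)

    clinical = _simulate_clinical(spec, tumor, np.random.default_rng(s_surv))
    dependency = _simulate_dependency(spec, np.random.default_rng(s_dep))
    return SyntheticCohort(tumor=tumor, normal=normal, clinical=clinical,
                           dependency=dependency, truth=_truth_from_spec(spec))


def _simulate_clinical(spec: SyntheticCohortSpec, tumor: ExpressionMatrix,
                       rng: np.random.Generator) -> pd.DataFrame:
    logx = tumor.log2p1()
    n = tumor.n_samples
    eta = np.zeros(n)
    for g, coef in spec.survival.coefficients.items():
        v = logx.loc[g].to_numpy()
        sd = v.std()
        if sd > 0:
            eta += coef * (v - v.mean()) / sd
    lam = spec.survival.baseline_hazard * np.exp(eta)
    event_t = rng.exponential(1.0 / lam)
    c = spec.survival.censoring_rate
    if c > 0:
        censor_t = rng.exponential((1.0 - c) / (c * lam))
        os_time = np.minimum(event_t, censor_t)
        os_event = (event_t <= censor_t).astype(int)
    else:
        os_time, os_event = event_t, np.ones(n, dtype=int)

    # stage tracks the proliferation program, subtype the EMT program:
    # aggressive (high-Fp) tumors are later stage, mesenchymal tumors
    # form their own subtype.
    marker = logx.loc[spec.marker_gene].to_numpy()
    stage = pd.cut(pd.Series(marker).rank(method="first"),
                   bins=3, labels=["I", "II", "III"]).astype(str)
    emt_proxy = (logx.loc[spec.mesenchymal_genes].mean()
                 - logx.loc[spec.epithelial_genes].mean()).to_numpy()
    subtype = np.where(emt_proxy > np.median(emt_proxy), "mesenchymal",
                       "epithelial")
    return pd.DataFrame(
        {"os_time": np.round(os_time, 1), "os_event": os_event,
         "stage": stage.to_numpy(), "subtype": subtype},
        index=pd.Index(tumor.samples, name="sample"))


def _simulate_dependency(spec: SyntheticCohortSpec,
                         rng: np.random.Generator) -> pd.DataFrame:
    genes = list(spec.family_genes) + list(spec.background_genes)
    ess = np.array([spec.dependency.essentiality.get(g, 0.0) for g in genes])
    n_lines = spec.dependency.n_cell_lines
    scores = (1.0 - ess[:, None]
              + rng.standard_normal((len(genes), n_lines)) * 0.1)
    cols = [f"CL{i:04d}" for i in range(1, n_lines + 1)]
    return pd.DataFrame(scores, index=genes, columns=cols)


# ---------------------------------------------------------------------------
# population correlation oracle


def population_spearman(spec: SyntheticCohortSpec, condition: str,
                        genes: list[str]) -> pd.DataFrame:
    """Population Spearman matrix among ``genes`` on the generating model.

    The log-scale model is jointly Gaussian, so population Pearson
    correlations follow from the loadings/blocks/noise, and Spearman is
    obtained through the Gaussian-copula rank relation
    rho_s = (6/pi) * arcsin(rho/2).
    """
    all_genes = spec.genes
    idx = {g: i for i, g in enumerate(all_genes)}
    a, b = spec.loading_vectors()
    k = len(all_genes)
    cov = np.outer(a, a) + np.outer(b, b)
    for blk in spec.coexpr_blocks:
        rho = blk.rho_normal if condition == "normal" else blk.rho_tumor
        rows = [idx[g] for g in blk.members]
        s2 = spec.block_scale ** 2
        for i in rows:
            for j in rows:
                cov[i, j] += s2 * (1.0 if i == j else rho)
    noise = np.full(k, spec.noise_sd ** 2)
    noise[idx[spec.marker_gene]] = spec.marker_noise_sd ** 2
    cov[np.diag_indices(k)] += noise
    sd = np.sqrt(np.diag(cov))
    pearson = cov / np.outer(sd, sd)
    rows = [idx[g] for g in genes]
    sub = np.clip(pearson[np.ix_(rows, rows)], -1.0, 1.0)
    spear = (6.0 / np.pi) * np.arcsin(sub / 2.0)
    return pd.DataFrame(spear, index=genes, columns=genes)


# ---------------------------------------------------------------------------
# fixture bundles


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def emit_fixture_bundle(spec: SyntheticCohortSpec, out_dir: str | Path) -> dict:
    """Write a complete on-disk fixture bundle; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec)

    paths = {
        "tumor_expression": out / "tumor_expression.tsv",
        "normal_expression": out / "normal_expression.tsv",
        "clinical": out / "clinical.tsv",
        "dependency": out / "dependency.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    write_expression(cohort.tumor, paths["tumor_expression"])
    write_expression(cohort.normal, paths["normal_expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    dep = cohort.dependency.copy()
    dep.index.name = "gene"
    dep.to_csv(paths["dependency"], sep="\t")
    write_gmt(hallmark_sets(spec), paths["gene_sets"])
    paths["truth"].write_text(
        json.dumps(cohort.truth.to_jsonable(), indent=1, sort_keys=True))

    manifest = {
        "cohort": spec.cohort,
        "seed": spec.seed,
        "files": {k: {"path": str(p), "sha256": _sha256(p)}
                  for k, p in paths.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
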