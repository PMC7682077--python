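"""Readers and writers for the tabular formats the pipeline touches.

All on-disk formats are plain text: tab-separated tables (expression
matrices, clinical tables, gene-family catalogs, PPI edge lists) and GMT
gene-set files.  Gene symbols are matched exactly and case-sensitively;
no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSet",
    "GeneFamilyCatalog",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "load_catalog",
    "write_catalog",
    "read_clinical",
    "write_clinical",
    "read_ppi",
    "write_ppi",
    "canonical_pair",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format or invariants."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return an unordered gene pair in canonical (lexicographic) order."""
    if a == b:
        raise FormatError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values for one cohort and condition.

    Values are nonnegative, in whatever unit the source cohort uses
    (RSEM/TPM/FPKM); units are cohort-local and never compared across
    datasets.
    """

    values: pd.DataFrame  # index: gene symbols, columns: sample ids
    condition: str  # "tumor" | "normal"
    cohort: str

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate gene row: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample column: {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric expression values")
        if not np.isfinite(arr).all():
            raise FormatError("non-finite expression values")
        if (arr < 0).any():
            raise FormatError("negative expression values")
        if not self.condition:
            raise FormatError("condition tag required")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2p1(self) -> pd.DataFrame:
        """log2(x + 1) transform, the scale used for t-tests and scoring."""
        return np.log2(self.values + 1.0)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. an epithelial or hallmark signature)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("gene set requires a name")
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneFamilyCatalog:
    """Mapping of gene symbol to (family, subfamily).

    The finest classification label (subfamily where present, family
    otherwise) is the unit used for family-level tallies, mirroring how
    chaperone families/sub-families are conventionally counted.
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sub_to_fam: dict[str, str] = {}
        for gene, (fam, sub) in self.entries.items():
            if not fam:
                raise FormatError(f"gene {gene!r} has no family label")
            if sub:
                if sub_to_fam.setdefault(sub, fam) != fam:
                    raise FormatError(
                        f"subfamily {sub!r} assigned to more than one family"
                    )

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    def label(self, gene: str) -> str:
        """Finest family label for a gene (subfamily if present)."""
        fam, sub = self.entries[gene]
        return sub or fam

    def family_sizes(self, by: str = "finest") -> dict[str, int]:
        """Tally of genes per family.

        by="finest" counts subfamilies separately (the 9-group view);
        by="family" collapses subfamilies into their parent family.
        """
        sizes: dict[str, int] = {}
        for gene, (fam, sub) in self.entries.items():
            key = (sub or fam) if by == "finest" else fam
            sizes[key] = sizes.get(key, 0) + 1
        return sizes

    def members(self, label: str) -> list[str]:
        return [g for g in self.entries if self.label(g) == label
                or self.entries[g][0] == label]


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path, condition: str, cohort: str) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene symbols, header sample ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed header / ragged rows
        raise FormatError(f"{path}: cannot parse expression TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise FormatError(f"{path}: non-numeric column {non_numeric[0]!r}")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df, condition=condition, cohort=cohort)


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    out = em.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name TAB description TAB member TAB member ..."""
    sets: list[GeneSet] = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
        name, desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        uniq = list(dict.fromkeys(members))
        if len(uniq) < len(members):
            log.warning("%s:%d: deduplicated %d repeated members in %r",
                        path, lineno, len(members) - len(uniq), name)
        sets.append(GeneSet(name=name, genes=frozenset(uniq), description=desc))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# gene-family catalog


def load_catalog(path: str | Path = "default") -> GeneFamilyCatalog:
    """Load a gene,family,subfamily TSV; "default" loads the packaged catalog.

    The packaged catalog is a reference list of 82 chaperone genes in 9
    families/sub-families; it is editable data, not code, and every
    analysis takes the catalog as an explicit input.
    """
    if str(path) == "default":
        ref = resources.files("hspnet.data").joinpath("hsp_catalog.tsv")
        with resources.as_file(ref) as p:
            return load_catalog(p)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "family"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: catalog requires columns gene,family[,subfamily]")
    if "subfamily" not in df.columns:
        df["subfamily"] = ""
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"{path}: duplicate gene {dup!r} in catalog")
    entries = {
        str(r.gene): (str(r.family), str(r.subfamily))
        for r in df.itertuples(index=False)
    }
    return GeneFamilyCatalog(entries=entries)


def write_catalog(cat: GeneFamilyCatalog, path: str | Path) -> None:
    rows = [(g, fam, sub) for g, (fam, sub) in cat.entries.items()]
    pd.DataFrame(rows, columns=["gene", "family", "subfamily"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical tables


REQUIRED_CLINICAL = ("sample", "os_time", "os_event")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with columns sample, os_time, os_event [, extras]."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing clinical columns {missing}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise FormatError(f"{path}: duplicate sample {dup!r}")
    if (df["os_time"] < 0).any():
        raise FormatError(f"{path}: negative OS time")
    if not df["os_event"].isin([0, 1]).all():
        raise FormatError(f"{path}: os_event must be 0/1")
    df["sample"] = df["sample"].astype(str)
    return df.set_index("sample")


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# PPI edge lists


def read_ppi(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column TSV of gene pairs; pairs are canonicalized."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: PPI file needs two columns")
    a, b = df.columns[:2]
    return {canonical_pair(str(x), str(y)) for x, y in zip(df[a], df[b])}


def write_ppi(pairs: set[tuple[str, str]], path: str | Path) -> None:
    rows = sorted(canonical_pair(*p) for p in pairs)
    pd.DataFrame(rows, columns=["geneA", "geneB"]).to_csv(path, sep="\t", index=False)
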