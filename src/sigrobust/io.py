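"""Readers, writers and domain containers for expression data, signatures and labels.

The universal currency of the pipeline is the :class:`ExpressionMatrix`
(genes x samples). Gene-signature lists come in as GMT sets or two-column
``gene<TAB>class`` TSVs; per-sample subtype labels and survival tables are
plain TSV. A small registry exposes the five published pancreatic-cancer
signature schemes (Moffitt tumor/stroma, Collisson, Bailey, Puleo) as
packaged fixtures with their published sizes and class schemes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SubtypeScheme",
    "GeneSignature",
    "SubtypeLabelSet",
    "SurvivalTable",
    "FormatError",
    "ValidationError",
    "read_expression",
    "write_expression",
    "collapse_duplicates",
    "read_signature",
    "write_signature",
    "read_labels",
    "write_labels",
    "read_survival",
    "write_survival",
    "registry_get",
    "registry_names",
]


class FormatError(ValueError):
    """Malformed file layout (bad header, non-numeric cell, ...)."""


class ValidationError(ValueError):
    """Content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Normalized expression values, genes as rows and samples as columns.

    ``values`` is a float DataFrame indexed by unique gene symbols with
    unique sample-ID columns and no missing entries; rows with missing
    values are dropped at ingestion.
    """

    values: pd.DataFrame
    cohort_id: str = ""
    platform: str = "synthetic"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene symbols in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample IDs in expression matrix")
        if self.platform not in ("array", "rnaseq", "synthetic"):
            raise ValidationError(f"unknown platform {self.platform!r}")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        self.values = self.values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Subset to the given genes, keeping this matrix's row order."""
        keep = [g for g in self.genes if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.cohort_id, self.platform)


@dataclass(frozen=True)
class SubtypeScheme:
    """A named subtype scheme: the ordered class names of one stratification."""

    name: str
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValidationError("a subtype scheme needs k >= 2 classes")
        if len(set(self.classes)) != len(self.classes):
            raise ValidationError("duplicate class names in scheme")

    @property
    def k(self) -> int:
        return len(self.classes)


@dataclass
class GeneSignature:
    """A named gene list tied to a subtype scheme.

    ``direction`` optionally maps each gene to the class in which it is
    up-regulated; it may cover only part of the list or be absent.
    """

    name: str
    genes: list[str]
    scheme: SubtypeScheme
    direction: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        if self.direction:
            bad = set(self.direction.values()) - set(self.scheme.classes)
            if bad:
                raise ValidationError(f"direction classes {sorted(bad)} not in scheme")

    @property
    def size(self) -> int:
        return len(self.genes)

    def overlap(self, matrix: ExpressionMatrix) -> list[str]:
        """Signature genes present in ``matrix``, in signature order."""
        present = set(matrix.genes)
        return [g for g in self.genes if g in present]


@dataclass
class SubtypeLabelSet:
    """Per-sample class assignments under one scheme.

    ``origin`` records whether the labels are ground truth, a clustering
    output, or classifier predictions.
    """

    scheme: SubtypeScheme
    labels: pd.Series  # sample ID -> class name
    origin: str = "truth"

    def __post_init__(self) -> None:
        if self.origin not in ("truth", "cluster", "predicted"):
            raise ValidationError(f"unknown origin {self.origin!r}")
        bad = set(self.labels.unique()) - set(self.scheme.classes)
        if bad:
            raise ValidationError(f"labels {sorted(bad)} not in scheme {self.scheme.name!r}")
        if self.labels.index.has_duplicates:
            raise ValidationError("duplicate sample IDs in label set")
        self.labels = self.labels.astype(str)

    @property
    def samples(self) -> list[str]:
        return list(self.labels.index)

    def align_to(self, samples: Sequence[str]) -> pd.Series:
        missing = [s for s in samples if s not in self.labels.index]
        if missing:
            raise ValidationError(f"samples without labels: {missing[:5]}")
        return self.labels.loc[list(samples)]


@dataclass
class SurvivalTable:
    """Per-sample overall-survival record: time in months, event indicator.

    ``event`` is 1 when death was observed and 0 for censoring; ``group``
    (optional column) carries a class name.
    """

    data: pd.DataFrame  # index sample, columns time, event[, group]

    def __post_init__(self) -> None:
        required = {"time", "event"}
        if not required.issubset(self.data.columns):
            raise ValidationError("survival table needs 'time' and 'event' columns")
        if (self.data["time"] < 0).any():
            raise ValidationError("negative survival times")
        if not self.data["event"].isin([0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample IDs in survival table")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(samples)].copy())


# ---------------------------------------------------------------------------
# Expression IO
# ---------------------------------------------------------------------------


def collapse_duplicates(rows: np.ndarray | Sequence[Sequence[float]]) -> np.ndarray:
    """Collapse several probe rows for one gene into one, by element-wise median.

    A single row is returned unchanged. Median matches the probe-to-gene
    mapping convention used when several array probes hit one symbol.
    """
    arr = np.asarray(rows, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] == 0:
        raise ValidationError("collapse_duplicates needs at least one row")
    return np.median(arr, axis=0)


def _collapse_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene symbols by element-wise median, preserving
    first-occurrence row order."""
    if not df.index.has_duplicates:
        return df
    order = df.index.drop_duplicates()
    collapsed = df.groupby(level=0, sort=False).median()
    return collapsed.loc[order]


def read_expression(path: str | Path, format: str = "tsv", cohort_id: str | None = None,
                    platform: str = "synthetic") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT v1.2.

    TSV dialect: header row, first column ``gene``, remaining columns sample
    IDs. GCT v1.2: two header lines, then ``Name``/``Description`` columns
    before the samples. Gene symbols are whitespace-trimmed and matched
    case-sensitively. Duplicate symbols are collapsed by element-wise
    median; rows containing any missing value are dropped with a logged
    count.
    """
    path = Path(path)
    if format not in ("tsv", "gct"):
        raise FormatError(f"unknown expression format {format!r}")
    if format == "gct":
        with open(path) as fh:
            magic = fh.readline().strip()
            if magic != "#1.2":
                raise FormatError(f"{path}: expected GCT v1.2 magic '#1.2', got {magic!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}: malformed GCT dimension line")
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0, float_precision="round_trip")
        df = df.drop(columns=df.columns[0])  # single Description column
        n_rows, n_cols = int(dims[0]), int(dims[1])
        if df.shape != (n_rows, n_cols):
            raise FormatError(
                f"{path}: GCT dimension line says {n_rows}x{n_cols}, found {df.shape}")
    else:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        if df.shape[1] == 0:
            raise FormatError(f"{path}: no sample columns found")
    df.index = df.index.astype(str).str.strip()

    # locate non-numeric cells precisely before coercing
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        na_like = str(df.loc[gene, col]).strip().upper() if not isinstance(df.loc[gene, col], float) else ""
        if na_like not in ("NA", "NAN", ""):
            raise FormatError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}")
    incomplete = numeric.isna().any(axis=1)
    if incomplete.any():
        logger.info("read_expression: dropped %d gene rows with missing values", int(incomplete.sum()))
        numeric = numeric.loc[~incomplete]
    numeric = _collapse_frame(numeric)
    return ExpressionMatrix(numeric, cohort_id=cohort_id or path.stem, platform=platform)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the TSV dialect read back by :func:`read_expression` (full precision)."""
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Signature IO and registry
# ---------------------------------------------------------------------------


def read_signature(path: str | Path, format: str = "tsv",
                   scheme: SubtypeScheme | None = None) -> GeneSignature | list[GeneSignature]:
    """Read gene signatures from GMT (one set per line) or gene/class TSV.

    GMT returns a list of signatures; class names must then come from
    ``scheme`` (one unnamed binary scheme is synthesized when absent, since
    GMT carries no class structure). The TSV dialect infers the scheme from
    the distinct ``class`` values in file order. Duplicate genes keep their
    first occurrence, except a gene listed under two different classes,
    which is an ambiguity error.
    """
    path = Path(path)
    if format == "gmt":
        sigs = []
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT line needs name, description, >=1 gene")
            name, genes = parts[0], [g.strip() for g in parts[2:] if g.strip()]
            if not genes:
                raise ValidationError(f"{path}: empty gene list for set {name!r}")
            seen, uniq = set(), []
            for g in genes:
                if g in seen:
                    logger.info("read_signature: duplicate gene %s in %s dropped", g, name)
                    continue
                seen.add(g)
                uniq.append(g)
            sc = scheme or SubtypeScheme(name, ("in-set", "rest"))
            sigs.append(GeneSignature(name=name, genes=uniq, scheme=sc))
        return sigs
    if format != "tsv":
        raise FormatError(f"unknown signature format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "class"}.issubset(df.columns):
        raise FormatError(f"{path}: signature TSV needs 'gene' and 'class' columns")
    df["gene"] = df["gene"].str.strip()
    direction: dict[str, str] = {}
    genes: list[str] = []
    for gene, cls in zip(df["gene"], df["class"]):
        if gene in direction:
            if direction[gene] != cls:
                raise ValidationError(
                    f"{path}: gene {gene!r} listed under classes {direction[gene]!r} and {cls!r}")
            logger.info("read_signature: duplicate gene %s dropped", gene)
            continue
        direction[gene] = cls
        genes.append(gene)
    classes = tuple(dict.fromkeys(df["class"]))
    sc = scheme or SubtypeScheme(path.stem, classes)
    return GeneSignature(name=path.stem, genes=genes, scheme=sc, direction=direction)


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    direction = sig.direction or {}
    df = pd.DataFrame({
        "gene": sig.genes,
        "class": [direction.get(g, sig.scheme.classes[0]) for g in sig.genes],
    })
    df.to_csv(path, sep="\t", index=False)


# published sizes and schemes of the five pancreatic-cancer signatures;
# vendored gene lists are synthetic stand-ins with exactly these shapes
_REGISTRY: dict[str, tuple[str, int, SubtypeScheme]] = {
    "moffitt_tumor": ("moffitt_tumor_synthetic.tsv", 50,
                      SubtypeScheme("moffitt_tumor", ("basal-like", "classical"))),
    "moffitt_stroma": ("moffitt_stroma_synthetic.tsv", 48,
                       SubtypeScheme("moffitt_stroma", ("normal", "activated"))),
    "collisson": ("collisson_synthetic.tsv", 62,
                  SubtypeScheme("collisson", ("classical", "quasi-mesenchymal", "exocrine-like"))),
    "bailey": ("bailey_synthetic.tsv", 613,
               SubtypeScheme("bailey", ("squamous", "immunogenic", "pancreatic-progenitor", "ADEX"))),
    "puleo": ("puleo_synthetic.tsv", 403,
              SubtypeScheme("puleo", ("pure-classical", "immune-classical", "desmoplastic",
                                      "stroma-activated", "pure-basal-like"))),
}


def registry_names() -> list[str]:
    return sorted(_REGISTRY)


def _signature_dir():
    return resources.files("sigrobust.data") / "signatures"


def registry_checksums_ok() -> bool:
    """Verify the vendored signature files against their recorded SHA-256 sums."""
    root = _signature_dir()
    for line in (root / "signatures.sha256").read_text().splitlines():
        digest, fname = line.split()
        actual = hashlib.sha256((root / fname).read_bytes()).hexdigest()
        if actual != digest:
            return False
    return True


def registry_get(name: str) -> GeneSignature:
    """Fetch a packaged signature by registry name.

    The vendored gene lists are synthetic placeholders; size, class count
    and class names match the published signatures exactly.
    """
    if name not in _REGISTRY:
        raise KeyError(f"unknown signature {name!r}; registered: {registry_names()}")
    fname, size, scheme = _REGISTRY[name]
    with resources.as_file(_signature_dir() / fname) as p:
        sig = read_signature(p, format="tsv", scheme=scheme)
    assert isinstance(sig, GeneSignature)
    sig.name = name
    if sig.size != size:
        raise ValidationError(f"registry fixture {name!r} has {sig.size} genes, expected {size}")
    return sig


# ---------------------------------------------------------------------------
# Labels and survival IO
# ---------------------------------------------------------------------------


def read_labels(path: str | Path, scheme: SubtypeScheme | None = None,
                origin: str = "truth") -> SubtypeLabelSet:
    """Read a sample/label TSV; the scheme is inferred from the distinct
    labels (file order) when not supplied."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "label"}.issubset(df.columns):
        raise FormatError(f"{path}: label TSV needs 'sample' and 'label' columns")
    labels = pd.Series(df["label"].values, index=df["sample"].values)
    sc = scheme or SubtypeScheme(Path(path).stem, tuple(dict.fromkeys(df["label"])))
    return SubtypeLabelSet(scheme=sc, labels=labels, origin=origin)


def write_labels(labels: SubtypeLabelSet, path: str | Path) -> None:
    pd.DataFrame({"sample": labels.labels.index, "label": labels.labels.values}).to_csv(
        path, sep="\t", index=False)


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise FormatError(f"{path}: survival TSV needs a 'sample' column")
    df = df.set_index("sample")
    return SurvivalTable(df)


def write_survival(t: SurvivalTable, path: str | Path) -> None:
    out = t.data.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format="%.17g")
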