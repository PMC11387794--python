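"""Readers/writers for the pipeline's external formats and the expression filter.

Canonical on-disk formats are plain text: expression matrices as TSV
(gene ids in the first column, sample ids in the header), gene-set
collections in the Broad GMT dialect, clinical and multi-region tables as
TSV. CSV input is accepted by sniffing the delimiter of the header line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINEAR = "linear"
LOG2P1 = "log2p1"
_SCALES = (LINEAR, LOG2P1)


class FormatError(ValueError):
    """A file could not be parsed into the expected structure."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with a declared scale.

    scale "linear" means non-negative normalized expression (TPM-like);
    "log2p1" means log2(x + 1) of such values.
    """

    data: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression values must be finite")
        if self.scale == LINEAR and values.size and (values < 0).any():
            raise ValidationError("linear-scale expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_log2p1(self) -> "ExpressionMatrix":
        if self.scale == LOG2P1:
            return self
        return ExpressionMatrix(np.log2(self.data + 1.0), scale=LOG2P1)

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == LINEAR:
            return self
        return ExpressionMatrix(np.power(2.0, self.data) - 1.0, scale=LINEAR)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes], scale=self.scale)


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def read_expression(path: str | Path, scale: str = LINEAR) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV into an :class:`ExpressionMatrix`.

    The first column holds gene ids, the header row sample ids. Raises
    :class:`FormatError` naming the offending row and column for
    non-numeric cells and :class:`ValidationError` for duplicate ids.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise FormatError(
            f"{path}: non-numeric value {df.loc[gene, sample]!r} at gene {gene!r}, sample {sample!r}"
        )
    if numeric.isna().to_numpy().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing value in row for gene {gene!r}")
    return ExpressionMatrix(numeric.astype(float), scale=scale)


def write_expression(mat: ExpressionMatrix, path: str | Path) -> None:
    mat.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def filter_expressed_genes(
    mat: ExpressionMatrix, min_level: float = 1.0, min_fraction: float = 0.2
) -> ExpressionMatrix:
    """Keep genes expressed at >= ``min_level`` in >= ``min_fraction`` of samples.

    Both comparisons are inclusive ("at least"); the required sample count
    is ``ceil(min_fraction * n_samples)``. Intended for TPM-scale cohort
    matrices, e.g. at least 1 TPM in at least 20% of samples.
    """
    if mat.scale != LINEAR:
        raise ValidationError("expression filter expects a linear-scale matrix")
    if not 0.0 <= min_fraction <= 1.0:
        raise ValidationError("min_fraction must be in [0, 1]")
    n_samples = mat.shape[1]
    required = math.ceil(min_fraction * n_samples)
    counts = (mat.data.to_numpy() >= min_level).sum(axis=1)
    keep = counts >= required
    if not keep.any():
        logger.warning("expression filter removed all %d genes", mat.shape[0])
    return ExpressionMatrix(mat.data.loc[keep], scale=mat.scale)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name -> :class:`GeneSet`."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if not gs.genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(gs.genes)) != len(gs.genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        return cls({name: GeneSet(name, "", list(genes)) for name, genes in mapping.items()})


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file (name, description, genes...).

    Duplicate genes within a line are collapsed (first occurrence kept)
    with a logged warning; lines with fewer than three fields raise
    :class:`FormatError` with the line number.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            name, description, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning("%s:%d: collapsed %d duplicate genes in set %r",
                               path, lineno, len(genes) - len(deduped), name)
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, description, deduped)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Clinical and multi-region tables
# ---------------------------------------------------------------------------

REQUIRED_COHORT_COLUMNS = ("sample_id", "time", "event")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a clinical table with required columns sample_id, time, event.

    Rows with missing time or event are dropped with a logged count;
    other covariates may be missing and are kept as NaN. Validates
    time > 0, event in {0, 1}, unique sample ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    n_before = len(df)
    df = df.dropna(subset=["time", "event"]).copy()
    if len(df) < n_before:
        logger.warning("%s: dropped %d rows with missing time/event", path, n_before - len(df))
    df["time"] = pd.to_numeric(df["time"])
    df["event"] = pd.to_numeric(df["event"]).astype(int)
    if (df["time"] <= 0).any():
        raise ValidationError(f"{path}: survival times must be > 0")
    if not df["event"].isin((0, 1)).all():
        raise ValidationError(f"{path}: event must be 0 or 1")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    return df.reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> pd.DataFrame:
    """Read a multi-region table with patient_id and region_id columns."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in ("patient_id", "region_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df.duplicated(subset=["patient_id", "region_id"]).any():
        raise ValidationError(f"{path}: duplicate (patient_id, region_id) pairs")
    return df.reset_index(drop=True)


def write_regions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
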