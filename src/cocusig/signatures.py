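"""Crosstalk signature derivation and per-sample scoring.

Two derivation routes mirror the two published strategies:

* pathway-frequency: per dataset and cell type, run gene-set enrichment
  of co- vs mono-culture, pool the leading-edge genes of upregulated
  sets significant at FDR < 0.05, keep genes belonging to >= 20% of the
  enriched sets (membership counted against full set membership), then
  intersect the kept lists across all datasets of a cell type and union
  the cancer and CAF lists (the CoCu8-style rule);
* fold-change: per dataset and cell type keep genes with co/mono fold
  change >= 1.5, intersect across datasets of a cell type, union the
  two cell-type lists (the CoCu30-style rule).

A signature is scored on a cohort as the mean of per-gene z-scores of
log2(x+1) expression, which makes quartile stratification scale-free.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .enrichment import EnrichmentResult, fold_changes
from .io import ExpressionMatrix, GeneSetCollection
from .simulate import CAF, CANCER, CultureExperiment

logger = logging.getLogger(__name__)


@dataclass
class SignatureDefinition:
    """A named gene list with per-cell-type provenance.

    ``genes`` is the union of the cancer and CAF contributing lists, so
    |genes| = |cancer| + |caf| - |cancer ∩ caf| by construction.
    """

    name: str
    cancer_list: list[str]
    caf_list: list[str]

    def __post_init__(self) -> None:
        for label, lst in (("cancer", self.cancer_list), ("caf", self.caf_list)):
            if len(set(lst)) != len(lst):
                raise ValueError(f"{label} list contains duplicates")

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.cancer_list) | set(self.caf_list))

    def __len__(self) -> int:
        return len(self.genes)

    def to_json(self, path: str | Path, params: dict | None = None) -> None:
        payload = {
            "name": self.name,
            "genes": self.genes,
            "cancer_list": sorted(self.cancer_list),
            "caf_list": sorted(self.caf_list),
        }
        if params:
            payload["params"] = params
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureDefinition":
        payload = json.loads(Path(path).read_text())
        return cls(payload["name"], payload["cancer_list"], payload["caf_list"])


@dataclass
class DerivationParams:
    fdr_threshold: float = 0.05
    pathway_frequency_threshold: float = 0.20
    fold_change_threshold: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if not 0.0 < self.pathway_frequency_threshold <= 1.0:
            raise ValueError("pathway_frequency_threshold must be in (0, 1]")
        if self.fold_change_threshold <= 0:
            raise ValueError("fold_change_threshold must be > 0")


# ---------------------------------------------------------------------------
# Pathway-frequency derivation (CoCu8-style)
# ---------------------------------------------------------------------------

class FrequencySignatureSelector(BaseEstimator):
    """Select signature genes by pathway-frequency across enrichment runs.

    Parameters
    ----------
    fdr_threshold : float
        Upregulated sets with permutation FDR q below this count as enriched.
    frequency_threshold : float
        A gene is kept in a dataset when it belongs to at least
        ``ceil(frequency_threshold * n_enriched_sets)`` of that dataset's
        enriched sets (boundary inclusive).
    name : str
        Name given to the fitted signature.

    Attributes
    ----------
    signature_ : SignatureDefinition
    per_dataset_genes_ : dict mapping (dataset_id, cell_type) -> kept genes
    """

    def __init__(self, fdr_threshold: float = 0.05, frequency_threshold: float = 0.20,
                 name: str = "frequency_signature"):
        self.fdr_threshold = fdr_threshold
        self.frequency_threshold = frequency_threshold
        self.name = name

    def fit(
        self,
        enrichments: Mapping[tuple[str, str], Sequence[EnrichmentResult]],
        collection: GeneSetCollection,
    ) -> "FrequencySignatureSelector":
        """Fit from per-(dataset, cell_type) enrichment results.

        ``enrichments`` maps (dataset_id, cell_type) to the GSEA results of
        that experiment; ``collection`` supplies full set membership for
        the frequency count.
        """
        DerivationParams(self.fdr_threshold, self.frequency_threshold)  # validate
        per_dataset: dict[tuple[str, str], set[str]] = {}
        for key, results in enrichments.items():
            enriched = [r for r in results if r.es > 0 and r.fdr_q < self.fdr_threshold]
            if not enriched:
                logger.warning("no enriched sets for %s; empty gene list", key)
                per_dataset[key] = set()
                continue
            pool = set().union(*(r.leading_edge for r in enriched))
            required = math.ceil(self.frequency_threshold * len(enriched))
            memberships = [set(collection[r.set_name].genes) for r in enriched]
            per_dataset[key] = {
                g for g in pool if sum(g in m for m in memberships) >= required
            }
        self.per_dataset_genes_ = per_dataset
        self.signature_ = SignatureDefinition(
            self.name,
            sorted(_intersect_cell_type(per_dataset, CANCER)),
            sorted(_intersect_cell_type(per_dataset, CAF)),
        )
        if not len(self.signature_):
            logger.warning("derived frequency signature is empty")
        return self


def _intersect_cell_type(per_dataset: Mapping[tuple[str, str], set[str]], cell_type: str) -> set[str]:
    lists = [genes for (_, ct), genes in per_dataset.items() if ct == cell_type]
    if not lists:
        return set()
    return set.intersection(*lists)


def derive_frequency_signature(
    enrichments: Mapping[tuple[str, str], Sequence[EnrichmentResult]],
    collection: GeneSetCollection,
    params: DerivationParams | None = None,
    name: str = "frequency_signature",
) -> SignatureDefinition:
    params = params or DerivationParams()
    sel = FrequencySignatureSelector(
        params.fdr_threshold, params.pathway_frequency_threshold, name
    ).fit(enrichments, collection)
    return sel.signature_


# ---------------------------------------------------------------------------
# Fold-change derivation (CoCu30-style)
# ---------------------------------------------------------------------------

class FoldChangeSignatureSelector(BaseEstimator):
    """Select signature genes upregulated >= fold_change_threshold in every
    dataset of a cell type (inclusive threshold; +inf fold changes count,
    undefined 0/0 fold changes are excluded)."""

    def __init__(self, fold_change_threshold: float = 1.5, name: str = "foldchange_signature"):
        self.fold_change_threshold = fold_change_threshold
        self.name = name

    def fit(self, experiments: Sequence[CultureExperiment]) -> "FoldChangeSignatureSelector":
        DerivationParams(fold_change_threshold=self.fold_change_threshold)
        per_dataset: dict[tuple[str, str], set[str]] = {}
        for exp in experiments:
            fc = fold_changes(exp)
            keep = fc.index[(fc >= self.fold_change_threshold) & ~fc.isna()]
            per_dataset[(exp.dataset_id, exp.cell_type)] = set(keep)
        self.per_dataset_genes_ = per_dataset
        self.signature_ = SignatureDefinition(
            self.name,
            sorted(_intersect_cell_type(per_dataset, CANCER)),
            sorted(_intersect_cell_type(per_dataset, CAF)),
        )
        return self


def derive_foldchange_signature(
    experiments: Sequence[CultureExperiment],
    params: DerivationParams | None = None,
    name: str = "foldchange_signature",
) -> SignatureDefinition:
    params = params or DerivationParams()
    sel = FoldChangeSignatureSelector(params.fold_change_threshold, name).fit(experiments)
    return sel.signature_


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

class SignatureScorer(BaseEstimator, TransformerMixin):
    """Score samples as the mean per-gene z-score of signature genes.

    Expression is converted to log2(x+1); each signature gene present in
    the matrix is z-scored across samples (ddof=1) and the per-sample
    score is the mean over those genes. All-constant genes contribute 0.

    Attributes
    ----------
    genes_used_ : list of signature genes present in the fitted matrix
    gene_means_, gene_stds_ : per-gene standardization parameters
    """

    def __init__(self, signature=None):
        self.signature = signature

    def _signature_genes(self) -> list[str]:
        if self.signature is None:
            raise ValueError("signature must be provided")
        return list(getattr(self.signature, "genes", self.signature))

    def fit(self, X: ExpressionMatrix, y=None) -> "SignatureScorer":
        log = X.to_log2p1().data
        genes = [g for g in self._signature_genes() if g in log.index]
        if not genes:
            raise ValueError("no signature gene present in the expression matrix")
        missing = set(self._signature_genes()) - set(genes)
        if missing:
            logger.info("%d signature genes absent from matrix: %s",
                        len(missing), sorted(missing)[:5])
        sub = log.loc[genes]
        self.genes_used_ = genes
        self.gene_means_ = sub.mean(axis=1)
        self.gene_stds_ = sub.std(axis=1, ddof=1)
        return self

    def transform(self, X: ExpressionMatrix) -> pd.Series:
        log = X.to_log2p1().data
        sub = log.loc[self.genes_used_]
        stds = self.gene_stds_.replace(0.0, np.nan)
        z = sub.sub(self.gene_means_, axis=0).div(stds, axis=0).fillna(0.0)
        return pd.Series(z.mean(axis=0), index=log.columns, name="score")


def score_signature(mat: ExpressionMatrix, sig: SignatureDefinition | Sequence[str]) -> pd.Series:
    """Per-sample signature score: mean of per-gene z-scores on log2(x+1)."""
    return SignatureScorer(sig).fit(mat).transform(mat)
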