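"""Contamination estimation and correction for sorted co-culture samples.

Sorted samples from direct co-cultures can carry transcripts of the
other lineage. Treating a sorted sample as a two-component convex
mixture, the contaminating fraction alpha is estimated by constrained
least squares restricted to lineage marker genes:

    alpha = argmin_{a in [0,1]} || s - ((1-a) * own + a * other) ||^2

over the union of carcinoma markers (CDH1, EPCAM, CD24, KRT family) and
fibroblast markers (COL1A1, COL1A2, DCN, CD248, PDGFR family). The
closed-form solution <s - own, other - own> / ||other - own||^2 is
clipped to [0, 1]. Correction inverts the mixture per gene on the
linear scale: corrected = max(0, (observed - alpha * other) / (1 - alpha)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

DEFAULT_CARCINOMA_MARKERS = ("CDH1", "EPCAM", "CD24")
DEFAULT_CARCINOMA_PREFIXES = ("KRT",)
DEFAULT_FIBROBLAST_MARKERS = ("COL1A1", "COL1A2", "DCN", "CD248")
DEFAULT_FIBROBLAST_PREFIXES = ("PDGFR",)

DEFAULT_ALPHA_MAX = 0.9


@dataclass
class MarkerPanel:
    """Lineage marker genes, with prefix families expanded against the data."""

    carcinoma_markers: tuple[str, ...] = DEFAULT_CARCINOMA_MARKERS
    carcinoma_prefixes: tuple[str, ...] = DEFAULT_CARCINOMA_PREFIXES
    fibroblast_markers: tuple[str, ...] = DEFAULT_FIBROBLAST_MARKERS
    fibroblast_prefixes: tuple[str, ...] = DEFAULT_FIBROBLAST_PREFIXES

    def expand(self, gene_universe) -> tuple[list[str], list[str]]:
        """Resolve exact names and prefix families against ``gene_universe``."""
        universe = list(gene_universe)
        carcinoma = [
            g for g in universe
            if g in self.carcinoma_markers or any(g.startswith(p) for p in self.carcinoma_prefixes)
        ]
        fibroblast = [
            g for g in universe
            if g in self.fibroblast_markers or any(g.startswith(p) for p in self.fibroblast_prefixes)
        ]
        overlap = set(carcinoma) & set(fibroblast)
        if overlap:
            raise ValueError(f"marker panels overlap after expansion: {sorted(overlap)[:5]}")
        if not carcinoma or not fibroblast:
            raise ValueError("each marker panel must match >= 1 gene in the data")
        return carcinoma, fibroblast

    def marker_union(self, gene_universe) -> list[str]:
        carcinoma, fibroblast = self.expand(gene_universe)
        return carcinoma + fibroblast


@dataclass
class MixtureEstimate:
    sample_id: str
    alpha: float
    residual: float  # RMSE over marker genes at the fitted alpha
    n_markers: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


def estimate_impurity(
    sample: pd.Series,
    own_mono: pd.Series,
    other_mono: pd.Series,
    panel: MarkerPanel | None = None,
) -> MixtureEstimate:
    """Estimate the contaminating fraction alpha of a sorted sample.

    All profiles must be linear scale over a shared gene universe. Raises
    if the two mono-culture profiles are collinear on the markers
    (relative difference < 1e-6), in which case the mixture fraction is
    unidentifiable.
    """
    panel = panel or MarkerPanel()
    if not (sample.index.equals(own_mono.index) and sample.index.equals(other_mono.index)):
        raise ValueError("profiles must share one gene universe")
    markers = panel.marker_union(sample.index)
    s = sample.loc[markers].to_numpy(dtype=float)
    a = own_mono.loc[markers].to_numpy(dtype=float)
    b = other_mono.loc[markers].to_numpy(dtype=float)
    d = b - a
    scale = max(np.linalg.norm(a), np.linalg.norm(b), 1.0)
    if np.linalg.norm(d) / scale < 1e-6:
        raise ValueError("unidentifiable mixture: mono profiles collinear on markers")
    alpha = float(np.dot(s - a, d) / np.dot(d, d))
    alpha = float(np.clip(alpha, 0.0, 1.0))
    residual = float(np.sqrt(np.mean((s - ((1 - alpha) * a + alpha * b)) ** 2)))
    return MixtureEstimate(str(sample.name or "sample"), alpha, residual, len(markers))


def correct_contamination(
    sample: pd.Series,
    other_mono: pd.Series,
    alpha: float,
    alpha_max: float = DEFAULT_ALPHA_MAX,
) -> pd.Series:
    """Invert the two-component mixture per gene on the linear scale.

    corrected = max(0, (observed - alpha * other_mono) / (1 - alpha));
    genes driven negative are clipped to 0 with a logged count. Raises
    when alpha >= alpha_max (default 0.9), where the inversion amplifies
    noise too strongly to be trusted.
    """
    if not 0.0 <= alpha < alpha_max:
        raise ValueError(f"correction unstable: alpha={alpha} not in [0, {alpha_max})")
    if not sample.index.equals(other_mono.index):
        raise ValueError("profiles must share one gene universe")
    corrected = (sample - alpha * other_mono) / (1.0 - alpha)
    n_clipped = int((corrected < 0).sum())
    if n_clipped:
        logger.info("clipped %d negative corrected values to 0", n_clipped)
    return corrected.clip(lower=0.0)


class MixtureCorrector(BaseEstimator):
    """Estimator wrapper: fit estimates alpha, transform corrects profiles.

    Attributes
    ----------
    alpha_ : fitted contaminating fraction
    residual_ : marker-gene RMSE at the fitted alpha
    """

    def __init__(self, panel: MarkerPanel | None = None, alpha_max: float = DEFAULT_ALPHA_MAX):
        self.panel = panel
        self.alpha_max = alpha_max

    def fit(self, sample: pd.Series, own_mono: pd.Series, other_mono: pd.Series) -> "MixtureCorrector":
        est = estimate_impurity(sample, own_mono, other_mono, self.panel)
        self.alpha_ = est.alpha
        self.residual_ = est.residual
        self.other_mono_ = other_mono
        return self

    def transform(self, sample: pd.Series) -> pd.Series:
        return correct_contamination(sample, self.other_mono_, self.alpha_, self.alpha_max)
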