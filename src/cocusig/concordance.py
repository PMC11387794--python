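"""Multi-region signature concordance analysis.

Regions are labeled high when their signature score exceeds the
cohort-wide median of region scores (ties go to low). A multi-region
patient is concordant when all regions share one label, discordant
otherwise; single-region patients are excluded from the concordance
denominator but keep their risk label.

Under the chance null, each region's label is an independent
Bernoulli(q) draw, so the expected number of concordant patients is

    E[concordant] = sum_i ( q^{n_i} + (1-q)^{n_i} )

over per-patient region counts n_i >= 2. The observed and
expected-rounded counts form a 2x2 table tested with a two-sided
Fisher's exact test (summing hypergeometric tables whose point
probability does not exceed the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

HIGH = "high"
LOW = "low"

CONCORDANT_HIGH = "concordant_high"
CONCORDANT_LOW = "concordant_low"
DISCORDANT = "discordant"
SINGLE_REGION = "single_region"


def classify_regions(
    regions: pd.DataFrame, score_col: str = "score", threshold: float | None = None
) -> pd.DataFrame:
    """Label each region high/low by the cohort-wide median split.

    ``threshold`` overrides the median. A region scoring exactly at the
    threshold is labeled low. Returns a copy with a ``label`` column.
    """
    if len(regions) < 2:
        raise ValueError("need >= 2 regions to classify")
    scores = regions[score_col].astype(float)
    if scores.nunique() == 1:
        raise ValueError("all region scores equal: classification undefined")
    cut = float(np.median(scores)) if threshold is None else float(threshold)
    out = regions.copy()
    out["label"] = np.where(scores > cut, HIGH, LOW)
    return out


def classify_patients(labeled: pd.DataFrame) -> pd.Series:
    """Per-patient concordance call from labeled regions.

    All regions high -> concordant_high; all low -> concordant_low;
    mixed -> discordant; exactly one region -> single_region.
    """
    def call(labels: pd.Series) -> str:
        if len(labels) == 1:
            return SINGLE_REGION
        uniq = set(labels)
        if uniq == {HIGH}:
            return CONCORDANT_HIGH
        if uniq == {LOW}:
            return CONCORDANT_LOW
        return DISCORDANT

    return labeled.groupby("patient_id")["label"].apply(call).rename("patient_class")


def expected_concordant_by_chance(region_counts, q: float = 0.5) -> tuple[float, float]:
    """Closed-form chance expectation of concordant multi-region patients.

    ``region_counts`` are per-patient region counts, all >= 2; ``q`` is
    the probability a region is labeled high under the null. Returns
    (expected_concordant, expected_discordant).
    """
    counts = np.asarray(list(region_counts), dtype=int)
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if (counts < 2).any():
        raise ValueError("all region counts must be >= 2")
    expected = float(np.sum(q ** counts + (1.0 - q) ** counts))
    return expected, float(len(counts) - expected)


def concordance_test(
    observed_concordant: int,
    observed_discordant: int,
    expected_concordant: float,
    expected_discordant: float,
) -> tuple[np.ndarray, float]:
    """Two-sided Fisher's exact test of observed vs expected-by-chance.

    The expectation is rounded to integers with the discordant cell
    taken as the complement so both rows share the multi-region total.
    """
    n = observed_concordant + observed_discordant
    exp_total = expected_concordant + expected_discordant
    if round(exp_total) != n:
        raise ValueError("expected counts must total the observed multi-region patients")
    exp_conc = round(expected_concordant)
    exp_disc = n - exp_conc
    table = np.array(
        [[observed_concordant, observed_discordant], [exp_conc, exp_disc]], dtype=int
    )
    if (table < 0).any():
        raise ValueError("negative cell in the Fisher table")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


@dataclass
class ConcordanceResult:
    n_patients_total: int
    n_multiregion: int
    concordant_high: int
    concordant_low: int
    discordant: int
    expected_concordant: float
    expected_discordant: float
    fisher_table: np.ndarray
    fisher_p: float
    patient_classes: pd.Series

    @property
    def concordant(self) -> int:
        return self.concordant_high + self.concordant_low

    def to_dict(self) -> dict:
        return {
            "n_patients_total": self.n_patients_total,
            "n_multiregion": self.n_multiregion,
            "concordant_high": self.concordant_high,
            "concordant_low": self.concordant_low,
            "discordant": self.discordant,
            "expected_concordant": self.expected_concordant,
            "expected_discordant": self.expected_discordant,
            "fisher_table": self.fisher_table.tolist(),
            "fisher_p": self.fisher_p,
        }


def analyze_concordance(
    regions: pd.DataFrame,
    score_col: str = "score",
    q: float = 0.5,
    threshold: float | None = None,
) -> ConcordanceResult:
    """Full concordance analysis of a multi-region score table."""
    labeled = classify_regions(regions, score_col, threshold)
    classes = classify_patients(labeled)
    multi = classes[classes != SINGLE_REGION]
    counts = labeled.groupby("patient_id").size()
    multi_counts = counts[counts >= 2]
    exp_conc, exp_disc = expected_concordant_by_chance(multi_counts, q)
    conc_high = int((multi == CONCORDANT_HIGH).sum())
    conc_low = int((multi == CONCORDANT_LOW).sum())
    disc = int((multi == DISCORDANT).sum())
    table, p = concordance_test(conc_high + conc_low, disc, exp_conc, exp_disc)
    return ConcordanceResult(
        n_patients_total=int(counts.size),
        n_multiregion=int(multi_counts.size),
        concordant_high=conc_high,
        concordant_low=conc_low,
        discordant=disc,
        expected_concordant=exp_conc,
        expected_discordant=exp_disc,
        fisher_table=table,
        fisher_p=p,
        patient_classes=classes,
    )
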