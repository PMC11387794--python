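"""Synthetic data generators emulating the statistical structure of the analysis.

Four generators cover the pipeline end to end:

* paired mono-/co-culture transcriptomes for several cancer-cell/CAF
  dataset pairs with a planted co-upregulated gene program shared across
  datasets and cell types;
* sorted co-culture samples contaminated as convex mixtures of the two
  mono-culture profiles;
* proportional-hazards survival cohorts whose hazard depends on a
  per-sample signature score;
* multi-region cohorts with per-patient region counts and controllable
  between-region concordance.

Noise is multiplicative log-normal (Gaussian on the log2 scale), matching
the log-scale analyses downstream. All generators are pure functions of
(config, seed): a single global seed expands to per-component child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, GeneSetCollection, LINEAR

MONO = "mono"
CO = "co"
CANCER = "cancer"
CAF = "caf"
CELL_TYPES = (CANCER, CAF)


class ConfigurationError(ValueError):
    pass


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(list(keys))


# ---------------------------------------------------------------------------
# Co-culture experiments with a planted program
# ---------------------------------------------------------------------------

@dataclass
class CultureExperiment:
    """One cancer/CAF dataset for one cell type: mono and co sample groups."""

    dataset_id: str
    cell_type: str
    expression: ExpressionMatrix
    conditions: pd.Series  # sample_id -> "mono" | "co"

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ConfigurationError(f"cell_type must be one of {CELL_TYPES}")
        labels = set(self.conditions)
        if not labels <= {MONO, CO}:
            raise ConfigurationError(f"unknown condition labels {labels - {MONO, CO}}")
        if set(self.conditions.index) != set(self.expression.sample_ids):
            raise ConfigurationError("condition labels must cover all samples exactly")
        for cond in (MONO, CO):
            if (self.conditions == cond).sum() < 2:
                raise ConfigurationError(f"need >= 2 {cond!r} samples")

    def samples(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


@dataclass
class SimulationConfig:
    """Study conditions for the paired mono/co-culture simulation.

    Defaults mirror the analysed design: three cancer/CAF dataset pairs,
    four replicates per condition, a 30-gene planted program upregulated
    by log2 fold change +1.5 in co-culture in both cell types, and
    log-scale Gaussian noise with sd 0.2.
    """

    seed: int = 0
    n_genes: int = 2000
    n_datasets: int = 3
    replicates_per_condition: int = 4
    planted_program: dict[str, float] | None = None  # gene -> log2 FC; None = 30 genes at +1.5
    n_planted: int = 30
    planted_log2_fc: float = 1.5
    noise_sd: float = 0.2
    baseline_log_mean_range: tuple[float, float] = (3.0, 8.0)

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 2:
            raise ConfigurationError("replicates_per_condition must be >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.planted_program is None:
            self.planted_program = {
                f"PRG{i:04d}": self.planted_log2_fc for i in range(1, self.n_planted + 1)
            }

    @property
    def gene_ids(self) -> list[str]:
        planted = list(self.planted_program)
        n_background = self.n_genes - len(planted)
        if n_background < 0:
            raise ConfigurationError("planted program larger than gene universe")
        background = [f"G{i:05d}" for i in range(1, n_background + 1)]
        return planted + background


def simulate_coculture_experiments(cfg: SimulationConfig) -> list[CultureExperiment]:
    """Simulate mono/co expression for each dataset pair and cell type.

    Per dataset and cell type every gene gets a baseline log2 mean drawn
    uniformly from ``baseline_log_mean_range``; co-culture samples add the
    planted program's log2 fold changes; each replicate adds N(0, noise_sd)
    on the log2 scale. Returned matrices are linear scale.
    """
    genes = cfg.gene_ids
    missing = [g for g in cfg.planted_program if g not in genes]
    if missing:
        raise ConfigurationError(f"planted genes absent from gene universe: {missing[:5]}")
    lfc = np.array([cfg.planted_program.get(g, 0.0) for g in genes])
    experiments = []
    for d in range(cfg.n_datasets):
        for c, cell_type in enumerate(CELL_TYPES):
            rng = _rng(cfg.seed, 11, d, c)
            baseline = rng.uniform(*cfg.baseline_log_mean_range, size=len(genes))
            r = cfg.replicates_per_condition
            cols, log_means = [], []
            for cond, shift in ((MONO, 0.0), (CO, lfc)):
                for i in range(r):
                    cols.append(f"D{d + 1}_{cell_type}_{cond}_{i + 1}")
                    log_means.append(baseline + shift)
            log_expr = np.column_stack(log_means)
            log_expr = log_expr + rng.normal(0.0, cfg.noise_sd, size=log_expr.shape)
            data = pd.DataFrame(np.power(2.0, log_expr), index=genes, columns=cols)
            conditions = pd.Series([MONO] * r + [CO] * r, index=cols)
            experiments.append(
                CultureExperiment(
                    dataset_id=f"D{d + 1}",
                    cell_type=cell_type,
                    expression=ExpressionMatrix(data, scale=LINEAR),
                    conditions=conditions,
                )
            )
    return experiments


def simulate_gene_set_collection(
    cfg: SimulationConfig,
    n_responsive: int = 6,
    n_null: int = 6,
    set_size: int = 50,
    program_fraction: float = 0.6,
) -> GeneSetCollection:
    """Build a fixed gene-set collection for the simulated universe.

    Emulates a pathway database in which the planted program is spread
    over several overlapping "responsive" pathways: each responsive set
    contains a random ``program_fraction`` of the planted genes topped up
    with background genes; null sets are pure background. All sets share
    one size so permutation nulls coincide across sets.
    """
    rng = _rng(cfg.seed, 23)
    genes = np.array(cfg.gene_ids)
    planted = np.array(list(cfg.planted_program))
    background = np.array([g for g in genes if g not in set(planted)])
    n_prog = max(1, round(program_fraction * len(planted)))
    sets: dict[str, GeneSet] = {}
    for i in range(n_responsive):
        members = rng.choice(planted, size=n_prog, replace=False)
        filler = rng.choice(background, size=set_size - n_prog, replace=False)
        name = f"RESPONSIVE_{i + 1}"
        sets[name] = GeneSet(name, "program-bearing", sorted([*members, *filler]))
    for i in range(n_null):
        name = f"NULL_{i + 1}"
        members = rng.choice(background, size=set_size, replace=False)
        sets[name] = GeneSet(name, "background", sorted(members))
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Contaminated sorted samples
# ---------------------------------------------------------------------------

def simulate_contaminated_sort(
    mono_a: pd.Series,
    mono_b: pd.Series,
    alpha: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Convex mixture (1-alpha)*mono_a + alpha*mono_b with log-normal noise.

    Emulates a sorted co-culture sample whose fraction ``alpha`` comes
    from the contaminating lineage. Profiles must be linear scale on the
    same gene universe.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError("alpha must be in [0, 1]")
    if not mono_a.index.equals(mono_b.index):
        raise ConfigurationError("mono profiles must share one gene universe")
    mix = (1.0 - alpha) * mono_a + alpha * mono_b
    if noise_sd > 0:
        rng = _rng(seed, 31)
        mix = mix * np.power(2.0, rng.normal(0.0, noise_sd, size=len(mix)))
    return mix


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

@dataclass
class SurvivalSimConfig:
    """Proportional-hazards cohort: hazard = baseline * exp(beta*score + covs)."""

    seed: int = 0
    n_patients: int = 500
    log_hazard_ratio: float = np.log(2.0)  # beta per unit score
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    covariate_effects: dict[str, float] = field(default_factory=dict)  # age/sex/stage

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigurationError("censoring_rate must be in [0, 1)")
        unknown = set(self.covariate_effects) - {"age", "sex", "stage"}
        if unknown:
            raise ConfigurationError(f"unknown covariates {unknown}")


def simulate_survival_cohort(
    cfg: SurvivalSimConfig, scores: np.ndarray | pd.Series | None = None
) -> pd.DataFrame:
    """Draw exponential event times with hazard depending on the score.

    ``scores`` defaults to standard-normal per-sample signature scores.
    Censoring is independent Uniform(0, c) with c calibrated so the
    realized censoring fraction approximates ``censoring_rate``. Age
    (standardized), sex (0/1) and stage (1-4, carried as a continuous
    covariate) are always generated; their log-hazard effects default
    to 0 unless set in ``covariate_effects``.
    """
    rng = _rng(cfg.seed, 41)
    n = cfg.n_patients
    if scores is None:
        scores = rng.normal(size=n)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (n,):
        raise ConfigurationError(f"scores must have length n_patients={n}")
    if not np.isfinite(scores).all():
        raise ConfigurationError("scores must be finite")

    age = rng.normal(0.0, 1.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    stage = rng.integers(1, 5, size=n).astype(float)
    eff = cfg.covariate_effects
    log_hazard = (
        np.log(cfg.baseline_hazard)
        + cfg.log_hazard_ratio * scores
        + eff.get("age", 0.0) * age
        + eff.get("sex", 0.0) * sex
        + eff.get("stage", 0.0) * stage
    )
    times = rng.exponential(np.exp(-log_hazard))

    event = np.ones(n, dtype=int)
    observed = times.copy()
    if cfg.censoring_rate > 0:
        c_max = _calibrate_uniform_censoring(times, cfg.censoring_rate)
        censor = rng.uniform(0.0, c_max, size=n)
        event = (times <= censor).astype(int)
        observed = np.minimum(times, censor)
    observed = np.maximum(observed, 1e-9)
    return pd.DataFrame(
        {
            "sample_id": [f"P{i + 1:04d}" for i in range(n)],
            "time": observed,
            "event": event,
            "score": scores,
            "age": age,
            "sex": sex,
            "stage": stage,
        }
    )


def _calibrate_uniform_censoring(times: np.ndarray, target: float) -> float:
    """Bisection for c such that mean_i P(U(0,c) < t_i) == target."""

    def frac(c: float) -> float:
        return float(np.mean(np.minimum(times / c, 1.0)))

    lo, hi = 1e-9, float(times.max()) * 2
    while frac(hi) > target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Multi-region cohorts
# ---------------------------------------------------------------------------

@dataclass
class MultiRegionSimConfig:
    """Multi-region cohort with latent per-patient labels and region flips.

    Each patient draws a latent high label with probability ``q_patient``;
    each region's label flips with probability ``epsilon``; region scores
    are drawn from label-conditional Gaussians.
    """

    seed: int = 0
    n_patients: int = 100
    region_count_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.3, 3: 0.25, 4: 0.15, 5: 0.1}
    )
    q_patient: float = 0.5
    epsilon: float = 0.0
    high_mean: float = 1.0
    low_mean: float = -1.0
    score_sd: float = 0.3

    def __post_init__(self) -> None:
        probs = np.array(list(self.region_count_distribution.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("region count probabilities must sum to 1")
        if any(k < 1 for k in self.region_count_distribution):
            raise ConfigurationError("region counts must be >= 1")
        if not 0.0 < self.q_patient < 1.0:
            raise ConfigurationError("q_patient must be in (0, 1)")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigurationError("epsilon must be in [0, 1]")


def simulate_multiregion_cohort(cfg: MultiRegionSimConfig) -> pd.DataFrame:
    """Return a region table with columns patient_id, region_id, score, true_label."""
    rng = _rng(cfg.seed, 53)
    counts = np.array(list(cfg.region_count_distribution.keys()))
    probs = np.array(list(cfg.region_count_distribution.values()), dtype=float)
    rows = []
    for p in range(cfg.n_patients):
        n_regions = int(rng.choice(counts, p=probs))
        latent_high = rng.random() < cfg.q_patient
        for r in range(n_regions):
            label_high = latent_high ^ (rng.random() < cfg.epsilon)
            mean = cfg.high_mean if label_high else cfg.low_mean
            score = rng.normal(mean, cfg.score_sd)
            rows.append(
                {
                    "patient_id": f"PT{p + 1:04d}",
                    "region_id": f"R{r + 1}",
                    "score": score,
                    "true_label": "high" if label_high else "low",
                }
            )
    return pd.DataFrame(rows)
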