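"""Differential ranking and gene set enrichment analysis.

Genes are ranked co-culture vs mono-culture by a pooled-variance Student
t statistic on log2(x+1) expression. Enrichment of a gene set along the
ranked list uses the weighted Kolmogorov-Smirnov running-sum statistic:
in-set genes increment the running sum by |metric|^p normalized to the
in-set total, out-of-set genes decrement it by 1/(N - N_hit); the
enrichment score (ES) is the signed maximum deviation and the leading
edge is the in-set genes at or before (for ES > 0) the extremum.

Significance uses a gene-set permutation null: for each set size, random
same-size gene sets are drawn without replacement from the ranked list.
The normalized enrichment score (NES) divides ES by the mean |null ES|
of matching sign, empirical p-values carry +1 smoothing, and the FDR q
is the sign-stratified ratio of null to observed tail fractions with a
monotonicity pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .simulate import CO, MONO, CultureExperiment

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8
ES_TIE_TOL = 1e-12  # |max| vs |min| running-sum ties break toward positive


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

@dataclass
class RankedList:
    """Genes sorted by a ranking metric, descending, ties broken by gene id."""

    genes: np.ndarray
    metric: np.ndarray
    metric_name: str = "tstat"

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked genes must be unique")
        if np.any(np.diff(self.metric) > 0):
            raise ValueError("metric must be sorted descending")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_scores(cls, genes, metric, metric_name: str = "tstat") -> "RankedList":
        genes = np.asarray(genes, dtype=object)
        metric = np.asarray(metric, dtype=float)
        order = sorted(range(len(genes)), key=lambda i: (-metric[i], genes[i]))
        return cls(genes[order], metric[order], metric_name)


def fold_changes(exp: CultureExperiment) -> pd.Series:
    """Per-gene linear fold change: mean(co samples) / mean(mono samples).

    Genes with mono mean 0 and co mean > 0 map to +inf; 0/0 maps to NaN
    and is excluded downstream. Returns a pandas Series indexed by gene.
    """
    mat = exp.expression.to_linear().data
    co = mat[exp.samples(CO)].mean(axis=1)
    mono = mat[exp.samples(MONO)].mean(axis=1)
    for cond, group in ((CO, co), (MONO, mono)):
        if float(mat[exp.samples(cond)].to_numpy().sum()) == 0.0:
            raise ValueError(f"condition {cond!r} has an all-zero library")
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = co / mono
    fc[(mono == 0) & (co > 0)] = np.inf
    fc[(mono == 0) & (co == 0)] = np.nan
    return pd.Series(fc, index=mat.index, name="fold_change")


def rank_by_tstat(exp: CultureExperiment) -> RankedList:
    """Rank genes by the pooled-variance two-sample t statistic (co - mono).

    Computed on the log2(x+1) scale with a variance floor of 1e-8 so that
    zero-variance genes yield a finite (or zero) metric instead of an
    infinity.
    """
    mat = exp.expression.to_log2p1().data
    co = mat[exp.samples(CO)].to_numpy()
    mono = mat[exp.samples(MONO)].to_numpy()
    n1, n2 = co.shape[1], mono.shape[1]
    mean_diff = co.mean(axis=1) - mono.mean(axis=1)
    pooled = ((n1 - 1) * co.var(axis=1, ddof=1) + (n2 - 1) * mono.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    pooled = np.maximum(pooled, VARIANCE_FLOOR)
    t = np.where(mean_diff == 0.0, 0.0, mean_diff / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2)))
    return RankedList.from_scores(mat.index.to_numpy(dtype=object), t)


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(
    ranked: RankedList, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS running-sum enrichment of ``gene_set`` along ``ranked``.

    Returns (ES, running sum over positions, leading-edge genes). If all
    in-set metric weights are zero, hit increments fall back to uniform
    1/N_hit so the statistic stays defined.
    """
    genes = ranked.genes
    members = set(getattr(gene_set, "genes", gene_set))
    hit = np.array([g in members for g in genes])
    n_hit = int(hit.sum())
    n = len(genes)
    if n_hit == 0:
        raise ValueError("no overlap between gene set and ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the entire ranked list; miss penalty undefined")
    weights = np.abs(ranked.metric) ** weight_p
    in_weights = np.where(hit, weights, 0.0)
    total = in_weights.sum()
    if total == 0.0:
        in_weights = hit / n_hit
        total = 1.0
    steps = in_weights / total - (~hit) / (n - n_hit)
    running = np.cumsum(steps)
    max_pos = float(running.max())
    min_neg = float(running.min())
    # exact magnitude ties are common (P_hit reaches exactly 1 at the last
    # in-set gene); break them toward the positive extremum deterministically
    if max_pos + min_neg >= -ES_TIE_TOL:
        extremum = int(np.argmax(running))
        es = max_pos
    else:
        extremum = int(np.argmin(running))
        es = min_neg
    if es >= 0:
        leading = [g for i, g in enumerate(genes) if hit[i] and i <= extremum]
    else:
        leading = [g for i, g in enumerate(genes) if hit[i] and i >= extremum]
    return es, running, leading


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many gene sets given 0-based hit positions.

    ``positions`` is (B, k); candidate extrema occur only just after a hit
    (running-sum local max) or just before one (local min), so the ES is
    computable from sorted hit positions alone.
    """
    pos = np.sort(positions, axis=1)
    k = pos.shape[1]
    w = weights[pos]
    total = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    j = np.arange(1, k + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum_frac = np.where(total > 0, cum / np.where(total > 0, total, 1.0), j / k)
    n_miss = n - k
    miss_through = (pos + 1 - j) / n_miss  # misses among the first pos+1 genes
    cand_max = cum_frac - miss_through
    prev_frac = np.concatenate([np.zeros((pos.shape[0], 1)), cum_frac[:, :-1]], axis=1)
    cand_min = prev_frac - (pos - (j - 1)) / n_miss  # just before each hit
    best_max = cand_max.max(axis=1)
    best_min = cand_min.min(axis=1)
    return np.where(best_max + best_min >= -ES_TIE_TOL, best_max, best_min)


# ---------------------------------------------------------------------------
# Permutation GSEA
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    leading_edge: list[str]
    n_permutations: int


def gsea(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> list[EnrichmentResult]:
    """Gene-set-permutation GSEA over a collection of sets.

    The null for each set is the ES distribution of ``n_perm`` random
    same-size gene sets drawn without replacement from the ranked genes.
    The null stream is seeded by (seed, set size), so duplicate sets —
    and more generally sets of equal size — share one null distribution
    and results are deterministic given the seed. Sets outside
    [min_size, max_size] after intersection are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked)
    weights = np.abs(ranked.metric) ** weight_p
    ranked_genes = set(ranked.genes)

    analysed = []
    for gs in sets:
        overlap = [g for g in gs.genes if g in ranked_genes]
        k = len(overlap)
        if k < min_size or k > max_size:
            logger.warning("skipping set %r: size %d outside [%d, %d]", gs.name, k, min_size, max_size)
            continue
        if k == n:
            logger.warning("skipping set %r: covers the whole ranked list", gs.name)
            continue
        es, _, leading = enrichment_score(ranked, overlap, weight_p)
        analysed.append((gs.name, k, es, leading))

    null_cache: dict[int, np.ndarray] = {}

    def null_es(k: int) -> np.ndarray:
        if k not in null_cache:
            rng = np.random.default_rng([seed, k])
            positions = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
            null_cache[k] = _es_from_positions(positions, weights, n)
        return null_cache[k]

    # per-set ES -> NES and smoothed one-sided p against the size-matched null
    records = []
    all_null_nes = []
    for name, k, es, leading in analysed:
        null = null_es(k)
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.abs(null).mean() or 1.0
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.abs(null).mean() or 1.0
        nes = es / pos_mean if es >= 0 else es / neg_mean
        if es >= 0:
            p = (1.0 + float((null >= es).sum())) / (1.0 + float((null >= 0).sum()))
        else:
            p = (1.0 + float((null <= es).sum())) / (1.0 + float((null < 0).sum()))
        p = min(p, 1.0)
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        all_null_nes.append(null_nes)
        records.append([name, k, es, nes, p, leading])

    qs = _fdr_q(
        np.array([r[3] for r in records]),
        np.concatenate(all_null_nes) if all_null_nes else np.array([]),
    )
    return [
        EnrichmentResult(name, k, es, nes, p, q, leading, n_perm)
        for (name, k, es, nes, p, leading), q in zip(records, qs)
    ]


def _fdr_q(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Sign-stratified permutation FDR on NES values.

    q(NES*) = [null tail fraction at NES*] / [observed tail fraction at
    NES*] within the matching sign class, clipped to [0, 1] and made
    monotone non-decreasing toward less extreme NES.
    """
    q = np.ones(len(obs_nes))
    for sign in (1, -1):
        mask = obs_nes >= 0 if sign > 0 else obs_nes < 0
        if not mask.any():
            continue
        null = null_nes[null_nes >= 0] if sign > 0 else null_nes[null_nes < 0]
        obs = obs_nes[mask]
        raw = np.empty(len(obs))
        for i, v in enumerate(obs):
            if sign > 0:
                null_tail = (null >= v).mean() if len(null) else 1.0
                obs_tail = (obs >= v).mean()
            else:
                null_tail = (null <= v).mean() if len(null) else 1.0
                obs_tail = (obs <= v).mean()
            raw[i] = min(1.0, null_tail / obs_tail)
        # monotone: a less extreme NES never gets a smaller q
        order = np.argsort(-sign * obs, kind="stable")
        raw[order] = np.maximum.accumulate(raw[order])
        q[mask] = raw
    return q
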