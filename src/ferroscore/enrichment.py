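"""Single-sample and two-group gene-set enrichment engines.

Implements from scratch:

* ssGSEA — the rank-weighted running-sum score of Barbie et al., one
  enrichment score per gene set per sample.
* GSVA-style scoring — kernel-CDF expression standardization followed by a
  Kolmogorov-Smirnov-like random walk, one score per set per sample.
* Classic two-group GSEA with a signal-to-noise ranking metric and a
  label-permutation null.
* Benjamini-Hochberg step-up FDR adjustment.

All walks break expression ties by stable gene-id order so scores are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, GeneSetCollection, InputError

__all__ = [
    "ScoreMatrix",
    "GSEAResult",
    "ssgsea_scores",
    "gsva_scores",
    "gsea_two_group",
    "gsea_preranked",
    "bh_adjust",
]


@dataclass
class ScoreMatrix:
    """A gene-sets x samples enrichment score matrix."""

    set_names: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    method_tag: str = "ssgsea"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.set_names), len(self.sample_ids)):
            raise InputError("score matrix shape does not match its labels")
        if not np.all(np.isfinite(self.scores)):
            raise InputError("score matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.sample_ids)

    def row(self, set_name: str) -> np.ndarray:
        try:
            i = self.set_names.index(set_name)
        except ValueError:
            raise KeyError(f"score matrix has no row {set_name!r}") from None
        return self.scores[i]


@dataclass
class GSEAResult:
    """One gene set's two-group GSEA outcome."""

    set_name: str
    es: float
    nes: float
    pvalue: float
    padj: float
    size: int


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("bh_adjust expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _descending_order(values: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Indices sorting ``values`` descending, ties broken by gene id."""
    tie_rank = np.argsort(np.argsort(np.asarray(gene_ids, dtype=object), kind="stable"))
    return np.lexsort((tie_rank, -values))


def _set_indicators(
    genes: list[str], sets: GeneSetCollection, allow_full: bool = False
) -> dict[str, np.ndarray]:
    gene_index = {g: i for i, g in enumerate(genes)}
    indicators: dict[str, np.ndarray] = {}
    for s in sets:
        ind = np.zeros(len(genes), dtype=bool)
        for g in s.members:
            i = gene_index.get(g)
            if i is not None:
                ind[i] = True
        if not ind.any():
            raise InputError(f"gene set {s.name!r} has no members present in the expression matrix")
        if ind.all() and not allow_full:
            raise InputError(
                f"gene set {s.name!r} covers every gene in the matrix; "
                "the out-of-set walk is undefined"
            )
        indicators[s.name] = ind
    return indicators


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> ScoreMatrix:
    """Per-sample ssGSEA enrichment scores.

    For each sample, genes are ordered by decreasing expression and the score
    is the sum over all rank positions of the difference between the
    weighted in-set cumulative fraction (weight = rank value ** alpha, the
    highest-expressed gene carrying rank N) and the uniform out-of-set
    cumulative fraction.  With ``normalize``, the whole matrix is divided by
    its global score range.
    """
    if alpha < 0:
        raise InputError("alpha must be >= 0")
    indicators = _set_indicators(expr.gene_ids, sets)
    n_genes, n_samples = expr.values.shape

    # walk order per sample (descending expression, gene-id tie-break)
    tie_rank = np.argsort(np.argsort(np.asarray(expr.gene_ids, dtype=object), kind="stable"))
    order = np.lexsort(
        (np.broadcast_to(tie_rank[:, None], expr.values.shape), -expr.values), axis=0
    )
    # ordinal rank values along the walk: N at the top of the list
    rank_weight = (np.arange(n_genes, 0, -1, dtype=float) ** alpha)[:, None]

    scores = np.empty((len(sets), n_samples))
    for k, s in enumerate(sets):
        in_set = indicators[s.name][order]  # (genes, samples) along walk order
        w_in = np.where(in_set, rank_weight, 0.0)
        p_in = np.cumsum(w_in, axis=0) / np.sum(w_in, axis=0, keepdims=True)
        n_out = n_genes - in_set.sum(axis=0)
        p_out = np.cumsum(~in_set, axis=0) / n_out
        scores[k] = np.sum(p_in - p_out, axis=0)

    if normalize:
        rng = scores.max() - scores.min()
        if rng == 0:
            raise InputError("cannot normalize: all ssGSEA scores are identical")
        scores = scores / rng
    return ScoreMatrix(sets.names, list(expr.sample_ids), scores, method_tag="ssgsea")


def _kcdf_transform(values: np.ndarray, kcdf: str) -> np.ndarray:
    """Cross-sample cumulative statistic per gene (rows)."""
    n_genes, n_samples = values.shape
    z = np.empty_like(values, dtype=float)
    if kcdf == "none":
        for i in range(n_genes):
            z[i] = stats.rankdata(values[i], method="average") / n_samples
    elif kcdf == "gaussian":
        sd = values.std(axis=1, ddof=1)
        h = np.where(sd > 0, sd / 4.0, 1.0)
        for i in range(n_genes):
            diffs = (values[i][:, None] - values[i][None, :]) / h[i]
            z[i] = stats.norm.cdf(diffs).mean(axis=1)
    elif kcdf == "poisson":
        for i in range(n_genes):
            lam = values[i][None, :] + 0.5
            z[i] = stats.poisson.cdf(values[i][:, None], lam).mean(axis=1)
    else:
        raise InputError(f"unknown kcdf {kcdf!r}")
    return z


def gsva_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
    max_diff: bool = True,
    kcdf: str = "gaussian",
) -> ScoreMatrix:
    """Per-sample GSVA-style pathway scores.

    Each gene's expression is first transformed to a cross-sample cumulative
    statistic (gaussian kernel CDF with bandwidth SD/4, poisson kernel for
    counts, or the empirical CDF).  Per sample the transformed values are
    converted to ranks, centred into the symmetric statistic |N/2 - rank|,
    and a KS-like walk down the ranked gene list accumulates in-set weight
    |r|**tau against a uniform out-of-set penalty.  The score is
    max-positive minus |max-negative| deviation (``max_diff``) or the signed
    maximum deviation otherwise.
    """
    n_genes, n_samples = expr.values.shape
    if n_samples < 4:
        raise InputError("gsva_scores requires at least 4 samples for the kernel CDF")
    indicators = _set_indicators(expr.gene_ids, sets)

    z = _kcdf_transform(expr.values, kcdf)
    scores = np.empty((len(sets), n_samples))
    for j in range(n_samples):
        order = _descending_order(z[:, j], expr.gene_ids)
        # rank 1 = largest transformed value; symmetric statistic peaks at extremes
        ranks = np.empty(n_genes)
        ranks[order] = np.arange(1, n_genes + 1)
        r_stat = np.abs(n_genes / 2.0 - ranks)
        w = np.abs(r_stat[order]) ** tau
        for k, s in enumerate(sets):
            in_set = indicators[s.name][order]
            w_in = np.where(in_set, w, 0.0)
            denom = w_in.sum()
            p_in = np.cumsum(w_in) / (denom if denom > 0 else 1.0)
            p_out = np.cumsum(~in_set) / (n_genes - in_set.sum())
            walk = p_in - p_out
            if max_diff:
                scores[k, j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
            else:
                scores[k, j] = walk[np.argmax(np.abs(walk))]
    return ScoreMatrix(sets.names, list(expr.sample_ids), scores, method_tag="gsva")


def _signal_to_noise(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-gene signal-to-noise ratio between class 1 and class 0.

    Standard deviations are floored at 20% of the class mean magnitude (and
    at 0.2 absolute), the usual guard against near-constant genes.
    """
    g1, g0 = values[:, labels == 1], values[:, labels == 0]
    m1, m0 = g1.mean(axis=1), g0.mean(axis=1)
    s1, s0 = g1.std(axis=1, ddof=1), g0.std(axis=1, ddof=1)
    s1 = np.maximum(s1, np.maximum(0.2 * np.abs(m1), 0.2))
    s0 = np.maximum(s0, np.maximum(0.2 * np.abs(m0), 0.2))
    return (m1 - m0) / (s1 + s0)


def _weighted_ks_es(metric: np.ndarray, order: np.ndarray, in_set: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS walk (weight exponent 1)."""
    ind = in_set[order]
    w = np.abs(metric[order])
    w_in = np.where(ind, w, 0.0)
    denom = w_in.sum()
    if denom == 0:
        # all in-set metrics exactly zero: fall back to unweighted hits
        w_in = ind.astype(float)
        denom = w_in.sum()
    p_hit = np.cumsum(w_in) / denom
    p_miss = np.cumsum(~ind) / (ind.size - ind.sum())
    walk = p_hit - p_miss
    return float(walk[np.argmax(np.abs(walk))])


def _es_all_sets(
    metric: np.ndarray, gene_ids: list[str], indicators: dict[str, np.ndarray]
) -> dict[str, float]:
    order = _descending_order(metric, gene_ids)
    return {name: _weighted_ks_es(metric, order, ind) for name, ind in indicators.items()}


def gsea_two_group(
    expr: ExpressionMatrix,
    labels,
    sets: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[GSEAResult], list[tuple[str, int]]]:
    """Two-group GSEA with a label-permutation null.

    Genes are ranked by signal-to-noise between the two classes; each set's
    enrichment score is the signed maximum of the weighted KS walk.  The null
    distribution comes from ``n_perm`` label permutations; NES divides the
    observed score by the mean |null score| of matching sign, and the
    two-sided permutation p-value uses the add-one estimator.  Sets whose
    intersection with the matrix falls outside [min_size, max_size] are
    excluded and reported as ``(name, size)`` pairs.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise InputError("gsea_two_group requires exactly two classes")
    y = (labels == classes[1]).astype(int)
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise InputError("each class needs at least 3 samples")

    indicators_all = _set_indicators(expr.gene_ids, sets, allow_full=True)
    retained: dict[str, np.ndarray] = {}
    excluded: list[tuple[str, int]] = []
    for name, ind in indicators_all.items():
        size = int(ind.sum())
        if min_size <= size <= max_size and size < expr.n_genes:
            retained[name] = ind
        else:
            excluded.append((name, size))
    if not retained:
        raise InputError("no gene set survives the size filter")

    metric = _signal_to_noise(expr.values, y)
    observed = _es_all_sets(metric, expr.gene_ids, retained)

    rng = np.random.default_rng(seed)
    null = {name: np.empty(n_perm) for name in retained}
    for p in range(n_perm):
        perm = rng.permutation(y)
        es_p = _es_all_sets(_signal_to_noise(expr.values, perm), expr.gene_ids, retained)
        for name, v in es_p.items():
            null[name][p] = v

    results: list[GSEAResult] = []
    pvals = []
    for name, ind in retained.items():
        es = observed[name]
        nulls = null[name]
        same_sign = nulls[np.sign(nulls) == np.sign(es)] if es != 0 else nulls
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(nulls).mean()
        nes = es / denom if denom > 0 else 0.0
        p = (1.0 + np.sum(np.abs(nulls) >= abs(es))) / (n_perm + 1.0)
        pvals.append(p)
        results.append(GSEAResult(name, es, float(nes), float(p), np.nan, int(ind.sum())))
    padj = bh_adjust(np.array(pvals))
    for r, a in zip(results, padj):
        r.padj = float(a)
    results.sort(key=lambda r: r.pvalue)
    return results, excluded


def gsea_preranked(
    ranking: pd.Series,
    sets: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[GSEAResult], list[tuple[str, int]]]:
    """GSEA on a user-supplied gene ranking (e.g. GSVA-score contrasts).

    The null permutes gene labels of the ranking, since no sample labels
    exist to permute.
    """
    genes = [str(g) for g in ranking.index]
    metric = ranking.to_numpy(dtype=float)
    if len(set(genes)) != len(genes):
        raise InputError("preranked input has duplicate gene ids")

    dummy_sets = sets
    gene_index = {g: i for i, g in enumerate(genes)}
    retained: dict[str, np.ndarray] = {}
    excluded: list[tuple[str, int]] = []
    for s in dummy_sets:
        ind = np.zeros(len(genes), dtype=bool)
        for g in s.members:
            i = gene_index.get(g)
            if i is not None:
                ind[i] = True
        size = int(ind.sum())
        if min_size <= size <= max_size and 0 < size < len(genes):
            retained[s.name] = ind
        else:
            excluded.append((s.name, size))
    if not retained:
        raise InputError("no gene set survives the size filter")

    observed = _es_all_sets(metric, genes, retained)
    rng = np.random.default_rng(seed)
    null = {name: np.empty(n_perm) for name in retained}
    order_fixed = _descending_order(metric, genes)
    for p in range(n_perm):
        shuffled = rng.permutation(len(genes))
        for name, ind in retained.items():
            null[name][p] = _weighted_ks_es(metric, order_fixed, ind[shuffled])
    results: list[GSEAResult] = []
    pvals = []
    for name, ind in retained.items():
        es = observed[name]
        nulls = null[name]
        same_sign = nulls[np.sign(nulls) == np.sign(es)] if es != 0 else nulls
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(nulls).mean()
        nes = es / denom if denom > 0 else 0.0
        p = (1.0 + np.sum(np.abs(nulls) >= abs(es))) / (n_perm + 1.0)
        pvals.append(p)
        results.append(GSEAResult(name, es, float(nes), float(p), np.nan, int(ind.sum())))
    padj = bh_adjust(np.array(pvals))
    for r, a in zip(results, padj):
        r.padj = float(a)
    results.sort(key=lambda r: r.pvalue)
    return results, excluded
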