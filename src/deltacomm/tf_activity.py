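"""Transcription-factor activity from regulon enrichment.

A *regulon* is the intersection of a TF's prior targets with the genes
coexpressed with that TF (Spearman rho > rho_cut, test p < p_cut) in the
receiver cells.  The disease-vs-control fold-change ranking of all matrix
genes is then scored against the regulon with a weighted Kolmogorov-Smirnov
enrichment statistic (classic GSEA).  The null is gene-set permutation:
random same-size gene sets drawn from the ranking.  The normalized
enrichment score (NES) divides the observed ES by the mean |ES| of
same-sign permutation statistics; the permutation p-value counts same-sign
nulls at least as extreme, with the +1 pseudo-count floor.

Directional gating turns a GSEA result into a non-negative TF activity:
``up`` keeps |NES| only for significant positive enrichment, ``down`` only
for significant negative enrichment, ``both`` for either.  When an L-R pair
has several downstream TFs, the per-axis activities are combined by an
inverse-path-length weighted mean (weight 1/M, M = shortest receptor->TF
step count).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import AnnotatedMatrix, FoldChangeTable

__all__ = [
    "Regulon",
    "GseaResult",
    "TFActivity",
    "AggregatedTF",
    "build_regulon",
    "rank_genes",
    "gsea",
    "adjust_pvalues",
    "tf_activity_score",
    "aggregate_tf_scores",
]


@dataclass
class Regulon:
    tf: str
    targets: set[str]
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)  # gene -> (rho, p)


@dataclass
class GseaResult:
    tf: str
    es: float
    nes: float
    p: float
    adj_p: float | None
    n_perm: int
    seed: int | None
    set_size: int


@dataclass
class TFActivity:
    tf: str
    direction: str
    score: float
    alpha: float


@dataclass
class AggregatedTF:
    tf_k: float
    contributions: list[tuple[str, int, float]]  # (tf, distance M, score)


def build_regulon(
    tf: str,
    prior_targets: set[str],
    matrix: AnnotatedMatrix,
    cell_mask: np.ndarray,
    rho_cut: float = 0.1,
    p_cut: float = 0.05,
) -> Regulon:
    """Coexpression-filtered regulon over the selected cells.

    Targets absent from the matrix are dropped; a TF absent from the matrix
    yields an empty regulon with a warning.
    """
    if int(cell_mask.sum()) < 3:
        raise ValueError("regulon construction requires at least 3 cells")
    if tf not in matrix.genes:
        warnings.warn(f"TF {tf!r} absent from matrix; empty regulon")
        return Regulon(tf=tf, targets=set())
    tf_expr = matrix.gene_values(tf, mask=cell_mask)
    candidates = sorted(g for g in prior_targets if g in set(matrix.genes))
    retained: set[str] = set()
    stats_out: dict[str, tuple[float, float]] = {}
    if np.ptp(tf_expr) == 0:
        warnings.warn(f"TF {tf!r} constant over selected cells; empty regulon")
        return Regulon(tf=tf, targets=set())
    block = matrix.matrix(candidates, mask=cell_mask)
    for j, gene in enumerate(candidates):
        y = block[:, j]
        if np.ptp(y) == 0:
            continue
        rho, p = stats.spearmanr(tf_expr, y)
        if np.isnan(rho):
            continue
        if rho > rho_cut and p < p_cut:
            retained.add(gene)
            stats_out[gene] = (float(rho), float(p))
    return Regulon(tf=tf, targets=retained, stats=stats_out)


def rank_genes(fc: FoldChangeTable) -> pd.Series:
    """Fold changes sorted descending; ties broken by gene symbol ascending."""
    if fc.fc.empty:
        raise ValueError("fold-change table is empty")
    s = fc.fc.rename("log2fc").rename_axis("gene")
    df = s.reset_index().sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    )
    return pd.Series(df["log2fc"].values, index=df["gene"].values)


def _es_from_indicator(scores: np.ndarray, hit: np.ndarray, w: float) -> float:
    """Signed max-deviation running-sum ES for one hit indicator."""
    n = scores.size
    nh = int(hit.sum())
    weights = np.abs(scores) ** w
    nr = float(weights[hit].sum())
    inc = np.empty(n)
    if nr > 0:
        inc[hit] = weights[hit] / nr
    else:  # degenerate all-zero scores in the set: unweighted hits
        inc[hit] = 1.0 / nh
    inc[~hit] = -1.0 / (n - nh)
    run = np.cumsum(inc)
    return float(run[np.argmax(np.abs(run))])


def _null_es(scores: np.ndarray, set_size: int, w: float, picks: np.ndarray) -> np.ndarray:
    """Vectorized ES for many permuted gene sets.

    ``picks`` is (B, set_size) integer positions into the ranking.
    """
    B = picks.shape[0]
    n = scores.size
    weights = np.abs(scores) ** w
    hitw = weights[picks]  # (B, k)
    nr = hitw.sum(axis=1)  # (B,)
    miss = -1.0 / (n - set_size)
    inc = np.full((B, n), miss)
    rows = np.repeat(np.arange(B), set_size)
    vals = np.where(
        nr[:, None] > 0, hitw / np.where(nr[:, None] > 0, nr[:, None], 1.0), 1.0 / set_size
    )
    inc[rows, picks.ravel()] = vals.ravel()
    run = np.cumsum(inc, axis=1)
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(B), idx]


def gsea(
    ranked: pd.Series,
    gene_set,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> GseaResult:
    """Classic gene-set-permutation GSEA on a ranked fold-change list.

    ``ranked`` maps gene -> score, descending.  With ``exhaustive=True`` the
    null enumerates every same-size subset of the ranking instead of sampling
    (only sensible for tiny instances).  p uses the +1 floor:
    ``(1 + #{same-sign |null| >= |ES|}) / (1 + #same-sign nulls)``.
    """
    genes = np.asarray(ranked.index)
    scores = np.asarray(ranked.values, dtype=float)
    n = genes.size
    in_rank = set(genes)
    eff = sorted(set(gene_set) & in_rank)
    dropped = set(gene_set) - in_rank
    if dropped:
        warnings.warn(f"{len(dropped)} gene-set members absent from ranking dropped")
    k = len(eff)
    if k == 0:
        raise ValueError("gene set has no members in the ranking")
    if k >= n:
        raise ValueError("gene set must be a strict subset of the ranking")
    hit = np.isin(genes, eff)
    es = _es_from_indicator(scores, hit, weight_exponent)

    if exhaustive:
        picks = np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)
        n_used = picks.shape[0]
    else:
        if seed is None:
            raise ValueError("seed is required for sampled permutations")
        rng = np.random.default_rng(seed)
        # B x k distinct positions per row
        picks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k].astype(np.intp)
        n_used = n_perm
    null = _null_es(scores, k, weight_exponent, picks)

    if es > 0:
        same = null[null > 0]
    elif es < 0:
        same = null[null < 0]
    else:
        same = np.array([])
    n_same = same.size
    if n_same == 0:
        nes = 0.0
        p = 1.0
    else:
        nes = es / float(np.abs(same).mean())
        p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + n_same)
    return GseaResult(
        tf="", es=es, nes=float(nes), p=float(p), adj_p=None,
        n_perm=n_used, seed=seed, set_size=k,
    )


def adjust_pvalues(ps) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    ps = np.asarray(list(ps), dtype=float)
    if ps.size == 0:
        return ps
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(ps, method="fdr_bh")[1]


def tf_activity_score(
    res: GseaResult, direction: str, alpha: float = 0.05, gate_on: str = "adj_p"
) -> TFActivity:
    """Directional gate turning a GSEA result into a non-negative activity.

    up:   |NES| if gate-p < alpha and NES > 0, else 0
    down: |NES| if gate-p < alpha and NES < 0, else 0
    both: |NES| if gate-p < alpha, else 0
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if gate_on == "adj_p":
        gate_p = res.adj_p if res.adj_p is not None else res.p
    elif gate_on == "p":
        gate_p = res.p
    else:
        raise ValueError(f"gate_on must be 'p' or 'adj_p', got {gate_on!r}")
    score = 0.0
    if gate_p < alpha:
        if direction == "up" and res.nes > 0:
            score = abs(res.nes)
        elif direction == "down" and res.nes < 0:
            score = abs(res.nes)
        elif direction == "both":
            score = abs(res.nes)
    return TFActivity(tf=res.tf, direction=direction, score=score, alpha=alpha)


def aggregate_tf_scores(scored: list[tuple[TFActivity, int]]) -> AggregatedTF:
    """Inverse-path-length weighted mean over an axis group's TF activities:
    TF_k = sum(score_i / M_i) / sum(1 / M_i)."""
    if not scored:
        raise ValueError("no TF activities to aggregate")
    num = 0.0
    den = 0.0
    contrib = []
    for act, m in scored:
        if m < 1:
            raise ValueError("distance M must be >= 1")
        num += act.score / m
        den += 1.0 / m
        contrib.append((act.tf, m, act.score))
    return AggregatedTF(tf_k=num / den, contributions=contrib)
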