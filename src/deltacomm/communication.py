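"""Unified communication scoring between sender and receiver cell types.

For each candidate sender -> receiver L-R pair passing the expression filter,
the score is

    S_k = ||LR_k||_2 x TF_k

where ``||LR_k||_2 = sqrt(softmax_L^2 + softmax_R^2)`` combines the
cell-type-specificity of ligand and receptor expression (softmax of the
per-cell-type summaries, taken across all cell types for each role) and
``TF_k`` is the aggregated downstream TF activity change in the receiver
(see :mod:`deltacomm.tf_activity`).  A pair is called *altered* when
S_k > 0, i.e. at least one downstream TF passed the significance gate.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import (
    AnnotatedMatrix,
    complex_expression_per_cell,
    compute_fold_changes,
)
from .knowledge_base import LRTFAxis, TFTGDatabase
from .tf_activity import (
    GseaResult,
    adjust_pvalues,
    aggregate_tf_scores,
    build_regulon,
    gsea,
    rank_genes,
    tf_activity_score,
)

__all__ = [
    "PipelineConfig",
    "CandidatePair",
    "enumerate_candidates",
    "softmax_pair",
    "lr_norm",
    "run_communication",
]

RESULT_COLUMNS = [
    "sender", "receiver", "ligand", "receptor", "pair_key",
    "softmax_L", "softmax_R", "l2_norm", "tf_list", "TF_k", "S_k", "altered",
]

DETAIL_COLUMNS = [
    "sender", "receiver", "pair_key", "tf", "distance",
    "n_targets", "ES", "NES", "p", "adj_p", "score",
]


@dataclass
class PipelineConfig:
    """All tunables of the scoring pipeline.  ``seed`` is mandatory whenever
    sampled permutations are used."""

    direction: str = "both"            # up | down | both
    alpha: float = 0.05                # significance gate for TF activity
    gate_on: str = "adj_p"             # p | adj_p
    statistic: str = "mean"            # mean | quantile
    quantile_q: float | None = None
    min_expressed_fraction: float = 0.10
    epsilon: float = 0.01              # fold-change pseudocount
    scale: float = 1e4                 # normalization scale factor
    rho_cut: float = 0.1               # regulon Spearman rho cutoff
    p_cut: float = 0.05                # regulon correlation-test p cutoff
    n_perm: int = 1000
    seed: int | None = None
    regulon_scope: str = "receiver"    # receiver | all

    def __post_init__(self):
        if self.direction not in ("up", "down", "both"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.gate_on not in ("p", "adj_p"):
            raise ValueError("gate_on must be 'p' or 'adj_p'")
        if self.statistic not in ("mean", "quantile"):
            raise ValueError("statistic must be 'mean' or 'quantile'")
        if self.statistic == "quantile" and not (self.quantile_q and 0 < self.quantile_q <= 1):
            raise ValueError("quantile statistic requires quantile_q in (0, 1]")
        if not (0 <= self.min_expressed_fraction < 1):
            raise ValueError("min_expressed_fraction must be in [0, 1)")
        if self.regulon_scope not in ("receiver", "all"):
            raise ValueError("regulon_scope must be 'receiver' or 'all'")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CandidatePair:
    sender: str
    receiver: str
    pair_key: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    axes: list[LRTFAxis] = field(default_factory=list)
    ligand_fraction: float = 0.0
    receptor_fraction: float = 0.0


def _detected_fraction(matrix: AnnotatedMatrix, gene: str, mask: np.ndarray) -> float:
    v = matrix.gene_values(gene, mask=mask)
    return float((v > 0).mean()) if v.size else 0.0


def enumerate_candidates(
    axes: list[LRTFAxis], matrix: AnnotatedMatrix, config: PipelineConfig
) -> list[CandidatePair]:
    """All (sender, receiver, L-R pair) combinations passing the expression
    filter: every ligand subunit detected (> 0) in at least
    ``min_expressed_fraction`` of sender cells, every receptor subunit
    likewise in receiver cells.  Self-pairs (sender == receiver) are allowed.
    """
    cell_types = matrix.cell_types
    masks = {ct: matrix.cell_mask(cell_type=ct) for ct in cell_types}
    # group axes by L-R pair
    groups: dict[str, list[LRTFAxis]] = {}
    for a in axes:
        groups.setdefault(a.pair_key, []).append(a)
    frac_cache: dict[tuple[str, str], float] = {}

    def frac(gene: str, ct: str) -> float:
        key = (gene, ct)
        if key not in frac_cache:
            frac_cache[key] = _detected_fraction(matrix, gene, masks[ct])
        return frac_cache[key]

    out: list[CandidatePair] = []
    thr = config.min_expressed_fraction
    genes_present = set(matrix.genes)

    def passes(fracs: list[float], subunits) -> bool:
        # threshold 0 keeps any pair whose genes exist in the matrix
        if thr == 0:
            return all(g in genes_present for g in subunits)
        return all(f > thr for f in fracs)

    for key in sorted(groups):
        group = groups[key]
        lig, rec = group[0].ligand_subunits, group[0].receptor_subunits
        for sender in cell_types:
            lig_fracs = [frac(g, sender) for g in lig]
            if not passes(lig_fracs, lig):
                continue
            for receiver in cell_types:
                rec_fracs = [frac(g, receiver) for g in rec]
                if not passes(rec_fracs, rec):
                    continue
                out.append(
                    CandidatePair(
                        sender=sender, receiver=receiver, pair_key=key,
                        ligand_subunits=lig, receptor_subunits=rec, axes=group,
                        ligand_fraction=min(lig_fracs),
                        receptor_fraction=min(rec_fracs),
                    )
                )
    if not out:
        warnings.warn("no candidate pairs passed the expression filter")
    return out


def softmax_pair(values, index: int) -> float:
    """Softmax of one entry among the per-cell-type summaries (max-shifted)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("softmax over an empty list")
    e = np.exp(v - v.max())
    return float(e[index] / e.sum())


def lr_norm(softmax_l: float, softmax_r: float) -> float:
    """L2 norm of the softmaxed ligand/receptor specificity pair."""
    return float(np.sqrt(softmax_l**2 + softmax_r**2))


def _summaries_by_cell_type(
    matrix: AnnotatedMatrix, subunits, config: PipelineConfig
) -> pd.Series:
    """Summary statistic (mean or lower-interpolation quantile) of a
    gene/complex per cell type, over all conditions."""
    vals = {}
    for ct in matrix.cell_types:
        mask = matrix.cell_mask(cell_type=ct)
        per_cell = complex_expression_per_cell(matrix, list(subunits), mask=mask)
        if config.statistic == "mean":
            vals[ct] = float(per_cell.mean())
        else:
            k = int(np.ceil(config.quantile_q * per_cell.size))
            vals[ct] = float(np.sort(per_cell)[k - 1])
    return pd.Series(vals)


def _stable_seed(base_seed: int, *tokens: str) -> int:
    """Deterministic per-(receiver, TF) seed independent of iteration order."""
    h = zlib.crc32("|".join(tokens).encode())
    return int((base_seed * 1_000_003 + h) % (2**31 - 1))


def run_communication(
    matrix: AnnotatedMatrix,
    axes: list[LRTFAxis],
    tftg: TFTGDatabase,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full two-condition communication scoring.

    Returns ``(results, detail)``: one row per candidate (sender, receiver,
    L-R pair) with softmax weights, ||LR||_2, aggregated TF_k and S_k; and a
    long-format per-TF table with regulon sizes and GSEA statistics.
    Deterministic given ``config.seed``.
    """
    if not matrix.normalized:
        raise ValueError("run_communication requires a normalized matrix")
    if config.seed is None:
        raise ValueError("config.seed must be set")
    candidates = enumerate_candidates(axes, matrix, config)

    # fold changes and gene ranking once per receiver cell type
    receivers = sorted({c.receiver for c in candidates})
    rankings: dict[str, pd.Series] = {}
    for ct in receivers:
        fc = compute_fold_changes(matrix, ct, epsilon=config.epsilon)
        rankings[ct] = rank_genes(fc)

    # GSEA once per (receiver, TF); BH across TFs within a receiver
    needed: dict[str, set[str]] = {ct: set() for ct in receivers}
    for c in candidates:
        for a in c.axes:
            needed[c.receiver].add(a.tf)

    gsea_cache: dict[tuple[str, str], GseaResult] = {}
    for ct in receivers:
        mask = (
            matrix.cell_mask(cell_type=ct)
            if config.regulon_scope == "receiver"
            else np.ones(len(matrix.cells), dtype=bool)
        )
        results_ct: dict[str, GseaResult] = {}
        for tf in sorted(needed[ct]):
            prior = tftg.get(tf, set())
            regulon = build_regulon(
                tf, prior, matrix, mask, rho_cut=config.rho_cut, p_cut=config.p_cut
            )
            ranking = rankings[ct]
            n_eff = len(set(regulon.targets) & set(ranking.index))
            if n_eff == 0 or n_eff >= len(ranking):
                res = GseaResult(tf=tf, es=0.0, nes=0.0, p=1.0, adj_p=None,
                                 n_perm=0, seed=None, set_size=n_eff)
            else:
                res = gsea(
                    ranking, regulon.targets,
                    n_perm=config.n_perm,
                    seed=_stable_seed(config.seed, ct, tf),
                )
                res.tf = tf
            results_ct[tf] = res
        tfs = sorted(results_ct)
        if tfs:
            adj = adjust_pvalues([results_ct[t].p for t in tfs])
            for t, a in zip(tfs, adj):
                results_ct[t].adj_p = float(a)
        for t in tfs:
            gsea_cache[(ct, t)] = results_ct[t]

    # ligand/receptor summaries and softmax across cell types, per role
    summary_cache: dict[tuple[str, tuple[str, ...]], pd.Series] = {}

    def summaries(subunits: tuple[str, ...]) -> pd.Series:
        key = ("x", tuple(subunits))
        if key not in summary_cache:
            summary_cache[key] = _summaries_by_cell_type(matrix, subunits, config)
        return summary_cache[key]

    rows = []
    detail_rows = []
    for c in candidates:
        lig_sum = summaries(c.ligand_subunits)
        rec_sum = summaries(c.receptor_subunits)
        cts = list(lig_sum.index)
        sm_l = softmax_pair(lig_sum.values, cts.index(c.sender))
        sm_r = softmax_pair(rec_sum.values, cts.index(c.receiver))
        norm = lr_norm(sm_l, sm_r)
        scored = []
        for a in c.axes:
            res = gsea_cache[(c.receiver, a.tf)]
            act = tf_activity_score(
                res, config.direction, alpha=config.alpha, gate_on=config.gate_on
            )
            scored.append((act, a.distance))
            detail_rows.append({
                "sender": c.sender, "receiver": c.receiver, "pair_key": c.pair_key,
                "tf": a.tf, "distance": a.distance, "n_targets": res.set_size,
                "ES": res.es, "NES": res.nes, "p": res.p, "adj_p": res.adj_p,
                "score": act.score,
            })
        agg = aggregate_tf_scores(scored)
        s_k = norm * agg.tf_k
        rows.append({
            "sender": c.sender, "receiver": c.receiver,
            "ligand": "+".join(sorted(c.ligand_subunits)),
            "receptor": "+".join(sorted(c.receptor_subunits)),
            "pair_key": c.pair_key,
            "softmax_L": sm_l, "softmax_R": sm_r, "l2_norm": norm,
            "tf_list": ";".join(sorted({a.tf for a in c.axes})),
            "TF_k": agg.tf_k, "S_k": s_k, "altered": s_k > 0,
        })
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    detail = pd.DataFrame(detail_rows, columns=DETAIL_COLUMNS)
    if not results.empty:
        results = results.sort_values(
            ["S_k", "sender", "receiver", "pair_key"],
            ascending=[False, True, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return results, detail
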