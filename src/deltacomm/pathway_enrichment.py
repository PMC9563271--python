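"""Pathway enrichment of altered L-R pairs.

Two complementary readouts per pathway:

* **PAS** — Jaccard overlap between the altered-pair set C and the pathway's
  pair set P, ``|C n P| / |C u P|``, z-normalized across pathways (population
  standard deviation) to give **nPAS**.
* An upper-tail hypergeometric p-value
  ``P(X >= q)`` with q = overlap, t = altered pairs, n = pathway pairs and
  m = universe size (distinct pairs in the pathway database), BH-adjusted
  across pathways within a scope.

Scopes are sender->receiver cell-type pairs by default (matching per-column
reporting of communication between specific populations), or pooled.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .knowledge_base import PathwayDatabase
from .tf_activity import adjust_pvalues

__all__ = [
    "pathway_activity_score",
    "normalize_pas",
    "hypergeometric_p",
    "enrich",
]

ENRICH_COLUMNS = [
    "scope", "pathway_id", "q", "t", "n", "m", "PAS", "nPAS", "P", "adj_P",
]


def pathway_activity_score(c_lr: set, p_lr: set) -> float:
    """Jaccard index of the altered L-R set and the pathway's L-R set."""
    if not c_lr:
        raise ValueError("altered pair set is empty")
    union = c_lr | p_lr
    if not union:
        return 0.0
    return len(c_lr & p_lr) / len(union)


def normalize_pas(scores) -> np.ndarray:
    """z-normalization across pathways with population sigma."""
    s = np.asarray(list(scores), dtype=float)
    if s.size < 2:
        raise ValueError("z-normalization requires >= 2 pathways")
    sigma = s.std(ddof=0)
    if sigma == 0:
        raise ValueError("all pathway scores identical; sigma is 0")
    return (s - s.mean()) / sigma


def hypergeometric_p(q: int, t: int, n: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= q) of drawing q or more
    pathway pairs when t pairs are sampled from a universe of m containing n.

    q=0 returns exactly 1."""
    if not (0 <= q <= min(t, n) <= m):
        raise ValueError(f"infeasible (q={q}, t={t}, n={n}, m={m})")
    if q == 0:
        return 1.0
    # survival function is computed in log space internally by scipy
    return float(stats.hypergeom.sf(q - 1, m, n, t))


def enrich(
    results: pd.DataFrame,
    pathways: PathwayDatabase,
    scope: str = "per-pair",
    universe: int | None = None,
) -> pd.DataFrame:
    """Enrichment table of pathways over the altered pairs in ``results``.

    ``results`` is the communication output table (needs ``sender``,
    ``receiver``, ``pair_key``, ``altered``).  ``scope`` is ``per-pair``
    (one block per sender->receiver combination) or ``pooled``.  ``universe``
    overrides m, which defaults to the number of distinct pairs in the
    pathway database.
    """
    if scope not in ("per-pair", "pooled"):
        raise ValueError("scope must be 'per-pair' or 'pooled'")
    all_pairs = set().union(*pathways.values()) if pathways else set()
    m = universe if universe is not None else len(all_pairs)
    altered = results[results["altered"]]
    if altered.empty:
        warnings.warn("no altered pairs; empty enrichment table")
        return pd.DataFrame(columns=ENRICH_COLUMNS)

    if scope == "pooled":
        blocks = {"pooled": set(altered["pair_key"])}
    else:
        blocks = {
            f"{s}->{r}": set(g["pair_key"])
            for (s, r), g in altered.groupby(["sender", "receiver"], sort=True)
        }

    out_rows = []
    for label, c_lr in blocks.items():
        t = len(c_lr)
        rows = []
        for pw in sorted(pathways):
            p_lr = pathways[pw]
            q = len(c_lr & p_lr)
            n = len(p_lr)
            pas = pathway_activity_score(c_lr, p_lr)
            p = hypergeometric_p(q, t, n, m) if min(t, n) <= m else np.nan
            rows.append({
                "scope": label, "pathway_id": pw, "q": q, "t": t, "n": n, "m": m,
                "PAS": pas, "P": p,
            })
        block = pd.DataFrame(rows)
        if len(block) >= 2 and block["PAS"].std(ddof=0) > 0:
            block["nPAS"] = normalize_pas(block["PAS"])
        else:
            block["nPAS"] = np.nan
        block["adj_P"] = adjust_pvalues(block["P"])
        out_rows.append(block.sort_values(["P", "pathway_id"], kind="mergesort"))
    return (
        pd.concat(out_rows, ignore_index=True)[ENRICH_COLUMNS]
        if out_rows
        else pd.DataFrame(columns=ENRICH_COLUMNS)
    )
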