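"""Model/Results interface over the scoring pipeline.

``CommunicationModel`` bundles an annotated expression matrix with the
prior-knowledge tables and a :class:`~deltacomm.communication.PipelineConfig`;
``fit()`` runs the full pipeline and returns a
:class:`CommunicationResults` carrying the per-pair score table, the per-TF
GSEA detail, and convenience methods for enrichment, plotting and export.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .communication import PipelineConfig, run_communication
from .expression import AnnotatedMatrix, load_expression, normalize_log_scaled
from .knowledge_base import (
    LRTFAxis,
    PathwayDatabase,
    TFTGDatabase,
    load_lr_tf_axes,
    load_tf_tg,
    validate_databases,
)
from .pathway_enrichment import enrich as _enrich

__all__ = ["CommunicationModel", "CommunicationResults"]


class CommunicationModel:
    """Two-condition cell-cell communication scoring model.

    Parameters
    ----------
    matrix : AnnotatedMatrix
        Expression with per-cell ``cell_type`` and ``condition`` labels.
        Raw counts are normalized on construction unless already normalized.
    axes : list of LRTFAxis
        Ligand-receptor-TF prior.
    tftg : dict
        TF -> prior target-gene sets.
    config : PipelineConfig, optional
        Pipeline tunables; ``seed`` must be set before ``fit``.
    """

    def __init__(
        self,
        matrix: AnnotatedMatrix,
        axes: list[LRTFAxis],
        tftg: TFTGDatabase,
        config: PipelineConfig | None = None,
    ):
        self.config = config or PipelineConfig()
        if not matrix.normalized:
            matrix = normalize_log_scaled(matrix, scale=self.config.scale)
        self.matrix = matrix
        self.axes = axes
        self.tftg = tftg
        self.validation = validate_databases(axes, tftg, matrix=matrix)

    @classmethod
    def from_files(
        cls,
        matrix_path,
        genes_path,
        barcodes_path,
        meta_path,
        axes_path,
        tftg_path,
        config: PipelineConfig | None = None,
    ) -> "CommunicationModel":
        matrix = load_expression(matrix_path, genes_path, barcodes_path, meta_path)
        return cls(matrix, load_lr_tf_axes(axes_path), load_tf_tg(tftg_path), config)

    def fit(self, seed: int | None = None) -> "CommunicationResults":
        """Run the pipeline; ``seed`` overrides ``config.seed``."""
        if seed is not None:
            self.config.seed = seed
        results, detail = run_communication(self.matrix, self.axes, self.tftg, self.config)
        return CommunicationResults(self, results, detail)


class CommunicationResults:
    """Fitted communication scores.

    Attributes
    ----------
    scores : DataFrame
        One row per (sender, receiver, L-R pair): softmax weights, ||LR||_2,
        aggregated TF activity TF_k, unified score S_k, and the altered flag.
    detail : DataFrame
        Long-format per-TF rows with regulon size, ES, NES, p, adj_p.
    """

    def __init__(self, model: CommunicationModel, scores: pd.DataFrame, detail: pd.DataFrame):
        self.model = model
        self.scores = scores
        self.detail = detail

    @property
    def altered(self) -> pd.DataFrame:
        return self.scores[self.scores["altered"]]

    def summary(self, top: int = 10) -> str:
        """Plain-text summary table (statsmodels-flavored)."""
        cfg = self.model.config
        lines = [
            "Two-condition cell-cell communication".center(72),
            "=" * 72,
            f"deltacomm {__version__}    direction={cfg.direction}  alpha={cfg.alpha}"
            f"  gate={cfg.gate_on}  n_perm={cfg.n_perm}  seed={cfg.seed}",
            f"cells: {len(self.model.matrix.cells)}   genes: {len(self.model.matrix.genes)}"
            f"   cell types: {len(self.model.matrix.cell_types)}",
            f"candidate pairs: {len(self.scores)}   altered: {int(self.scores['altered'].sum())}",
            "-" * 72,
        ]
        if self.scores.empty:
            lines.append("(no candidate pairs)")
        else:
            cols = ["sender", "receiver", "pair_key", "l2_norm", "TF_k", "S_k"]
            head = self.scores.head(top)[cols].copy()
            for c in ("l2_norm", "TF_k", "S_k"):
                head[c] = head[c].map(lambda v: f"{v:.4f}")
            lines.append(head.to_string(index=False))
        lines.append("=" * 72)
        return "\n".join(lines)

    def enrich(
        self, pathways: PathwayDatabase, scope: str = "per-pair", universe: int | None = None
    ) -> pd.DataFrame:
        """Pathway enrichment of the altered pairs (see
        :mod:`deltacomm.pathway_enrichment`)."""
        return _enrich(self.scores, pathways, scope=scope, universe=universe)

    def heatmap_matrix(self) -> pd.DataFrame:
        """Senders x receivers matrix of summed S_k (the plotted quantity)."""
        cts = self.model.matrix.cell_types
        mat = pd.DataFrame(0.0, index=cts, columns=cts)
        for (s, r), g in self.scores.groupby(["sender", "receiver"]):
            mat.loc[s, r] = g["S_k"].sum()
        mat.index.name = "sender"
        mat.columns.name = "receiver"
        return mat

    def plot_heatmap(self, out_path=None):
        """Render the sender x receiver S_k heatmap with matplotlib."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mat = self.heatmap_matrix()
        if mat.empty:
            raise ValueError("no results to plot")
        fig, ax = plt.subplots(figsize=(1.2 + 0.6 * len(mat.columns), 1.2 + 0.6 * len(mat)))
        im = ax.imshow(mat.values, cmap="viridis")
        ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(mat.index)), mat.index)
        ax.set_xlabel("receiver")
        ax.set_ylabel("sender")
        fig.colorbar(im, ax=ax, label="sum of S_k")
        fig.tight_layout()
        if out_path is not None:
            fig.savefig(out_path, dpi=150)
            plt.close(fig)
            return Path(out_path)
        return fig

    def to_tsv(self, out_dir) -> dict[str, Path]:
        """Write the scores, per-TF detail, and heatmap matrix as TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "results": out / "results.tsv",
            "detail": out / "detail.tsv",
            "heatmap": out / "heatmap_matrix.tsv",
        }
        self.scores.to_csv(paths["results"], sep="\t", index=False, float_format="%.10g")
        self.detail.to_csv(paths["detail"], sep="\t", index=False, float_format="%.10g")
        self.heatmap_matrix().to_csv(paths["heatmap"], sep="\t", float_format="%.10g")
        return paths
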