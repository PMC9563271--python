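"""Seeded two-condition scRNA-seq fixtures with planted signaling cascades.

The generator emulates the causal story the scorer is built to detect:
a ligand expressed by sender cells, its receptor on receiver cells, a
downstream TF whose regulon (TF + targets) is genuinely coexpressed in
receiver cells through a shared per-cell latent activity factor, and a
disease-only mean shift of the targets in the receiver type.  Decoy axes
have expressed ligands/receptors and coexpressed regulons but no condition
shift, so that under the null the permutation machinery can be calibrated.

Background counts are iid negative binomial with multiplicative per-cell
size factors; dropout is simulated by independent zeroing.  This emulates
overdispersed UMI counts but none of the structured artifacts of real data
(batch effects, ambient RNA, UMI saturation); a green recovery test
establishes the pipeline's mechanics, not performance on real tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .expression import AnnotatedMatrix
from .knowledge_base import (
    LRTFAxis,
    PathwayDatabase,
    TFTGDatabase,
    pair_key,
    write_lr_tf_axes,
    write_pathways,
    write_tf_tg,
)

__all__ = ["PlantedAxis", "SimConfig", "GroundTruth", "simulate", "write_fixture"]


@dataclass
class PlantedAxis:
    sender: str
    receiver: str
    ligand: str
    receptor: str
    tf: str
    n_targets: int = 20
    target_log2_shift: float = 1.5
    expression_factor: float = 8.0  # ligand/receptor mean multiplier


@dataclass
class SimConfig:
    n_cell_types: int = 2
    cells_per_type_per_condition: int = 150
    n_background_genes: int = 200
    planted_axes: list[PlantedAxis] = field(default_factory=list)
    n_decoy_axes: int = 20
    decoy_targets_per_tf: int = 20
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0      # NB size parameter; smaller = noisier
    dropout_rate: float = 0.2
    latent_sigma: float = 0.8       # lognormal sd of the shared TF activity factor
    expression_factor: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_cell_types < 1 or self.cells_per_type_per_condition < 3:
            raise ValueError("need >= 1 cell type and >= 3 cells per group")
        for ax in self.planted_axes:
            if not np.isfinite(ax.target_log2_shift):
                raise ValueError("target_log2_shift must be finite")


@dataclass
class GroundTruth:
    planted: list[dict]
    decoys: list[str]  # decoy pair keys
    config: dict

    def to_json(self) -> str:
        return json.dumps(
            {"planted": self.planted, "decoys": self.decoys, "config": self.config},
            indent=2,
        )


def default_planted_axis(**kw) -> PlantedAxis:
    """The standard single planted cascade between the first two cell types."""
    base = dict(
        sender="CT1", receiver="CT2", ligand="LIGP01", receptor="RECP01",
        tf="TFP01", n_targets=20, target_log2_shift=1.5,
    )
    base.update(kw)
    return PlantedAxis(**base)


def _nb_counts(rng, mean, size, dispersion):
    """Negative binomial draws parameterized by mean and size (dispersion)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    r = dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p, size=size).astype(np.float64)


def simulate(config: SimConfig):
    """Generate (raw AnnotatedMatrix, axes, tftg, pathways, GroundTruth).

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cell_types = [f"CT{i+1}" for i in range(config.n_cell_types)]
    conditions = ["control", "disease"]

    # --- gene roster -----------------------------------------------------
    genes: list[str] = [f"BG{i:04d}" for i in range(1, config.n_background_genes + 1)]
    used = set(genes)

    def register(*names):
        for g in names:
            if g in used:
                raise ValueError(f"planted gene collision: {g}")
            used.add(g)
            genes.append(g)

    axes: list[LRTFAxis] = []
    tftg: TFTGDatabase = {}
    pathways: PathwayDatabase = {}
    planted_records: list[dict] = []
    decoy_keys: list[str] = []
    # (gene, list-of-targets) bookkeeping for expression effects
    effects = []  # dicts describing per-gene expression modifiers

    tg_counter = 1
    for idx, ax in enumerate(config.planted_axes, start=1):
        targets = [f"TGP{j:04d}" for j in range(tg_counter, tg_counter + ax.n_targets)]
        tg_counter += ax.n_targets
        register(ax.ligand, ax.receptor, ax.tf, *targets)
        axis = LRTFAxis((ax.ligand,), (ax.receptor,), ax.tf, 1, frozenset({f"PWP{idx:02d}"}))
        axes.append(axis)
        tftg[ax.tf] = set(targets)
        pathways.setdefault(f"PWP{idx:02d}", set()).add(axis.pair_key)
        planted_records.append({
            "sender": ax.sender, "receiver": ax.receiver,
            "pair_key": axis.pair_key, "tf": ax.tf,
            "target_log2_shift": ax.target_log2_shift,
        })
        effects.append({
            "kind": "planted", "axis": ax, "targets": targets,
        })

    dg_counter = 1
    for idx in range(1, config.n_decoy_axes + 1):
        lig, rec, tf = f"LIGD{idx:03d}", f"RECD{idx:03d}", f"TFD{idx:03d}"
        targets = [f"TGD{j:04d}" for j in range(dg_counter, dg_counter + config.decoy_targets_per_tf)]
        dg_counter += config.decoy_targets_per_tf
        register(lig, rec, tf, *targets)
        axis = LRTFAxis((lig,), (rec,), tf, 1, frozenset({f"PWD{1 + (idx - 1) // 5:02d}"}))
        axes.append(axis)
        tftg[tf] = set(targets)
        pathways.setdefault(f"PWD{1 + (idx - 1) // 5:02d}", set()).add(axis.pair_key)
        decoy_keys.append(axis.pair_key)
        effects.append({"kind": "decoy", "ligand": lig, "receptor": rec,
                        "tf": tf, "targets": targets})

    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # --- cells -----------------------------------------------------------
    obs_rows = []
    for ct in cell_types:
        for cond in conditions:
            for j in range(config.cells_per_type_per_condition):
                obs_rows.append((f"{ct}_{cond}_{j:04d}", ct, cond))
    obs = pd.DataFrame(obs_rows, columns=["barcode", "cell_type", "condition"]).set_index("barcode")
    n_cells = len(obs)
    ct_arr = obs["cell_type"].to_numpy()
    cond_arr = obs["condition"].to_numpy()

    # --- per-cell per-gene NB means -------------------------------------
    base = rng.uniform(0.5, 1.5, size=n_genes) * config.nb_mean  # per-gene baseline
    size_factors = np.exp(rng.normal(0, 0.25, size=n_cells))
    mu = np.outer(size_factors, base)  # cells x genes

    for eff in effects:
        if eff["kind"] == "planted":
            ax: PlantedAxis = eff["axis"]
            send_mask = ct_arr == ax.sender
            recv_mask = ct_arr == ax.receiver
            mu[send_mask, gene_idx[ax.ligand]] *= ax.expression_factor
            mu[recv_mask, gene_idx[ax.receptor]] *= ax.expression_factor
            # shared latent activity induces TF-target coexpression in receivers
            latent = np.exp(rng.normal(0, config.latent_sigma, size=int(recv_mask.sum())))
            cols = [gene_idx[ax.tf]] + [gene_idx[t] for t in eff["targets"]]
            mu[np.ix_(recv_mask, cols)] *= latent[:, None]
            shift_mask = recv_mask & (cond_arr == "disease")
            tcols = [gene_idx[t] for t in eff["targets"]]
            mu[np.ix_(shift_mask, tcols)] *= 2.0 ** ax.target_log2_shift
        else:
            # decoys: expressed everywhere, coexpressed regulon, no shift
            mu[:, gene_idx[eff["ligand"]]] *= config.expression_factor
            mu[:, gene_idx[eff["receptor"]]] *= config.expression_factor
            latent = np.exp(rng.normal(0, config.latent_sigma, size=n_cells))
            cols = [gene_idx[eff["tf"]]] + [gene_idx[t] for t in eff["targets"]]
            mu[:, cols] *= latent[:, None]

    counts = _nb_counts(rng, mu, (n_cells, n_genes), config.nb_dispersion)
    if config.dropout_rate > 0:
        keep = rng.random((n_cells, n_genes)) >= config.dropout_rate
        counts *= keep

    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["normalized"] = False
    matrix = AnnotatedMatrix(adata)
    truth = GroundTruth(
        planted=planted_records,
        decoys=decoy_keys,
        config={**{k: v for k, v in asdict(config).items() if k != "planted_axes"},
                "planted_axes": [asdict(a) for a in config.planted_axes]},
    )
    return matrix, axes, tftg, pathways, truth


def write_fixture(bundle, out_dir, force: bool = False) -> dict[str, Path]:
    """Write a simulated bundle as MTX + TSV side files + databases + truth.json.

    ``bundle`` is the 5-tuple returned by :func:`simulate`.
    """
    matrix, axes, tftg, pathways, truth = bundle
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "barcodes": out / "barcodes.tsv",
        "meta": out / "meta.tsv",
        "axes": out / "axes.tsv",
        "tftg": out / "tftg.tsv",
        "pathways": out / "pathways.tsv",
        "truth": out / "truth.json",
    }
    X = matrix.adata.X
    X = X.T.tocoo() if sp.issparse(X) else sp.coo_matrix(np.asarray(X).T)  # genes x cells
    scipy.io.mmwrite(str(paths["matrix"]), X)
    pd.Series(matrix.genes).to_csv(paths["genes"], sep="\t", index=False, header=False)
    pd.Series(matrix.cells).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    meta = matrix.cell_meta.reset_index(names="barcode")[["barcode", "cell_type", "condition"]]
    meta.to_csv(paths["meta"], sep="\t", index=False)
    write_lr_tf_axes(axes, paths["axes"])
    write_tf_tg(tftg, paths["tftg"])
    write_pathways(pathways, paths["pathways"])
    paths["truth"].write_text(truth.to_json())
    return paths
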