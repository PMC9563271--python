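"""Prior-knowledge tables: ligand-receptor-TF axes, TF->target interactions,
and pathway membership of L-R pairs.

All three tables are plain TSV files so that databases assembled elsewhere
(KEGG-, Reactome- or literature-derived) can be dropped in.  Complexes are
encoded inline as comma-separated subunit lists; the canonical key for an
L-R pair joins the sorted subunits of each side with ``+`` and the two sides
with an arrow, e.g. ``IFNG->IFNGR1+IFNGR2``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "LRTFAxis",
    "TFTGDatabase",
    "PathwayDatabase",
    "ValidationReport",
    "pair_key",
    "load_lr_tf_axes",
    "load_tf_tg",
    "load_pathways",
    "write_lr_tf_axes",
    "write_tf_tg",
    "write_pathways",
    "validate_databases",
    "build_toy_database",
]

PAIR_ARROW = "->"


class SchemaError(ValueError):
    """A required column is missing or a row violates the schema."""


def _subunits(token: str) -> tuple[str, ...]:
    parts = tuple(s.strip() for s in str(token).split(",") if s.strip())
    if not parts:
        raise SchemaError(f"empty subunit list: {token!r}")
    return parts


def pair_key(ligand_subunits, receptor_subunits) -> str:
    """Canonical identifier of an L-R pair: subunits sorted within each
    complex, joined by '+', sides joined by '->'."""
    lig = "+".join(sorted(ligand_subunits))
    rec = "+".join(sorted(receptor_subunits))
    return f"{lig}{PAIR_ARROW}{rec}"


@dataclass(frozen=True)
class LRTFAxis:
    """One ligand (>=1 subunits), one receptor (>=1 subunits), one downstream
    transcription factor, with the shortest receptor->TF step count ``distance``
    and the pathways the axis was extracted from."""

    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    tf: str
    distance: int
    pathway_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.ligand_subunits or not self.receptor_subunits:
            raise SchemaError("subunit lists must be non-empty")
        if not isinstance(self.distance, int) or self.distance < 1:
            raise SchemaError(f"distance must be an integer >= 1, got {self.distance!r}")

    @property
    def pair_key(self) -> str:
        return pair_key(self.ligand_subunits, self.receptor_subunits)

    @property
    def triple(self) -> tuple[str, str, str]:
        return (
            ",".join(self.ligand_subunits),
            ",".join(self.receptor_subunits),
            self.tf,
        )

    @property
    def genes(self) -> set[str]:
        return set(self.ligand_subunits) | set(self.receptor_subunits) | {self.tf}


# TF -> set of prior target genes.  A TF may target itself.
TFTGDatabase = dict[str, set[str]]

# pathway_id -> set of canonical pair keys.
PathwayDatabase = dict[str, set[str]]


@dataclass
class ValidationReport:
    """Cross-reference check over the three loaded databases (and optionally
    an expression matrix).  Report-only: soft failures never raise."""

    n_axes: int
    n_tfs: int
    n_targets: int
    n_pathways: int
    axes_tf_missing: list[str] = field(default_factory=list)
    pathway_pairs_unmatched: list[tuple[str, str]] = field(default_factory=list)
    matrix_overlap: dict[str, float] = field(default_factory=dict)

    @property
    def is_valid(self) -> bool:
        return not self.axes_tf_missing and not self.pathway_pairs_unmatched


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def load_lr_tf_axes(path) -> list[LRTFAxis]:
    """Load the axes TSV (columns: ligand, receptor, tf, distance, pathways).

    Duplicate (ligand, receptor, tf) triples are merged: minimum distance,
    union of pathway ids.
    """
    df = _read_tsv(path, ["ligand", "receptor", "tf", "distance", "pathways"])
    merged: dict[tuple, dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            dist = int(str(row.distance))
        except (TypeError, ValueError):
            raise SchemaError(f"{path}: line {i}: non-integer distance {row.distance!r}") from None
        if dist < 1:
            raise SchemaError(f"{path}: line {i}: distance must be >= 1, got {dist}")
        lig = _subunits(row.ligand)
        rec = _subunits(row.receptor)
        tf = str(row.tf).strip()
        pw = frozenset(
            p.strip() for p in str(row.pathways).split(";")
            if p.strip() and str(row.pathways) != "nan"
        )
        key = (lig, rec, tf)
        if key in merged:
            merged[key]["distance"] = min(merged[key]["distance"], dist)
            merged[key]["pathways"] |= pw
        else:
            merged[key] = {"distance": dist, "pathways": set(pw)}
    return [
        LRTFAxis(lig, rec, tf, d["distance"], frozenset(d["pathways"]))
        for (lig, rec, tf), d in merged.items()
    ]


def load_tf_tg(path) -> TFTGDatabase:
    """Load the TF->target TSV (columns: tf, target); duplicates collapse."""
    df = _read_tsv(path, ["tf", "target"])
    if df.empty:
        raise SchemaError(f"{path}: no TF-target rows")
    db: TFTGDatabase = {}
    for row in df.itertuples(index=False):
        db.setdefault(str(row.tf).strip(), set()).add(str(row.target).strip())
    return db


def load_pathways(path) -> PathwayDatabase:
    """Load the pathway membership TSV (columns: pathway_id, ligand, receptor)."""
    df = _read_tsv(path, ["pathway_id", "ligand", "receptor"])
    if df.empty:
        raise SchemaError(f"{path}: no pathway rows")
    db: PathwayDatabase = {}
    for row in df.itertuples(index=False):
        key = pair_key(_subunits(row.ligand), _subunits(row.receptor))
        db.setdefault(str(row.pathway_id).strip(), set()).add(key)
    return db


def write_lr_tf_axes(axes: list[LRTFAxis], path) -> None:
    rows = [
        {
            "ligand": ",".join(a.ligand_subunits),
            "receptor": ",".join(a.receptor_subunits),
            "tf": a.tf,
            "distance": a.distance,
            "pathways": ";".join(sorted(a.pathway_ids)),
        }
        for a in sorted(axes, key=lambda a: a.triple)
    ]
    pd.DataFrame(rows, columns=["ligand", "receptor", "tf", "distance", "pathways"]).to_csv(
        path, sep="\t", index=False
    )


def write_tf_tg(tftg: TFTGDatabase, path) -> None:
    rows = [
        {"tf": tf, "target": tg}
        for tf in sorted(tftg)
        for tg in sorted(tftg[tf])
    ]
    pd.DataFrame(rows, columns=["tf", "target"]).to_csv(path, sep="\t", index=False)


def write_pathways(pathways: PathwayDatabase, path) -> None:
    rows = []
    for pw in sorted(pathways):
        for key in sorted(pathways[pw]):
            lig, rec = key.split(PAIR_ARROW)
            rows.append({"pathway_id": pw, "ligand": lig.replace("+", ","),
                         "receptor": rec.replace("+", ",")})
    pd.DataFrame(rows, columns=["pathway_id", "ligand", "receptor"]).to_csv(
        path, sep="\t", index=False
    )


def validate_databases(
    axes: list[LRTFAxis],
    tftg: TFTGDatabase,
    pathways: PathwayDatabase | None = None,
    matrix=None,
) -> ValidationReport:
    """Cross-reference the three databases; report-only.

    With ``matrix`` given (an AnnotatedMatrix), also reports what fraction of
    database genes are present in the expression matrix.
    """
    pathways = pathways or {}
    report = ValidationReport(
        n_axes=len(axes),
        n_tfs=len(tftg),
        n_targets=sum(len(v) for v in tftg.values()),
        n_pathways=len(pathways),
    )
    for a in axes:
        if a.tf not in tftg:
            report.axes_tf_missing.append(a.tf)
    axis_keys = {a.pair_key for a in axes}
    for pw, keys in pathways.items():
        for key in keys:
            if key not in axis_keys:
                report.pathway_pairs_unmatched.append((pw, key))
    if matrix is not None:
        genes = set(matrix.genes)
        db_genes = set()
        for a in axes:
            db_genes |= a.genes
        tg_genes = set().union(*tftg.values()) if tftg else set()
        report.matrix_overlap = {
            "axis_genes_in_matrix": _frac(db_genes & genes, db_genes),
            "target_genes_in_matrix": _frac(tg_genes & genes, tg_genes),
        }
    return report


def _frac(part, whole) -> float:
    return len(part) / len(whole) if whole else 1.0


def build_toy_database(
    n_axes: int,
    n_targets_per_tf: int,
    seed: int,
    complex_fraction: float = 0.2,
    axes_per_pathway: int = 5,
) -> tuple[list[LRTFAxis], TFTGDatabase, PathwayDatabase]:
    """Small deterministic synthetic database for tests and demos.

    Gene symbols are synthetic (LIG001, REC001, TF001, TG0001, ...); every
    axis TF has ``n_targets_per_tf`` prior targets, and one pathway is
    created per ~``axes_per_pathway`` axes.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    rng = random.Random(seed)
    axes: list[LRTFAxis] = []
    tftg: TFTGDatabase = {}
    pathways: PathwayDatabase = {}
    tg_counter = 1
    for i in range(1, n_axes + 1):
        lig = (f"LIG{i:03d}",)
        rec = (f"REC{i:03d}",)
        if rng.random() < complex_fraction:
            rec = (f"REC{i:03d}A", f"REC{i:03d}B")
        tf = f"TF{i:03d}"
        dist = rng.randint(1, 4)
        pw = f"PW{1 + (i - 1) // axes_per_pathway:03d}"
        axes.append(LRTFAxis(lig, rec, tf, dist, frozenset({pw})))
        tftg[tf] = {f"TG{j:04d}" for j in range(tg_counter, tg_counter + n_targets_per_tf)}
        tg_counter += n_targets_per_tf
        pathways.setdefault(pw, set()).add(pair_key(lig, rec))
    return axes, tftg, pathways
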