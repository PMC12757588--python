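"""Readers and writers for the external formats the tool touches.

Matrices come in as MatrixMarket (.mtx) with companion row/column name
files, or dense CSV/TSV with a header row of cell ids and a first column
of gene ids.  Gene annotations come in as BED6 or GTF; internally all
coordinates are 0-based half-open (BED passes through, GTF gene starts
are decremented).  Networks are exchanged as edge-list TSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import yaml

from .containers import (
    CellMatrix,
    CellOrdering,
    FormatError,
    GeneAnnotation,
    RunConfig,
    ValidationError,
)

log = logging.getLogger("popinfer")

EDGE_COLUMNS = ["regulator", "target", "weight", "sign"]


def _read_names(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise FormatError(f"cannot infer matrix format from {path!r}")


def read_cell_matrix(
    path: str | Path,
    format: Optional[str] = None,
    modality: str = "expression",
    genes_path: Optional[str | Path] = None,
    cells_path: Optional[str | Path] = None,
) -> CellMatrix:
    """Read a genes x cells matrix.

    For ``mtx`` the companion ``genes_path`` / ``cells_path`` plain-text
    name files are required (one identifier per line, in matrix order).
    For ``csv``/``tsv`` the header row holds cell ids and the first
    column holds gene ids.
    """
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        if genes_path is None or cells_path is None:
            raise FormatError("mtx input requires genes_path and cells_path")
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:  # scipy raises bare ValueError on bad files
            raise FormatError(f"could not parse MatrixMarket file {path}: {exc}") from exc
        genes = _read_names(genes_path)
        cells = _read_names(cells_path)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix is {mat.shape} but name files give "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        values = mat.tocsr() if modality == "peaks" else np.asarray(mat.todense(), dtype=float)
        return CellMatrix(values, genes, cells, modality)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return CellMatrix(
            df.to_numpy(dtype=float),
            [str(g) for g in df.index],
            [str(c) for c in df.columns],
            modality,
        )
    raise FormatError(f"unknown matrix format {fmt!r}")


def write_cell_matrix(matrix: CellMatrix, path: str | Path, format: str = "tsv") -> None:
    if format not in ("csv", "tsv"):
        raise FormatError(f"unsupported output format {format!r}")
    sep = "," if format == "csv" else "\t"
    df = pd.DataFrame(matrix.to_dense(), index=matrix.gene_ids, columns=matrix.cell_ids)
    df.to_csv(path, sep=sep)


# -- edge lists ------------------------------------------------------------

def validate_edge_list(edges: pd.DataFrame) -> pd.DataFrame:
    """Check the edge-list invariants and normalize dtypes."""
    missing = [c for c in ("regulator", "target") if c not in edges.columns]
    if missing:
        raise FormatError(f"edge list missing columns {missing}")
    edges = edges.copy()
    edges["regulator"] = edges["regulator"].astype(str).str.strip()
    edges["target"] = edges["target"].astype(str).str.strip()
    if "weight" not in edges.columns:
        edges["weight"] = 1.0
    if "sign" not in edges.columns:
        edges["sign"] = np.sign(edges["weight"]).astype(int)
    edges["weight"] = edges["weight"].astype(float)
    edges["sign"] = edges["sign"].astype(int)
    if not edges["sign"].isin([-1, 0, 1]).all():
        raise ValidationError("edge signs must be -1, 0 or +1")
    if (edges["regulator"] == edges["target"]).any():
        raise ValidationError("self-edges are not allowed")
    if edges.duplicated(subset=["regulator", "target"]).any():
        raise ValidationError("duplicate (regulator, target) pairs")
    return edges[EDGE_COLUMNS].reset_index(drop=True)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_edge_list(df)


def read_reference_edges(path: str | Path) -> pd.DataFrame:
    """Read a 2+-column reference network TSV (regulator, target, ...)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("reference network needs >= 2 columns")
    df = df.iloc[:, :2]
    df.columns = ["regulator", "target"]
    return validate_edge_list(df)


def write_edge_list(edges, path: str | Path) -> None:
    """Write a network as TSV with columns regulator/target/weight/sign.

    Accepts an edge-list DataFrame or any object with a ``to_edge_list()``
    method (e.g. a fitted signed network).
    """
    if hasattr(edges, "to_edge_list"):
        edges = edges.to_edge_list()
    edges = validate_edge_list(pd.DataFrame(edges))
    edges.to_csv(path, sep="\t", index=False, float_format="%.12g")


# -- per-cell metadata -----------------------------------------------------

def read_pseudotime(path: str | Path) -> pd.Series:
    """Read a 2-column TSV (cell_id, pseudotime) into a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("pseudotime file needs columns cell_id, pseudotime")
    s = pd.Series(df.iloc[:, 1].astype(float).values,
                  index=df.iloc[:, 0].astype(str).str.strip())
    if s.index.duplicated().any():
        raise ValidationError("duplicate cell ids in pseudotime file")
    return s


def read_cluster_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("cluster file needs columns cell_id, cluster")
    s = pd.Series(df.iloc[:, 1].astype(str).values,
                  index=df.iloc[:, 0].astype(str).str.strip())
    if s.index.duplicated().any():
        raise ValidationError("duplicate cell ids in cluster file")
    return s


def make_ordering(
    matrix: CellMatrix,
    pseudotime: pd.Series,
    clusters: Optional[pd.Series] = None,
) -> CellOrdering:
    """Align per-cell pseudotime (and clusters) with a matrix's cells."""
    missing = [c for c in matrix.cell_ids if c not in pseudotime.index]
    if missing:
        raise ValidationError(f"cells missing pseudotime: {missing[:5]}")
    cells = matrix.cell_ids
    labels = None
    if clusters is not None:
        missing = [c for c in cells if c not in clusters.index]
        if missing:
            raise ValidationError(f"cells missing cluster label: {missing[:5]}")
        labels = [clusters[c] for c in cells]
    return CellOrdering.from_pseudotime(cells, [pseudotime[c] for c in cells], labels)


# -- gene annotations ------------------------------------------------------

def read_annotations(path: str | Path, format: Optional[str] = None) -> list[GeneAnnotation]:
    """Read gene annotations from BED6 or GTF.

    BED is 0-based half-open and passes through; GTF is 1-based closed,
    so starts are decremented.  Only GTF ``gene`` features are kept; a
    gene represented only by exon/transcript lines is skipped with a
    warning.
    """
    fmt = format or ("bed" if Path(path).suffix.lower() == ".bed" else "gtf")
    if fmt == "bed":
        return _read_bed(path)
    if fmt == "gtf":
        return _read_gtf(path)
    raise FormatError(f"unknown annotation format {fmt!r}")


def _read_bed(path: str | Path) -> list[GeneAnnotation]:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{ln}: BED6 needs 6 fields, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            records.append(GeneAnnotation(name.strip(), chrom, int(start), int(end), strand))
    return records


def _read_gtf(path: str | Path) -> list[GeneAnnotation]:
    import gffutils

    records: dict[str, GeneAnnotation] = {}
    seen_non_gene: set[str] = set()
    for feature in gffutils.DataIterator(str(path)):
        gene_id = (feature.attributes.get("gene_id") or [feature.id or ""])[0]
        if feature.featuretype != "gene":
            if gene_id:
                seen_non_gene.add(gene_id)
            continue
        if feature.strand not in ("+", "-"):
            raise ValidationError(f"gene {gene_id}: unknown strand {feature.strand!r}")
        # GTF is 1-based closed; 0-based half-open = (start-1, end)
        records[gene_id] = GeneAnnotation(
            gene_id, feature.seqid, feature.start - 1, feature.end, feature.strand
        )
    for gene_id in seen_non_gene - set(records):
        log.warning("gene %s has no 'gene' feature in GTF; skipped", gene_id)
    return list(records.values())


# -- run configuration -----------------------------------------------------

def load_config(path: Optional[str | Path] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Precedence: dataclass defaults < YAML values < explicit overrides.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise FormatError("config YAML must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(values) - valid
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)
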