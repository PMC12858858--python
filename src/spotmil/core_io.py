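"""Domain containers and file readers/writers.

All geometry lives in a single internal frame: full-resolution pixel
coordinates, origin at the top-left corner, ``x`` along columns and ``y``
along rows.  Positions tables written in the Space Ranger convention
(``pxl_row``/``pxl_col``) are converted on read.

Matrices on disk follow the MatrixMarket + TSV-sidecar bundle used by
Space Ranger; on disk the matrix may be stored either genes x spots or
spots x genes — orientation is inferred from the sidecar lengths and
normalised to spots-in-rows internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class FormatError(ValueError):
    """Raised when an on-disk artefact is structurally inconsistent."""


class AlignmentError(ValueError):
    """Raised when two containers that must share identifiers disagree."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SpotCounts:
    """Spot-by-gene raw transcript counts plus spot geometry.

    ``counts`` is a dense ``S x G`` array of non-negative integers,
    ``spot_xy`` the spot centres in pixels and ``spot_radius`` the capture
    radius in the same units.  The physical radius depends on the scan
    resolution, so it is a required input rather than a constant.
    """

    counts: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    slide_id: str
    spot_xy: np.ndarray
    spot_radius: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.spot_xy = np.asarray(self.spot_xy, dtype=float)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D spot x gene matrix")
        s, g = self.counts.shape
        if len(self.spot_ids) != s or len(self.gene_ids) != g:
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.spot_ids)} spot ids / {len(self.gene_ids)} gene ids"
            )
        if self.spot_xy.shape != (s, 2):
            raise FormatError("spot_xy must be S x 2")
        if len(set(self.spot_ids)) != s:
            raise FormatError("spot_ids must be unique")
        if len(set(self.gene_ids)) != g:
            raise FormatError("gene_ids must be unique")
        if self.spot_radius <= 0:
            raise ValueError("spot_radius must be positive")
        arr = np.asarray(self.counts)
        if arr.size and (np.any(arr < 0) or not np.allclose(arr, np.round(arr))):
            raise FormatError("counts must be non-negative integers")
        self.counts = np.round(arr).astype(np.int64)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class CellTable:
    """Detected cells: identifiers, centroids and optional broad-type labels.

    Labels, when present, mirror the broad nucleus classes retained from the
    upstream detector (e.g. neoplastic / connective / inflammatory).
    ``crop_ref`` is an opaque pointer to an image crop and is never decoded.
    """

    cell_ids: np.ndarray
    slide_id: str
    cell_xy: np.ndarray
    label: np.ndarray | None = None
    crop_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.cell_xy = np.asarray(self.cell_xy, dtype=float)
        n = len(self.cell_ids)
        if len(set(self.cell_ids)) != n:
            dupes = pd.Series(self.cell_ids).value_counts()
            dupes = list(dupes[dupes > 1].index[:5])
            raise FormatError(f"duplicate cell ids: {dupes}")
        if self.cell_xy.shape != (n, 2):
            raise FormatError("cell_xy must be N x 2")
        if not np.all(np.isfinite(self.cell_xy)):
            bad = int(np.where(~np.isfinite(self.cell_xy).all(axis=1))[0][0])
            raise FormatError(f"non-finite coordinates at row {bad}")
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=object)
            if len(self.label) != n:
                raise FormatError("label length mismatch")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class EmbeddingMatrix:
    """Cell-by-dimension embedding matrix, aligned to a :class:`CellTable`.

    Rows are the vectors ``h = f_phi(x)`` produced by whatever encoder was
    used (an external self-supervised network, a one-hot label encoding, or
    the synthetic cluster encoder); ``encoder_tag`` records provenance.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    encoder_tag: str = "external"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise FormatError("embedding values must be 2-D")
        if self.values.shape[0] != len(self.cell_ids):
            raise FormatError(
                f"{self.values.shape[0]} embedding rows vs "
                f"{len(self.cell_ids)} cell ids"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise FormatError("embedding contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class BagAssignment:
    """Mapping from spot index to the ordered member-cell indices (the bag).

    A cell belongs to at most one spot; ``k_s`` is the bag cardinality per
    spot.  Spots absent from ``spot_to_cells`` have no assigned cells.
    """

    spot_to_cells: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        clean: dict[int, np.ndarray] = {}
        for s, cells in self.spot_to_cells.items():
            arr = np.asarray(cells, dtype=np.int64)
            for c in arr:
                if int(c) in seen:
                    raise AlignmentError(
                        f"cell index {int(c)} assigned to more than one spot"
                    )
                seen.add(int(c))
            clean[int(s)] = arr
        self.spot_to_cells = clean

    @property
    def k_s(self) -> dict[int, int]:
        return {s: len(c) for s, c in self.spot_to_cells.items()}

    @property
    def n_assigned(self) -> int:
        return sum(len(c) for c in self.spot_to_cells.values())

    def spots(self) -> list[int]:
        return sorted(self.spot_to_cells)


@dataclass
class CellPrediction:
    """Per-cell predicted gene scores (non-negative by the softplus contract)."""

    scores: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.scores.ndim != 2:
            raise FormatError("scores must be 2-D")
        if self.scores.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError("scores shape does not match id sidecars")
        if self.scores.size and self.scores.min() < 0:
            raise ValueError("predicted scores must be non-negative")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = [
    "barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col",
]


def _read_positions(path: str | Path) -> pd.DataFrame:
    """Read a Space-Ranger-style tissue positions table.

    Both circulating dialects are accepted: with a header line (any column
    names containing ``barcode`` / ``in_tissue`` / ``pxl_row*`` / ``pxl_col*``)
    or headerless with the canonical six columns.
    """
    first = pd.read_csv(path, nrows=1, header=None)
    has_header = isinstance(first.iloc[0, 0], str) and "barcode" in str(
        first.iloc[0, 0]
    ).lower().replace('"', "")
    if has_header:
        df = pd.read_csv(path)
        rename = {}
        for col in df.columns:
            low = col.lower()
            if "barcode" in low:
                rename[col] = "barcode"
            elif low == "in_tissue":
                rename[col] = "in_tissue"
            elif low.startswith("pxl_row"):
                rename[col] = "pxl_row"
            elif low.startswith("pxl_col"):
                rename[col] = "pxl_col"
            elif low == "array_row":
                rename[col] = "array_row"
            elif low == "array_col":
                rename[col] = "array_col"
        df = df.rename(columns=rename)
    else:
        df = pd.read_csv(path, header=None)
        if df.shape[1] != 6:
            raise FormatError(
                f"headerless positions table must have 6 columns, got {df.shape[1]}"
            )
        df.columns = _POSITION_COLUMNS
    missing = {"barcode", "in_tissue", "pxl_row", "pxl_col"} - set(df.columns)
    if missing:
        raise FormatError(f"positions table lacks columns: {sorted(missing)}")
    return df


def _read_id_column(path: str | Path) -> np.ndarray:
    if Path(path).stat().st_size == 0:
        return np.array([], dtype=object)
    df = pd.read_csv(path, sep="\t", header=None)
    return df.iloc[:, 0].astype(str).to_numpy(dtype=object)


def read_counts(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    positions_path: str | Path,
    *,
    slide_id: str = "slide",
    spot_radius: float,
) -> SpotCounts:
    """Read a MatrixMarket counts bundle restricted to in-tissue spots.

    Orientation on disk (genes x spots vs spots x genes) is inferred from the
    barcode/feature sidecar lengths; ambiguous square matrices default to the
    genes-in-rows convention.  Barcodes missing from the positions table are
    dropped with a warning naming them.
    """
    mat = spio.mmread(str(matrix_path))
    mat = sparse.coo_matrix(mat)
    barcodes = _read_id_column(barcodes_path)
    features = _read_id_column(features_path)
    nb, nf = len(barcodes), len(features)
    r, c = mat.shape
    if (r, c) == (nf, nb):
        counts = mat.T.toarray()
    elif (r, c) == (nb, nf):
        counts = mat.toarray()
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {nf} features x {nb} "
            f"barcodes nor its transpose"
        )
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise FormatError("count matrix must hold non-negative integers")

    pos = _read_positions(positions_path).set_index("barcode")
    known = np.array([b in pos.index for b in barcodes])
    if not known.all():
        lost = [b for b, k in zip(barcodes, known) if not k]
        warnings.warn(
            f"{len(lost)} barcode(s) missing from positions table, dropped: "
            f"{lost[:10]}",
            stacklevel=2,
        )
    keep_idx = [
        i
        for i in range(nb)
        if known[i] and int(pos.loc[barcodes[i], "in_tissue"]) == 1
    ]
    xy = np.array(
        [
            [float(pos.loc[barcodes[i], "pxl_col"]), float(pos.loc[barcodes[i], "pxl_row"])]
            for i in keep_idx
        ]
    ).reshape(len(keep_idx), 2)
    return SpotCounts(
        counts=counts[keep_idx],
        spot_ids=barcodes[keep_idx],
        gene_ids=features,
        slide_id=slide_id,
        spot_xy=xy,
        spot_radius=spot_radius,
    )


def read_cell_table(path: str | Path, *, slide_id: str = "slide") -> CellTable:
    """Read a delimited cell table with at least ``id``, ``x``, ``y`` columns."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    for need in ("id", "x", "y"):
        if need not in cols:
            raise FormatError(f"cell table lacks required column '{need}'")
    for axis in ("x", "y"):
        vals = pd.to_numeric(df[cols[axis]], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise FormatError(f"non-numeric {axis} coordinate at row {row}")
        df[cols[axis]] = vals
    label = None
    if "label" in cols:
        label = df[cols["label"]].astype(str).to_numpy(dtype=object)
    crop = None
    if "crop_ref" in cols:
        crop = df[cols["crop_ref"]].to_numpy(dtype=object)
    return CellTable(
        cell_ids=df[cols["id"]].astype(str).to_numpy(dtype=object),
        slide_id=slide_id,
        cell_xy=df[[cols["x"], cols["y"]]].to_numpy(dtype=float),
        label=label,
        crop_ref=crop,
    )


def read_embeddings(path: str | Path, *, encoder_tag: str = "external_file") -> EmbeddingMatrix:
    """Read an embedding matrix: ``.npy`` dense array or TSV with cell_id first."""
    p = Path(path)
    if p.suffix == ".npy":
        values = np.load(p)
        ids = np.array([str(i) for i in range(values.shape[0])], dtype=object)
    else:
        df = pd.read_csv(p, sep="\t", header=None)
        ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    return EmbeddingMatrix(values=values, cell_ids=ids, encoder_tag=encoder_tag)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line, blank lines ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line)
    return out


def read_marker_sets(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (cell_type, gene_id) -> {cell_type: [gene ids]}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_type", "gene_id"])
    out: dict[str, list[str]] = {}
    for ct, sub in df.groupby("cell_type", sort=False):
        out[str(ct)] = [str(g) for g in sub["gene_id"]]
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _write_ids(ids: Sequence, path: Path) -> None:
    pd.DataFrame({"id": list(ids)}).to_csv(path, sep="\t", header=False, index=False)


def write_prediction(pred: CellPrediction, path: str | Path) -> None:
    """Write predicted scores as an MTX + TSV bundle under directory ``path``.

    Emits ``scores.mtx`` (cells in rows), ``cells.tsv`` and ``genes.tsv``.
    Reading the bundle back reproduces the matrix to serialisation precision.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "scores.mtx"), sparse.csr_matrix(pred.scores))
    _write_ids(pred.cell_ids, out / "cells.tsv")
    _write_ids(pred.gene_ids, out / "genes.tsv")


def read_prediction(path: str | Path) -> CellPrediction:
    out = Path(path)
    scores = sparse.coo_matrix(spio.mmread(str(out / "scores.mtx"))).toarray()
    cells = _read_id_column(out / "cells.tsv") if (out / "cells.tsv").exists() else np.array([], dtype=object)
    genes = _read_id_column(out / "genes.tsv") if (out / "genes.tsv").exists() else np.array([], dtype=object)
    if scores.size == 0:
        scores = scores.reshape(len(cells), len(genes))
    return CellPrediction(scores=scores, gene_ids=genes, cell_ids=cells)


def write_counts(sc: SpotCounts, path: str | Path) -> None:
    """Write a SpotCounts bundle: matrix.mtx (genes x spots), sidecars, positions."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "matrix.mtx"), sparse.csr_matrix(sc.counts.T))
    _write_ids(sc.spot_ids, out / "barcodes.tsv")
    _write_ids(sc.gene_ids, out / "features.tsv")
    pos = pd.DataFrame(
        {
            "barcode": sc.spot_ids,
            "in_tissue": 1,
            "array_row": 0,
            "array_col": 0,
            "pxl_row_in_fullres": sc.spot_xy[:, 1],
            "pxl_col_in_fullres": sc.spot_xy[:, 0],
        }
    )
    pos.to_csv(out / "tissue_positions.csv", index=False)
    (out / "spot_radius.txt").write_text(f"{sc.spot_radius}\n")


def read_counts_bundle(path: str | Path, *, slide_id: str = "slide") -> SpotCounts:
    out = Path(path)
    radius = float((out / "spot_radius.txt").read_text().strip())
    return read_counts(
        out / "matrix.mtx",
        out / "barcodes.tsv",
        out / "features.tsv",
        out / "tissue_positions.csv",
        slide_id=slide_id,
        spot_radius=radius,
    )


def write_cell_table(cells: CellTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {"id": cells.cell_ids, "x": cells.cell_xy[:, 0], "y": cells.cell_xy[:, 1]}
    )
    if cells.label is not None:
        df["label"] = cells.label
    df.to_csv(path, index=False)


def write_embeddings(emb: EmbeddingMatrix, path: str | Path) -> None:
    df = pd.DataFrame(emb.values)
    df.insert(0, "cell_id", emb.cell_ids)
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Optional one-file hierarchical container (AnnData-compatible layout)
# ---------------------------------------------------------------------------

def write_h5(sc: SpotCounts, path: str | Path) -> None:
    """Write a SpotCounts to a single h5ad file (spots in obs, genes in var)."""
    import anndata as ad

    adata = ad.AnnData(
        X=sparse.csr_matrix(sc.counts),
        obs=pd.DataFrame(index=pd.Index([str(s) for s in sc.spot_ids], name="spot_id")),
        var=pd.DataFrame(index=pd.Index([str(g) for g in sc.gene_ids], name="gene_id")),
    )
    adata.obsm["spatial"] = sc.spot_xy
    adata.uns["slide_id"] = sc.slide_id
    adata.uns["spot_radius"] = float(sc.spot_radius)
    adata.write_h5ad(Path(path))


def read_h5(path: str | Path) -> SpotCounts:
    """Read a SpotCounts from the h5ad layout written by :func:`write_h5`."""
    import anndata as ad

    adata = ad.read_h5ad(Path(path))
    X = adata.X
    counts = X.toarray() if sparse.issparse(X) else np.asarray(X)
    return SpotCounts(
        counts=counts,
        spot_ids=adata.obs_names.to_numpy(dtype=object),
        gene_ids=adata.var_names.to_numpy(dtype=object),
        slide_id=str(adata.uns.get("slide_id", "slide")),
        spot_xy=np.asarray(adata.obsm["spatial"], dtype=float),
        spot_radius=float(adata.uns["spot_radius"]),
    )


# ---------------------------------------------------------------------------
# Alignment checks
# ---------------------------------------------------------------------------

def check_aligned(emb: EmbeddingMatrix, cells: CellTable) -> None:
    """Fail loudly if an embedding matrix and a cell table disagree on ids."""
    if emb.n_cells != cells.n_cells or not np.array_equal(
        emb.cell_ids, cells.cell_ids
    ):
        raise AlignmentError(
            "embedding matrix and cell table do not share identical cell ids"
        )


def derive_seed(root: int, name: str) -> int:
    """Deterministically derive a named child seed (< 2**31) from a root seed.

    One root seed fans out to independent streams (split, init, sampling,
    bootstrap, ...) so that pipelines are reproducible end to end.
    """
    import zlib

    ss = np.random.SeedSequence([int(root) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
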