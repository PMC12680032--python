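"""File formats and shared identifiers for linked SMR + expression data.

Two kinds of input move through the pipeline:

* **SMR event tables** — one row per measured cell, with its buoyant mass
  (pg) and optionally stiffness (a.u.), volume (um^3), a viability flag and
  sample/condition labels.  Headered delimited text (comma default, tab
  accepted), since the instrument emits columnar logs.
* **Count matrices** — gene x cell raw counts, either MatrixMarket triplets
  (1-based on disk, 0-based in memory; conversion only at the I/O boundary)
  with plain-text gene/cell label sidecars, or a dense TSV.

``pair_events_with_matrix`` inner-joins the two on ``cell_id``: cells that
were measured but failed library prep (or vice versa) are dropped and
counted, not erred — the platform routinely loses cells between the SMR and
the sequencer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

CONDITIONS = ("reference", "vehicle", "drug", "untyped")

_REQUIRED_COLS = ("cell_id", "sample_id", "buoyant_mass")
_OPTIONAL_COLS = ("condition", "stiffness", "volume", "viable")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


@dataclass
class SMREventTable:
    """Validated per-cell SMR measurements.

    ``df`` always has columns cell_id, sample_id, condition, buoyant_mass,
    and whichever of stiffness/volume/viable were provided.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [col for col in _REQUIRED_COLS if col not in df.columns]
        if missing:
            raise FormatError(f"missing mandatory columns: {missing}")
        if "condition" not in df.columns:
            df = df.assign(condition="untyped")
        bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown condition labels: {sorted(bad_cond)}")
        dup = df["cell_id"][df["cell_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate cell_id values: {sorted(set(dup))}")
        mass = pd.to_numeric(df["buoyant_mass"], errors="coerce")
        bad = df.index[~np.isfinite(mass) | (mass <= 0)]
        if len(bad):
            raise ValidationError(
                f"buoyant_mass must be finite and positive; offending rows: {list(bad)}"
            )
        if "volume" in df.columns:
            vol = pd.to_numeric(df["volume"], errors="coerce")
            bad = df.index[vol.notna() & (vol <= 0)]
            if len(bad):
                raise ValidationError(f"volume must be positive; offending rows: {list(bad)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cell_ids(self) -> list[str]:
        return self.df["cell_id"].tolist()

    def masses(self, sample_id: str | None = None, viable_only: bool = False) -> np.ndarray:
        """Buoyant masses, optionally restricted to one sample and to viable cells."""
        df = self.df
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
        if viable_only and "viable" in df.columns:
            df = df[df["viable"].astype(bool)]
        return df["buoyant_mass"].to_numpy(dtype=float)


@dataclass
class CountMatrix:
    """Gene x cell raw integer counts with label sidecars."""

    genes: list[str]
    cells: list[str]
    counts: np.ndarray  # shape (n_genes, n_cells), integer >= 0
    mito_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene symbols")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("duplicate cell ids")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                self.counts == np.floor(self.counts)
            ) and np.all(self.counts >= 0):
                self.counts = self.counts.astype(np.int64)
            else:
                raise ValidationError("counts must be non-negative integers")
        missing = set(self.mito_genes) - set(self.genes)
        if missing:
            raise ValidationError(f"mito_genes not in genes: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def mito_mask(self) -> np.ndarray:
        mito = set(self.mito_genes)
        return np.fromiter((g in mito for g in self.genes), dtype=bool, count=len(self.genes))

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        gm = np.ones(len(self.genes), bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(len(self.cells), bool) if cell_mask is None else np.asarray(cell_mask)
        genes = [g for g, k in zip(self.genes, gm) if k]
        gset = set(genes)
        return CountMatrix(
            genes=genes,
            cells=[c for c, k in zip(self.cells, cm) if k],
            counts=self.counts[np.ix_(gm, cm)],
            mito_genes=[g for g in self.mito_genes if g in gset],
        )


@dataclass
class JoinReport:
    """Cells dropped on each side of the event/matrix inner join."""

    dropped_events: list[str]
    dropped_matrix_cells: list[str]
    n_joined: int


@dataclass
class PairedDataset:
    """SMR events and expression joined one-to-one on cell_id."""

    events: SMREventTable
    matrix: CountMatrix
    model_label: pd.Series  # indexed by cell_id
    tissue_label: pd.Series | None = None

    def __post_init__(self) -> None:
        ev = set(self.events.cell_ids)
        mx = set(self.matrix.cells)
        if ev != mx:
            raise ValidationError("events and matrix must cover the same cells")
        missing = mx - set(self.model_label.index)
        if missing:
            raise ValidationError(f"model_label missing for cells: {sorted(missing)[:5]}...")

    @property
    def cell_ids(self) -> list[str]:
        return self.matrix.cells

    def biophys_vector(self, column: str) -> np.ndarray:
        """Per-cell biophysical covariate in matrix cell order."""
        s = self.events.df.set_index("cell_id")[column]
        return s.loc[self.matrix.cells].to_numpy(dtype=float)

    def models(self) -> np.ndarray:
        return self.model_label.loc[self.matrix.cells].to_numpy()


# ---------------------------------------------------------------------------
# SMR event tables


def _sniff_delimiter(path: Path) -> str:
    head = path.open().readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def read_smr_events(path, delimiter: str | None = None) -> SMREventTable:
    """Read a headered CSV/TSV event table; delimiter sniffed when not given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delimiter = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"cell_id": str, "sample_id": str})
    for col in ("buoyant_mass", "stiffness", "volume"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise FormatError(
                    f"unparseable numeric values in column {col!r} at rows {list(bad)}"
                )
            df[col] = coerced.astype(float)
    if "viable" in df.columns:
        df["viable"] = df["viable"].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
        )
    return SMREventTable(df)


def write_smr_events(table: SMREventTable, path, delimiter: str = ",") -> None:
    """Write with full float precision so a read-back is bit-exact."""
    table.df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Count matrices


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.cells.txt")


def read_count_matrix(path, format: str = "mtx_triplet", mito_prefix: str = "MT-") -> CountMatrix:
    """Read raw counts from MatrixMarket triplets or a dense TSV.

    For ``mtx_triplet``, gene and cell labels come from ``<stem>.genes.txt``
    and ``<stem>.cells.txt`` sidecars (one label per line).  Mitochondrial
    genes are flagged by symbol prefix.
    """
    path = Path(path)
    if format == "mtx_triplet":
        genes_path, cells_path = _sidecar_paths(path)
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FormatError(f"missing label sidecar {p}")
        genes = genes_path.read_text().split()
        cells = cells_path.read_text().split()
        mat = scipy.io.mmread(path)
        counts = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        if counts.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix shape {counts.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        counts = df.to_numpy()
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")
    mito = [g for g in genes if g.startswith(mito_prefix)]
    return CountMatrix(genes=genes, cells=cells, counts=counts.astype(np.int64), mito_genes=mito)


def write_count_matrix(matrix: CountMatrix, path, format: str = "mtx_triplet") -> None:
    path = Path(path)
    if format == "mtx_triplet":
        genes_path, cells_path = _sidecar_paths(path)
        genes_path.write_text("\n".join(matrix.genes) + "\n")
        cells_path.write_text("\n".join(matrix.cells) + "\n")
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.counts), field="integer")
    elif format == "dense_tsv":
        pd.DataFrame(matrix.counts, index=matrix.genes, columns=matrix.cells).to_csv(
            path, sep="\t"
        )
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")


# ---------------------------------------------------------------------------
# Pairing


def pair_events_with_matrix(
    events: SMREventTable, matrix: CountMatrix, model_map
) -> tuple[PairedDataset, JoinReport]:
    """Inner join of events and matrix on cell_id.

    ``model_map`` maps cell_id -> model label (dict or Series) and must cover
    every retained cell.  Raises ``ValidationError`` when no cells overlap.
    """
    ev_ids = events.cell_ids
    shared = [c for c in matrix.cells if c in set(ev_ids)]
    if not shared:
        raise ValidationError("no overlapping cell_ids between events and matrix")
    report = JoinReport(
        dropped_events=sorted(set(ev_ids) - set(shared)),
        dropped_matrix_cells=sorted(set(matrix.cells) - set(shared)),
        n_joined=len(shared),
    )
    shared_set = set(shared)
    cell_mask = np.fromiter((c in shared_set for c in matrix.cells), bool, len(matrix.cells))
    sub_matrix = matrix.subset(cell_mask=cell_mask)
    ev_df = events.df[events.df["cell_id"].isin(shared_set)]
    # row order follows the matrix so downstream vectors align by position
    ev_df = ev_df.set_index("cell_id").loc[sub_matrix.cells].reset_index()
    model = pd.Series(dict(model_map) if not isinstance(model_map, pd.Series) else model_map)
    dataset = PairedDataset(
        events=SMREventTable(ev_df),
        matrix=sub_matrix,
        model_label=model.loc[sub_matrix.cells],
    )
    return dataset, report
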