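"""Peak-by-cell matrix container and on-disk formats.

The central object is :class:`PeakByCellMatrix`: a nonnegative integer count
matrix of shape ``(n_peaks, n_cells)`` with genomic-interval metadata for the
peaks (BED convention: 0-based, half-open) and unique string identifiers for
the cells. Two on-disk layouts are supported:

* ``mtx`` — MatrixMarket coordinate triplets (1-based on disk) plus sidecar
  ``peaks.bed`` (chrom / start / end) and ``cells.txt`` (one id per line);
* ``tsv`` — dense tab-separated values with ``chrom:start-end`` row names and
  cell ids as column names.

Cell-type labels, when present, live in a ``labels.tsv`` sidecar
(``cell_id <TAB> label``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "Peak",
    "PeakByCellMatrix",
    "read_matrix",
    "write_matrix",
    "parse_peak_id",
]

#: store sparse in memory below this density
_SPARSE_DENSITY = 0.5

_PEAK_RE = re.compile(r"^(?P<chrom>[^:]+)[:_](?P<start>\d+)[-_](?P<end>\d+)$")


@dataclass(frozen=True)
class Peak:
    """A genomic interval, 0-based half-open (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid peak interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_peak_id(text: str) -> Peak:
    """Parse a ``chrom:start-end`` (or ``chrom_start_end``) peak identifier."""
    m = _PEAK_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse peak identifier {text!r}")
    return Peak(m["chrom"], int(m["start"]), int(m["end"]))


class PeakByCellMatrix:
    """Counts of reads per peak per cell, with peak and cell metadata.

    Parameters
    ----------
    values
        ``(n_peaks, n_cells)`` nonnegative integer counts; dense ndarray or
        scipy sparse. The constructor picks the storage (sparse below 50%
        density); downstream operations are storage-agnostic.
    peaks
        One :class:`Peak` per row.
    cells
        Unique string identifier per column.
    labels
        Optional per-cell reference cell-type labels.
    batch
        Optional per-cell batch labels.
    """

    def __init__(
        self,
        values,
        peaks: Sequence[Peak | str],
        cells: Sequence[str],
        labels: Sequence[str] | None = None,
        batch: Sequence[str] | None = None,
    ) -> None:
        if sp.issparse(values):
            values = values.tocsr()
        else:
            values = np.asarray(values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.peaks = [p if isinstance(p, Peak) else parse_peak_id(p) for p in peaks]
        self.cells = [str(c) for c in cells]
        self.labels = list(labels) if labels is not None else None
        self.batch = list(batch) if batch is not None else None
        self.values = self._choose_storage(values)
        self.validate()

    @staticmethod
    def _choose_storage(values):
        n = values.shape[0] * values.shape[1]
        nnz = values.nnz if sp.issparse(values) else int(np.count_nonzero(values))
        density = nnz / n if n else 0.0
        if density < _SPARSE_DENSITY:
            return values.tocsr() if sp.issparse(values) else sp.csr_matrix(values)
        return values.toarray() if sp.issparse(values) else values

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n_peaks, n_cells = self.values.shape
        if len(self.peaks) != n_peaks:
            raise ValueError(f"{len(self.peaks)} peaks for {n_peaks} matrix rows")
        if len(self.cells) != n_cells:
            raise ValueError(f"{len(self.cells)} cells for {n_cells} matrix columns")
        if len(set(self.cells)) != len(self.cells):
            seen, dup = set(), None
            for c in self.cells:
                if c in seen:
                    dup = c
                    break
                seen.add(c)
            raise ValueError(f"duplicate cell identifier {dup!r}")
        if self.labels is not None and len(self.labels) != n_cells:
            raise ValueError("labels length does not match number of cells")
        if self.batch is not None and len(self.batch) != n_cells:
            raise ValueError("batch length does not match number of cells")
        mn = self.values.min() if not sp.issparse(self.values) else (
            self.values.data.min() if self.values.nnz else 0
        )
        if mn < 0:
            raise ValueError("counts must be nonnegative")

    # -- convenience --------------------------------------------------------

    @property
    def n_peaks(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        """Counts as a dense ndarray (copy when stored sparse)."""
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def peak_ids(self) -> list[str]:
        return [str(p) for p in self.peaks]

    def subset_peaks(self, idx) -> "PeakByCellMatrix":
        idx = np.asarray(idx)
        return PeakByCellMatrix(
            self.values[idx, :],
            [self.peaks[i] for i in idx],
            self.cells,
            labels=self.labels,
            batch=self.batch,
        )

    def subset_cells(self, idx) -> "PeakByCellMatrix":
        idx = np.asarray(idx)
        return PeakByCellMatrix(
            self.values[:, idx],
            self.peaks,
            [self.cells[i] for i in idx],
            labels=[self.labels[i] for i in idx] if self.labels is not None else None,
            batch=[self.batch[i] for i in idx] if self.batch is not None else None,
        )

    def with_values(self, values) -> "PeakByCellMatrix":
        """Same metadata, new values of identical shape."""
        return PeakByCellMatrix(
            values, self.peaks, self.cells, labels=self.labels, batch=self.batch
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _read_peaks(path: Path) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            try:
                if len(parts) >= 3:
                    peaks.append(Peak(parts[0], int(parts[1]), int(parts[2])))
                else:
                    peaks.append(parse_peak_id(parts[0]))
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: {e}") from None
    return peaks


def _read_cells(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _read_labels(path: Path, cells: list[str]) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] == 1:
        labels = df[0].tolist()
        if len(labels) != len(cells):
            raise ValueError("label file length does not match number of cells")
        return labels
    mapping = dict(zip(df[0], df[1]))
    missing = [c for c in cells if c not in mapping]
    if missing:
        raise ValueError(f"labels missing for cells: {missing[:5]} ...")
    return [mapping[c] for c in cells]


def read_matrix(
    path: str | Path,
    format: str = "mtx",
    *,
    transposed: bool = False,
    labels: str | Path | None = None,
) -> PeakByCellMatrix:
    """Read a peak-by-cell matrix from disk.

    Parameters
    ----------
    path
        For ``format="mtx"``: a directory containing ``matrix.mtx``,
        ``peaks.bed`` (or ``peaks.txt``) and ``cells.txt``. For
        ``format="tsv"``: the dense TSV file.
    transposed
        Set when the on-disk matrix is cells x peaks; the result is always
        peaks x cells.
    labels
        Optional labels TSV (``cell_id <TAB> label`` or one label per line).
    """
    path = Path(path)
    if format == "mtx":
        mdir = path if path.is_dir() else path.parent
        values = scipy.io.mmread(str(mdir / "matrix.mtx"))
        peaks_path = mdir / "peaks.bed"
        if not peaks_path.exists():
            peaks_path = mdir / "peaks.txt"
        peaks = _read_peaks(peaks_path)
        cells = _read_cells(mdir / "cells.txt")
        if labels is None and (mdir / "labels.tsv").exists():
            labels = mdir / "labels.tsv"
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if transposed:
            df = df.T
        values = df.to_numpy()
        peaks = [parse_peak_id(p) for p in df.index]
        cells = [str(c) for c in df.columns]
        transposed = False  # already applied
    else:
        raise ValueError(f"unknown format {format!r} (expected 'mtx' or 'tsv')")

    if transposed:
        values = values.T
        peaks, cells = cells, peaks  # type: ignore[assignment]
    values = values.astype(np.int64) if not sp.issparse(values) else values.astype(np.int64)
    lab = _read_labels(Path(labels), list(cells)) if labels is not None else None
    return PeakByCellMatrix(values, peaks, cells, labels=lab)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_matrix(m: PeakByCellMatrix, path: str | Path, format: str = "mtx") -> None:
    """Write a matrix so that :func:`read_matrix` round-trips it losslessly."""
    m.validate()
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        vals = m.values if sp.issparse(m.values) else sp.coo_matrix(m.values)
        scipy.io.mmwrite(str(path / "matrix.mtx"), vals.astype(np.int64))
        with open(path / "peaks.bed", "w") as fh:
            for p in m.peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
        with open(path / "cells.txt", "w") as fh:
            fh.write("\n".join(m.cells) + "\n")
        if m.labels is not None:
            with open(path / "labels.tsv", "w") as fh:
                for c, l in zip(m.cells, m.labels):
                    fh.write(f"{c}\t{l}\n")
    elif format == "tsv":
        df = pd.DataFrame(m.dense(), index=m.peak_ids(), columns=m.cells)
        df.to_csv(path, sep="\t")
        if m.labels is not None:
            side = Path(str(path) + ".labels.tsv")
            pd.DataFrame({"cell": m.cells, "label": m.labels}).to_csv(
                side, sep="\t", header=False, index=False
            )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'mtx' or 'tsv')")
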