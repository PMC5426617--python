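"""OTU × location abundance matrices: reading, validation, filtering, summaries.

The central container is :class:`AbundanceMatrix`: an N × L matrix of
non-negative abundances (raw sequence counts are integers; after tie-breaking
noise the entries are real-valued), with unique OTU and location identifiers
and an optional OTU → phylum map. The canonical in-memory orientation is
OTUs in rows, locations in columns; readers accept either orientation and
transpose on ingest.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "AbundanceParseError",
    "read_abundance_matrix",
    "write_abundance_matrix",
    "read_taxonomy",
    "filter_min_total",
    "sparsity",
    "classify_otus",
]

#: Label used for OTUs with no known phylum assignment.
OTHER_PHYLUM = "Other"


class AbundanceParseError(ValueError):
    """A cell of an abundance file failed to parse or violated a constraint."""


@dataclass
class AbundanceMatrix:
    """An OTU × location abundance matrix.

    Parameters
    ----------
    counts : ndarray of shape (n_otus, n_locations)
        Non-negative abundances. Raw data are integer sequence counts;
        noise-added matrices hold floats.
    otu_ids, location_ids : sequence of str
        Unique row and column identifiers.
    phylum : mapping otu_id -> phylum, optional
        Taxonomic labels. OTUs absent from the map are treated as ``"Other"``.
    """

    counts: np.ndarray
    otu_ids: Sequence[str]
    location_ids: Sequence[str]
    phylum: Optional[Mapping[str, str]] = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.location_ids = [str(c) for c in self.location_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        n, l = self.counts.shape
        if n != len(self.otu_ids) or l != len(self.location_ids):
            raise ValueError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTU ids / {len(self.location_ids)} location ids"
            )
        if len(set(self.otu_ids)) != n:
            raise AbundanceParseError("duplicate OTU ids")
        if len(set(self.location_ids)) != l:
            raise AbundanceParseError("duplicate location ids")
        if not np.all(np.isfinite(self.counts)):
            raise AbundanceParseError("non-finite abundance values")

    # -- basic views ----------------------------------------------------
    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_locations(self) -> int:
        return self.counts.shape[1]

    def row_totals(self) -> np.ndarray:
        """Total abundance of each OTU across all locations."""
        return self.counts.sum(axis=1)

    def occupancy(self) -> np.ndarray:
        """Number of locations with strictly positive abundance, per OTU."""
        return (self.counts > 0).sum(axis=1)

    def phylum_of(self, otu_id: str) -> str:
        if self.phylum is None:
            return OTHER_PHYLUM
        return self.phylum.get(otu_id, OTHER_PHYLUM)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.location_ids)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, phylum: Optional[Mapping[str, str]] = None
    ) -> "AbundanceMatrix":
        return cls(
            counts=frame.to_numpy(dtype=float),
            otu_ids=[str(i) for i in frame.index],
            location_ids=[str(c) for c in frame.columns],
            phylum=phylum,
        )


def _validate_cells(frame: pd.DataFrame, path: str) -> pd.DataFrame:
    """Coerce every cell to a non-negative number, naming offenders."""
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise AbundanceParseError(
            f"{path}: non-numeric or missing cell at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r}"
        )
    neg = numeric.to_numpy() < 0
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise AbundanceParseError(
            f"{path}: negative abundance at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r}"
        )
    return numeric


def read_abundance_matrix(
    path: str,
    orientation: str = "otus_in_rows",
    delimiter: Optional[str] = None,
    phylum: Optional[Mapping[str, str]] = None,
) -> AbundanceMatrix:
    """Read an abundance matrix from delimited text or XLSX.

    The first column holds row identifiers and the first row holds column
    identifiers. ``orientation`` says whether rows are OTUs
    (``"otus_in_rows"``) or locations (``"otus_in_columns"``); the returned
    matrix is always in the canonical OTUs-in-rows orientation. The delimiter
    is inferred from the extension (``.csv`` → comma, otherwise tab) unless
    given explicitly.
    """
    if orientation not in ("otus_in_rows", "otus_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".xlsx", ".xls"):
        frame = pd.read_excel(path, sheet_name=0, index_col=0)
    else:
        sep = delimiter if delimiter is not None else ("," if ext == ".csv" else "\t")
        frame = pd.read_csv(path, sep=sep, index_col=0)
    frame = _validate_cells(frame, path)
    if orientation == "otus_in_columns":
        frame = frame.T
    return AbundanceMatrix.from_frame(frame, phylum=phylum)


def write_abundance_matrix(m: AbundanceMatrix, path: str, delimiter: str = "\t") -> None:
    """Write ``m`` as delimited text, OTUs in rows, with a header line."""
    frame = m.to_frame()
    # Preserve integer appearance for raw count matrices.
    if np.allclose(frame.to_numpy(), np.round(frame.to_numpy())):
        frame = frame.astype(np.int64)
    frame.to_csv(path, sep=delimiter, index_label="otu_id")


def read_taxonomy(path: str, delimiter: str = "\t") -> Dict[str, str]:
    """Read a two-column (otu_id, phylum) table into a dict."""
    frame = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if frame.shape[1] < 2:
        raise AbundanceParseError(f"{path}: expected two columns (otu_id, phylum)")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def filter_min_total(m: AbundanceMatrix, min_total: float = 5) -> AbundanceMatrix:
    """Drop OTUs with total abundance below ``min_total`` across all locations.

    Rows whose sum is *at least* ``min_total`` are kept (OTUs with *fewer*
    than ``min_total`` sequences are discarded); the location set is
    unchanged. Quality-control step against sequencing errors and sample
    contamination.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = m.row_totals() >= min_total
    otu_ids = [o for o, k in zip(m.otu_ids, keep) if k]
    phylum = None
    if m.phylum is not None:
        phylum = {o: m.phylum[o] for o in otu_ids if o in m.phylum}
    return AbundanceMatrix(
        counts=m.counts[keep], otu_ids=otu_ids, location_ids=list(m.location_ids),
        phylum=phylum,
    )


def sparsity(m: AbundanceMatrix) -> float:
    """Fraction of exactly-zero entries in the matrix."""
    if m.counts.size == 0:
        raise ValueError("sparsity undefined for an empty matrix")
    return float((m.counts == 0).sum() / m.counts.size)


def classify_otus(
    m: AbundanceMatrix,
    generalist_min_sites: int = 80,
    specialist_max_sites: int = 10,
    specialist_min_mean_count: float = 18,
) -> Dict[str, str]:
    """Label each OTU as ``generalist``, ``specialist`` or ``neither``.

    A generalist occupies strictly more than ``generalist_min_sites``
    locations. A specialist occupies strictly fewer than
    ``specialist_max_sites`` locations with a mean abundance over its
    occupied sites strictly greater than ``specialist_min_mean_count``.
    Occupancy means strictly positive abundance. The two classes are
    mutually exclusive whenever ``generalist_min_sites >=
    specialist_max_sites``.
    """
    if generalist_min_sites <= 0 or specialist_max_sites <= 0 or specialist_min_mean_count <= 0:
        raise ValueError("classification thresholds must be positive")
    occ = m.occupancy()
    totals = m.row_totals()
    labels: Dict[str, str] = {}
    for i, otu in enumerate(m.otu_ids):
        if occ[i] > generalist_min_sites:
            labels[otu] = "generalist"
        elif occ[i] < specialist_max_sites and occ[i] > 0 and totals[i] / occ[i] > specialist_min_mean_count:
            labels[otu] = "specialist"
        else:
            labels[otu] = "neither"
    return labels
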