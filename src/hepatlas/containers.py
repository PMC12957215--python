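"""Core in-memory containers shared across the pipeline.

Expression matrices are stored genes x cells (single cell) or
genes x samples (bulk), with identifiers kept alongside as pandas
indexes so that every downstream table is keyed by gene/cell/sample ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_CELL_META = ("stage", "subtype", "mito_fraction", "n_detected_genes")


@dataclass
class LabeledExpression:
    """Genes x cells count matrix with per-cell labels.

    Attributes
    ----------
    counts : np.ndarray
        Non-negative integer matrix, shape (n_genes, n_cells).
    gene_ids : pd.Index
        Gene identifiers, length n_genes.
    cell_meta : pd.DataFrame
        One row per cell (index = cell barcode) with at least the columns
        ``stage``, ``subtype``, ``mito_fraction`` and ``n_detected_genes``.
    """

    counts: np.ndarray
    gene_ids: pd.Index
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"counts has {self.counts.shape[0]} rows but "
                f"{len(self.gene_ids)} gene ids"
            )
        if self.counts.shape[1] != len(self.cell_meta):
            raise ValueError(
                f"counts has {self.counts.shape[1]} columns but cell_meta "
                f"has {len(self.cell_meta)} rows"
            )
        missing = [c for c in REQUIRED_CELL_META if c not in self.cell_meta]
        if missing:
            raise ValueError(f"cell_meta missing required columns: {missing}")
        if not np.isfinite(self.counts).all():
            raise ValueError("counts must be finite")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "LabeledExpression":
        """Return a new container restricted to the given boolean masks."""
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return LabeledExpression(
            counts=self.counts[np.ix_(gm, cm)],
            gene_ids=self.gene_ids[gm],
            cell_meta=self.cell_meta.loc[cm],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.cell_meta.index
        )


@dataclass
class BulkCohort:
    """Bulk expression cohort with clinical follow-up.

    expression : genes x samples real matrix (pandas, indexed by gene ID,
    columns = sample IDs).  clinical : per-sample table (index = sample ID)
    with columns ``OS_time`` (> 0), ``event`` (0/1), ``age`` (years) and
    ``group`` ('normal' or 'tumor').  ``true_z`` (standardized planted
    burden) is attached by the simulator when ground truth is known.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expression.columns.equals(self.clinical.index):
            # allow same set in same order only
            raise ValueError("expression columns must equal clinical index")
        if self.clinical.index.has_duplicates:
            raise ValueError("sample IDs must be unique")
        for col in ("OS_time", "event", "age"):
            if col not in self.clinical:
                raise ValueError(f"clinical table missing column {col!r}")
        if (self.clinical["OS_time"] <= 0).any():
            raise ValueError("OS_time must be > 0 for all samples")
        if not self.clinical["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


@dataclass
class GeneSet:
    """A named, non-empty gene set with unique members."""

    name: str
    members: tuple[str, ...]

    def __init__(self, name: str, members) -> None:
        self.name = str(name)
        members = tuple(dict.fromkeys(members))  # dedupe, keep order
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        self.members = members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass
class FishScene:
    """Multi-channel fluorescence raster with channel semantics.

    channels maps channel name -> 2-D array (all identical shape);
    channel_map maps marker channel name -> marker gene.  'DAPI' and
    'tumor' are reserved channel names (nucleus stain / tumor-cell stain).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    channel_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        shapes = {name: np.asarray(a).shape for name, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape
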