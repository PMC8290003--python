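"""Core data containers shared across the pipeline.

The assay measures, for every segmented cell, the mean fluorescence
intensity (MFI) of a transcription-factor channel inside the nucleus and in
a cytosolic ring, and scores the cell by the nuclear/cytosolic (N/C) ratio.
These dataclasses are the in-memory contracts between the simulation,
segmentation, measurement and scoring stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleImage",
    "RegionMasks",
    "CellRecord",
    "SampleScore",
    "cell_records_to_frame",
    "CELL_RECORD_COLUMNS",
]


@dataclass
class SampleImage:
    """A registered two-channel image of one sample.

    Channel 1 (``nuclear_channel``) carries the DNA stain used for
    segmentation; channel 2 (``tf_channel``) carries the transcription-factor
    immunofluorescence that is actually measured. Both are 2-D nonnegative
    intensity arrays of identical shape, in arbitrary fluorescence units.
    """

    nuclear_channel: np.ndarray
    tf_channel: np.ndarray
    sample_id: str = "sample"
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.nuclear_channel = np.asarray(self.nuclear_channel, dtype=float)
        self.tf_channel = np.asarray(self.tf_channel, dtype=float)
        if self.nuclear_channel.ndim != 2 or self.tf_channel.ndim != 2:
            raise ValueError("channels must be 2-D arrays")
        if self.nuclear_channel.shape != self.tf_channel.shape:
            raise ValueError(
                f"channel shapes differ: {self.nuclear_channel.shape} vs "
                f"{self.tf_channel.shape}"
            )
        for name, chan in (("nuclear", self.nuclear_channel), ("tf", self.tf_channel)):
            if not np.all(np.isfinite(chan)):
                raise ValueError(f"{name} channel contains non-finite pixels")
            if np.any(chan < 0):
                raise ValueError(f"{name} channel contains negative intensities")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear_channel.shape


@dataclass
class RegionMasks:
    """Per-cell nuclear and cytosolic measurement regions.

    Both label images share cell ids; id 0 is background. The nuclear and
    cytosolic regions of one cell are disjoint by construction, and cells
    dropped during region definition are listed in ``qc_excluded`` with a
    reason code.
    """

    nuclear_labels: np.ndarray
    cytosol_labels: np.ndarray
    qc_excluded: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nuclear_labels = np.asarray(self.nuclear_labels)
        self.cytosol_labels = np.asarray(self.cytosol_labels)
        if self.nuclear_labels.shape != self.cytosol_labels.shape:
            raise ValueError("label image shapes differ")

    @property
    def cell_ids(self) -> list[int]:
        ids = np.unique(self.nuclear_labels)
        return [int(i) for i in ids if i != 0]


@dataclass
class CellRecord:
    """One cell's background-subtracted MFIs and their N/C ratio.

    ``nc_ratio`` is NaN when the cell failed QC (e.g. cytosolic MFI at the
    division-guard floor); guarded cells are excluded rather than clipped so
    the ratio distribution is never distorted by infinities.
    """

    sample_id: str
    cell_id: int
    nuclear_mfi: float
    cytosolic_mfi: float
    nc_ratio: float
    nuclear_area_px: int
    cytosol_area_px: int
    qc_pass: bool
    qc_reason: str = ""


CELL_RECORD_COLUMNS = [
    "sample_id",
    "cell_id",
    "nuclear_mfi",
    "cytosolic_mfi",
    "nc_ratio",
    "nuclear_area_px",
    "cytosol_area_px",
    "qc_pass",
    "qc_reason",
]


def cell_records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Tabulate cell records with a fixed, documented column order."""
    rows = [[getattr(r, c) for c in CELL_RECORD_COLUMNS] for r in records]
    return pd.DataFrame(rows, columns=CELL_RECORD_COLUMNS)


@dataclass
class SampleScore:
    """Per-sample translocation statistics.

    ``threshold`` is exactly ``k × mode_ratio``; a cell counts as
    translocated when its ratio strictly exceeds the threshold.
    ``aberrant_strength`` is the sum of the N/C ratios of translocated
    cells, and ``responder`` flags samples whose prevalence reaches the
    responder cutoff (default 5%).
    """

    sample_id: str
    n_cells: int
    mode_ratio: float
    threshold: float
    nt_count: int
    nt_prevalence_pct: float
    aberrant_strength: float
    responder: bool
    low_cell_warning: bool = False
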