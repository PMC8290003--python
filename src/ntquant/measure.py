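"""Per-cell MFI measurement on the transcription-factor channel.

MFI is the arithmetic mean intensity over a region's pixels. Background
subtraction is off by default (the simplest reading of an MFI ratio);
``global_median`` subtracts the median intensity of pixels belonging to no
cell, floored at zero, which real images generally need.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .core import CellRecord, RegionMasks, SampleImage

__all__ = ["measure_cells", "RATIO_EPSILON"]

# division guard: cells with cytosolic MFI at or below this floor are
# QC-excluded rather than given huge/infinite ratios
RATIO_EPSILON = 1e-6


def measure_cells(
    masks: RegionMasks,
    image: SampleImage,
    background: str = "none",
) -> list[CellRecord]:
    """Measure nuclear and cytosolic MFIs and the N/C ratio per cell.

    Parameters
    ----------
    masks
        Region masks from :func:`ntquant.segment.define_cell_regions`,
        derived from ``image``.
    image
        The two-channel sample image; only the TF channel is measured.
    background
        ``"none"`` (default) or ``"global_median"`` — subtract the median
        TF intensity over pixels outside every nuclear and cytosolic
        region, flooring MFIs at 0.

    Returns
    -------
    list of CellRecord, in ascending cell_id order; empty masks yield an
    empty list. Cells whose background-subtracted cytosolic MFI is at the
    division-guard floor carry ``qc_pass=False`` and a NaN ratio.
    """
    if background not in ("none", "global_median"):
        raise ValueError("background must be 'none' or 'global_median'")
    if masks.nuclear_labels.shape != image.shape:
        raise ValueError("masks do not match image shape")

    tf = image.tf_channel
    ids = sorted(
        set(np.unique(masks.nuclear_labels).tolist())
        & set(np.unique(masks.cytosol_labels).tolist())
        - {0}
    )
    if not ids:
        return []

    bg = 0.0
    if background == "global_median":
        outside = (masks.nuclear_labels == 0) & (masks.cytosol_labels == 0)
        if outside.any():
            bg = float(np.median(tf[outside]))

    idx = np.asarray(ids)
    nuc_mean = ndi.mean(tf, labels=masks.nuclear_labels, index=idx)
    cyt_mean = ndi.mean(tf, labels=masks.cytosol_labels, index=idx)
    nuc_area = ndi.sum_labels(
        np.ones_like(tf), labels=masks.nuclear_labels, index=idx
    ).astype(int)
    cyt_area = ndi.sum_labels(
        np.ones_like(tf), labels=masks.cytosol_labels, index=idx
    ).astype(int)

    records: list[CellRecord] = []
    for k, cell_id in enumerate(ids):
        n_mfi = max(float(nuc_mean[k]) - bg, 0.0)
        c_mfi = max(float(cyt_mean[k]) - bg, 0.0)
        if c_mfi > RATIO_EPSILON:
            records.append(
                CellRecord(
                    sample_id=image.sample_id,
                    cell_id=int(cell_id),
                    nuclear_mfi=n_mfi,
                    cytosolic_mfi=c_mfi,
                    nc_ratio=n_mfi / c_mfi,
                    nuclear_area_px=int(nuc_area[k]),
                    cytosol_area_px=int(cyt_area[k]),
                    qc_pass=True,
                )
            )
        else:
            records.append(
                CellRecord(
                    sample_id=image.sample_id,
                    cell_id=int(cell_id),
                    nuclear_mfi=n_mfi,
                    cytosolic_mfi=c_mfi,
                    nc_ratio=float("nan"),
                    nuclear_area_px=int(nuc_area[k]),
                    cytosol_area_px=int(cyt_area[k]),
                    qc_pass=False,
                    qc_reason="cytosol_below_floor",
                )
            )
    return records
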