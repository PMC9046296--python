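"""Segmentation and per-cell measurement of fluorescence images.

Replaces the manual measurement workflow with a transparent, standard
recipe: Otsu thresholding of the DAPI channel for nuclei (optionally
split by a distance-transform watershed seeded at h-maxima), a
nucleus-seeded watershed over the phalloidin foreground for whole
cells, and regionprops-based per-cell statistics (mean gray value per
marker channel, cell and nucleus areas in um^2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import h_maxima
from skimage.segmentation import clear_border, relabel_sequential, watershed

from .datatypes import MARKERS, MEASUREMENT_COLUMNS, SampleProfile, StageLabel

__all__ = [
    "SegmentationConfig",
    "segment_nuclei",
    "segment_cells",
    "measure_cells",
    "select_cells",
    "measurements_to_profile",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs for the thresholding/watershed pipeline.

    ``min_object_area_um2`` removes sub-cellular debris; ``watershed``
    splits touching nuclei via distance-transform maxima (``h_maxima_h``
    is the minimum prominence, in pixels of distance, for a maximum to
    seed its own nucleus); ``exclude_border`` drops cells touching the
    image edge so truncated areas never enter the panel.
    """

    method: str = "otsu"
    min_object_area_um2: float = 10.0
    watershed: bool = True
    fill_holes: bool = True
    pixel_size: float = 0.5
    exclude_border: bool = True
    h_maxima_h: float = 2.0
    background_subtract: float = 0.0
    log_transform: bool = True
    smooth_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.min_object_area_um2 < 0:
            raise ValueError("min_object_area_um2 must be >= 0")
        if self.method != "otsu":
            raise ValueError(f"unknown thresholding method {self.method!r}")


def _threshold(image: np.ndarray, config: SegmentationConfig) -> np.ndarray | None:
    img = image.astype(np.float64)
    if config.background_subtract:
        img = np.clip(img - config.background_subtract, 0, None)
    if config.log_transform:
        # fluorescence intensities are right-skewed across cells; Otsu on
        # the log scale separates background from the dimmest cell instead
        # of splitting dim from bright cells
        img = np.log1p(np.clip(img, 0, None))
    if np.ptp(img) == 0:
        return None
    # pick the threshold on a lightly smoothed histogram so read-noise
    # speckle does not form its own mode, but apply it to the raw pixels
    # so mask edges are not displaced by the blur
    ref = ndi.gaussian_filter(img, config.smooth_sigma) \
        if config.smooth_sigma > 0 else img
    return img > threshold_otsu(ref)


def _min_area_px(config: SegmentationConfig) -> int:
    return int(np.ceil(config.min_object_area_um2 / config.pixel_size**2))


def segment_nuclei(
    dapi_channel: np.ndarray,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Label nuclei in a DAPI channel.

    Foreground is the Otsu-thresholded channel; touching nuclei are
    split by a watershed on the distance transform seeded at h-maxima
    when enabled; objects below the minimum area are removed.  A
    degenerate (all-equal) image yields an empty mask with a warning.
    """
    config = config or SegmentationConfig()
    if dapi_channel.ndim != 2:
        raise ValueError("expected a 2D channel")
    fg = _threshold(dapi_channel, config)
    if fg is None:
        warnings.warn("degenerate image (all pixels equal): empty nucleus mask",
                      stacklevel=2)
        return np.zeros(dapi_channel.shape, dtype=np.int32)
    if config.fill_holes:
        fg = ndi.binary_fill_holes(fg)
    min_px = _min_area_px(config)

    if not config.watershed:
        labels = cc_label(fg)
    else:
        distance = ndi.distance_transform_edt(fg)
        # h-maxima gives one seed per sufficiently prominent peak, so a
        # single elongated nucleus (ridge-shaped distance map) is not
        # oversplit while genuinely touching nuclei are.
        seeds_mask = h_maxima(distance, config.h_maxima_h)
        seeds = cc_label(seeds_mask)
        if seeds.max() == 0:
            labels = cc_label(fg)
        else:
            labels = watershed(-distance, markers=seeds, mask=fg)
    if min_px > 1:
        sizes = np.bincount(labels.ravel())
        kill = np.flatnonzero(sizes < min_px)
        labels[np.isin(labels, kill[kill > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_cells(
    phalloidin_channel: np.ndarray,
    nuclei: np.ndarray,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Partition the phalloidin foreground into cells seeded at nuclei.

    Each cell label equals its seed nucleus label; foreground regions
    containing no nucleus are discarded.
    """
    config = config or SegmentationConfig()
    if phalloidin_channel.shape != nuclei.shape:
        raise ValueError(
            f"channel shape {phalloidin_channel.shape} != "
            f"nucleus mask shape {nuclei.shape}"
        )
    if nuclei.max() == 0:
        warnings.warn("no nucleus seeds: empty cell mask", stacklevel=2)
        return np.zeros(nuclei.shape, dtype=np.int32)
    fg = _threshold(phalloidin_channel, config)
    if fg is None:
        warnings.warn("degenerate phalloidin channel: empty cell mask",
                      stacklevel=2)
        return np.zeros(nuclei.shape, dtype=np.int32)
    if config.fill_holes:
        fg = ndi.binary_fill_holes(fg)
    fg = fg | (nuclei > 0)  # a nucleus is always inside its cell
    distance = ndi.distance_transform_edt(nuclei == 0)
    cells = watershed(distance, markers=nuclei, mask=fg)
    # drop foreground components that received no seed (watershed already
    # leaves them 0) and remove tiny fragments
    min_px = _min_area_px(config)
    if min_px > 1:
        sizes = np.bincount(cells.ravel())
        kill = np.flatnonzero(sizes < min_px)
        cells[np.isin(cells, kill[kill > 0])] = 0
    return cells.astype(np.int32)


def measure_cells(
    channels: dict[str, np.ndarray],
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    config: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Per-cell mean gray values and areas.

    ``channels`` maps marker names (rbp4, sod3, ifitm3, factin or
    phalloidin) to pixel arrays.  For each cell label: the mean gray
    value of each marker over the cell mask, cell_area = pixel count x
    pixel_size^2, nucleus_area likewise over the matching nucleus
    label.  Cells without a matching nucleus, with nucleus_area >
    cell_area, or (by default) touching the border are excluded; the
    exclusion count is logged.
    """
    config = config or SegmentationConfig()
    shapes = {a.shape for a in channels.values()} | {
        cell_mask.shape, nucleus_mask.shape
    }
    if len(shapes) != 1:
        raise ValueError(f"arrays have inconsistent shapes: {shapes}")

    marker_channels = {}
    for m in MARKERS:
        key = m if m in channels else ("phalloidin" if m == "factin" else None)
        if key is None or key not in channels:
            raise KeyError(f"no channel provided for marker {m!r}")
        marker_channels[m] = channels[key]

    work_mask = cell_mask
    if config.exclude_border:
        work_mask = clear_border(cell_mask)

    nucleus_areas = {
        p.label: p.area for p in regionprops(nucleus_mask)
    }
    px2 = config.pixel_size**2
    rows = []
    excluded = 0
    for prop in regionprops(work_mask):
        lbl = prop.label
        if lbl not in nucleus_areas:
            excluded += 1
            continue
        if nucleus_areas[lbl] > prop.area:
            excluded += 1
            continue
        region = work_mask == lbl
        row = {"cell_id": lbl}
        for m in MARKERS:
            row[m] = float(marker_channels[m][region].mean())
        row["cell_area_um2"] = prop.area * px2
        row["nucleus_area_um2"] = nucleus_areas[lbl] * px2
        rows.append(row)
    if excluded:
        logger.info("measure_cells: excluded %d cell(s) without a valid nucleus",
                    excluded)
    table = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
    table.attrs["n_excluded"] = excluded
    return table


def select_cells(
    measurements: pd.DataFrame,
    k: int = 20,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample k cells uniformly without replacement, ordered as rounds 1..k.

    Mirrors the detection-round design: k randomly selected individual
    cells per biomarker per sample (k = 20 by default).  Raises if
    fewer than k cells are available — no silent padding.
    """
    n = len(measurements)
    if n < k:
        raise ValueError(
            f"need at least {k} measured cells, have {n} (short by {k - n})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    out = measurements.iloc[idx].reset_index(drop=True)
    out.index = pd.RangeIndex(1, k + 1, name="round")
    return out


def measurements_to_profile(
    measurements: pd.DataFrame,
    sample_id: str,
    batch_id: str = "batch1",
    stage: StageLabel = StageLabel.UNKNOWN,
) -> SampleProfile:
    """Convert a k-round measurement table into a SampleProfile."""
    values = pd.DataFrame(
        {
            **{m: measurements[m].to_numpy() for m in MARKERS},
            "cell_size": measurements["cell_area_um2"].to_numpy(),
            "nucleus_size": measurements["nucleus_area_um2"].to_numpy(),
        }
    )
    return SampleProfile(
        sample_id=sample_id, batch_id=batch_id, stage=stage, values=values
    )
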