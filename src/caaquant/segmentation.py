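"""Vessel classification on maximum-projected immunofluorescence images.

Arterioles are structures positive for both Collagen IV and a *complete ring*
of alpha-SMA whose stained wall (excluding the unstained lumen) covers at
least ``min_arteriole_area_px`` pixels -- the 150-px threshold derives from
the anatomical minimum arteriole diameter of 10 um at 0.5676 um/px.
Capillaries are what remains of the comprehensive Collagen IV mask after
subtracting the arteriole mask dilated by 4 px, filtered at 29 px
(the projected area of a 3.5-um capillary).

"Complete ring" is operationalised as: morphological hole-filling of the
connected component adds at least ``min_lumen_px`` enclosed pixels.  A ring
cut by a gap, a solid disk, or a component truncated by the image border
therefore does not qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .imaging import px_to_um2

VESSEL_RECORD_COLUMNS = [
    "vessel_id", "kind", "area_px", "area_um2", "lumen_area_px",
]


@dataclass
class SegmentationParams:
    """Tunable parameters of the vessel classifier.

    ``threshold_method`` maps channel name to either the string ``"otsu"``
    or a fixed numeric threshold.  Connectivity is 4 or 8 (default 8,
    matching common particle-analysis behaviour).
    """

    threshold_method: dict[str, object] = field(
        default_factory=lambda: {"collagen4": "otsu", "sma": "otsu"}
    )
    min_arteriole_area_px: int = 150
    min_capillary_area_px: int = 29
    dilation_radius_px: int = 4
    copositivity_fraction: float = 0.5
    min_lumen_px: int = 1
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.min_arteriole_area_px < 0 or self.min_capillary_area_px < 0:
            raise ValueError("area thresholds must be nonnegative")
        if self.dilation_radius_px < 0:
            raise ValueError("dilation_radius_px must be nonnegative")
        if not 0 < self.copositivity_fraction <= 1:
            raise ValueError("copositivity_fraction must lie in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def _skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2


@dataclass
class LabeledVessels:
    """Labelled vessel objects of one kind plus their measurement records.

    ``labels`` is an integer grid (0 = background); ``records`` has one row
    per label with columns ``vessel_id, kind, area_px, area_um2,
    lumen_area_px`` (lumen only meaningful for arterioles).
    """

    labels: np.ndarray
    records: pd.DataFrame
    pixel_size_um: float

    @property
    def count(self) -> int:
        return len(self.records)

    def mask(self) -> np.ndarray:
        return self.labels > 0

    def mask_of(self, vessel_id: int) -> np.ndarray:
        return self.labels == vessel_id


def threshold_channel(channel: np.ndarray, method: object = "otsu",
                      value: float | None = None) -> np.ndarray:
    """Binarise an intensity channel: True where intensity exceeds the threshold.

    ``method`` is ``"otsu"``, ``"fixed"`` (requires ``value``) or directly a
    number.  A constant image under Otsu yields an all-False mask.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("channel is empty")
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        t = float(method)
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed threshold method requires a value")
        t = float(value)
    elif method == "otsu":
        if np.all(channel == channel.flat[0]):
            return np.zeros(channel.shape, dtype=bool)
        t = float(threshold_otsu(channel))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return channel > t


def find_complete_rings(
    sma_mask: np.ndarray, min_lumen_px: int = 1, connectivity: int = 8
) -> tuple[np.ndarray, pd.DataFrame]:
    """Identify which SMA connected components are complete rings.

    Returns the component label image and a frame with one row per
    component: ``label``, ``is_ring`` and ``lumen_px`` (pixels added by
    hole-filling, i.e. the enclosed lumen).  Components truncated by the
    image border enclose no hole on the open side and are not rings.
    """
    sma_mask = np.asarray(sma_mask, dtype=bool)
    conn = 1 if connectivity == 4 else 2
    labels = measure.label(sma_mask, connectivity=conn)
    rows = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, labels.max() + 1)):
        if sl is None:
            continue
        comp = labels[sl] == lab
        filled = ndimage.binary_fill_holes(comp)
        lumen_px = int(filled.sum() - comp.sum())
        rows.append({"label": lab, "is_ring": lumen_px >= min_lumen_px,
                     "lumen_px": lumen_px})
    frame = pd.DataFrame(rows, columns=["label", "is_ring", "lumen_px"])
    return labels, frame


def detect_arterioles(
    colIV_mask: np.ndarray,
    sma_mask: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
) -> LabeledVessels:
    """Classify arterioles: complete SMA rings co-positive for Collagen IV.

    A component qualifies if (a) it is a complete ring, (b) at least
    ``copositivity_fraction`` of its pixels are also Collagen-IV-positive
    and (c) its stained wall area (lumen excluded) is at least
    ``min_arteriole_area_px``.
    """
    colIV_mask = np.asarray(colIV_mask, dtype=bool)
    sma_mask = np.asarray(sma_mask, dtype=bool)
    if colIV_mask.shape != sma_mask.shape:
        raise ValueError(
            f"mask shapes differ: {colIV_mask.shape} vs {sma_mask.shape}"
        )
    comp_labels, rings = find_complete_rings(
        sma_mask, params.min_lumen_px, params.connectivity
    )
    out = np.zeros(colIV_mask.shape, dtype=np.int32)
    records = []
    next_id = 1
    for row in rings.itertuples(index=False):
        if not row.is_ring:
            continue
        comp = comp_labels == row.label
        area_px = int(comp.sum())
        if area_px < params.min_arteriole_area_px:
            continue
        overlap = np.count_nonzero(comp & colIV_mask)
        if overlap < params.copositivity_fraction * area_px:
            continue
        out[comp] = next_id
        records.append({
            "vessel_id": next_id,
            "kind": "arteriole",
            "area_px": area_px,
            "area_um2": px_to_um2(area_px, pixel_size_um),
            "lumen_area_px": int(row.lumen_px),
        })
        next_id += 1
    frame = pd.DataFrame(records, columns=VESSEL_RECORD_COLUMNS)
    return LabeledVessels(labels=out, records=frame, pixel_size_um=pixel_size_um)


def derive_capillaries(
    colIV_mask: np.ndarray,
    arterioles: LabeledVessels,
    params: SegmentationParams,
    pixel_size_um: float,
) -> LabeledVessels:
    """Carve capillaries from the Collagen IV mask.

    The arteriole wall mask is dilated by ``dilation_radius_px`` (disk
    element, to avoid edge effects) and subtracted from the comprehensive
    Collagen IV mask; remaining components of at least
    ``min_capillary_area_px`` pixels are capillaries.
    """
    colIV_mask = np.asarray(colIV_mask, dtype=bool)
    if colIV_mask.shape != arterioles.labels.shape:
        raise ValueError(
            f"mask shapes differ: {colIV_mask.shape} vs {arterioles.labels.shape}"
        )
    wall = arterioles.mask()
    if params.dilation_radius_px > 0 and wall.any():
        wall = morphology.dilation(
            wall, morphology.disk(params.dilation_radius_px)
        ).astype(bool)
    residual = colIV_mask & ~wall
    labels = measure.label(residual, connectivity=params._skimage_connectivity)
    out = np.zeros(colIV_mask.shape, dtype=np.int32)
    records = []
    next_id = 1
    for sl, lab in zip(ndimage.find_objects(labels), range(1, labels.max() + 1)):
        if sl is None:
            continue
        comp = labels[sl] == lab
        area_px = int(comp.sum())
        if area_px < params.min_capillary_area_px:
            continue
        out[sl][comp] = next_id
        records.append({
            "vessel_id": next_id,
            "kind": "capillary",
            "area_px": area_px,
            "area_um2": px_to_um2(area_px, pixel_size_um),
            "lumen_area_px": 0,
        })
        next_id += 1
    frame = pd.DataFrame(records, columns=VESSEL_RECORD_COLUMNS)
    return LabeledVessels(labels=out, records=frame, pixel_size_um=pixel_size_um)


def segment_vessels(
    projected_channels: dict[str, np.ndarray],
    params: SegmentationParams,
    pixel_size_um: float,
) -> tuple[LabeledVessels, LabeledVessels]:
    """Full vessel classification of one projected image.

    Thresholds the Collagen IV and SMA channels per ``params``, then runs
    arteriole detection followed by capillary derivation.
    """
    col_m = threshold_channel(
        projected_channels["collagen4"], params.threshold_method.get("collagen4", "otsu")
    )
    sma_m = threshold_channel(
        projected_channels["sma"], params.threshold_method.get("sma", "otsu")
    )
    arterioles = detect_arterioles(col_m, sma_m, params, pixel_size_um)
    capillaries = derive_capillaries(col_m, arterioles, params, pixel_size_um)
    return arterioles, capillaries
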