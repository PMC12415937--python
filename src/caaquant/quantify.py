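"""Study-level quantities: per-vessel amyloid coverage, per-aggregate size
and compartment, with the preprocessing rules applied before modelling.

Coverage is the percentage of the vessel wall occupied by amyloid
fluorescence.  Aggregates are assigned to the intramural compartment (inside
an arteriole wall) or the extramural compartment by strict-majority pixel
overlap.  Preprocessing: per-compartment size datasets drop extreme outliers
(more than 20x the next-largest value), and images in which no arteriole was
detected are excluded from arteriole-level analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import AggregateSet
from .segmentation import LabeledVessels

VESSEL_TABLE_COLUMNS = [
    "group", "mouse_id", "image_id", "vessel_id", "kind",
    "wall_area_px", "abeta_px", "coverage_pct",
]
AGGREGATE_TABLE_COLUMNS = [
    "group", "mouse_id", "image_id", "agg_id", "size_px", "compartment",
]


@dataclass
class StudyTable:
    """Long-format hierarchical records feeding the mixed models.

    ``vessels`` holds one row per vessel (coverage analysis), ``aggregates``
    one row per detected aggregate (size analysis).  ``exclusions`` logs
    images removed from arteriole-level analyses.
    """

    vessels: pd.DataFrame
    aggregates: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["image_id", "reason"])
    )

    def __post_init__(self) -> None:
        for frame in (self.vessels, self.aggregates):
            if len(frame) == 0:
                continue
            img_mouse = frame.groupby("image_id")["mouse_id"].nunique()
            if (img_mouse > 1).any():
                bad = img_mouse[img_mouse > 1].index.tolist()
                raise ValueError(f"image_id(s) {bad} map to multiple mouse_ids")
            mouse_grp = frame.groupby("mouse_id")["group"].nunique()
            if (mouse_grp > 1).any():
                bad = mouse_grp[mouse_grp > 1].index.tolist()
                raise ValueError(f"mouse_id(s) {bad} map to multiple groups")


def vessel_coverage(wall_mask: np.ndarray, abeta_mask: np.ndarray) -> float:
    """Percentage of the vessel wall covered by the amyloid mask."""
    wall_mask = np.asarray(wall_mask, dtype=bool)
    abeta_mask = np.asarray(abeta_mask, dtype=bool)
    if wall_mask.shape != abeta_mask.shape:
        raise ValueError(
            f"mask shapes differ: {wall_mask.shape} vs {abeta_mask.shape}"
        )
    wall_px = int(wall_mask.sum())
    if wall_px == 0:
        raise ValueError("empty vessel wall mask")
    overlap = int(np.count_nonzero(wall_mask & abeta_mask))
    return 100.0 * overlap / wall_px


def assign_compartment(
    aggregate_mask: np.ndarray,
    arteriole_wall_mask: np.ndarray,
    rule: str = "majority",
) -> str:
    """Assign an aggregate to the intramural or extramural compartment.

    ``majority``: intramural iff strictly more than half of the aggregate's
    pixels lie on the arteriole wall mask; ``any``: intramural iff any pixel
    does.
    """
    aggregate_mask = np.asarray(aggregate_mask, dtype=bool)
    arteriole_wall_mask = np.asarray(arteriole_wall_mask, dtype=bool)
    n = int(aggregate_mask.sum())
    if n == 0:
        raise ValueError("empty aggregate")
    on_wall = int(np.count_nonzero(aggregate_mask & arteriole_wall_mask))
    if rule == "majority":
        return "intramural" if on_wall > 0.5 * n else "extramural"
    if rule == "any":
        return "intramural" if on_wall > 0 else "extramural"
    raise ValueError(f"unknown compartment rule {rule!r}")


def remove_extreme_outliers(
    sizes, factor: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Drop values more than ``factor`` times the next-largest value.

    Applied iteratively: while the maximum strictly exceeds ``factor`` times
    the second-largest value, it is removed.  Returns ``(kept, removed)``;
    the removed values are kept for audit.  The rule is idempotent and the
    order of the kept values is preserved.
    """
    if not factor > 1:
        raise ValueError("factor must exceed 1")
    kept = list(np.asarray(sizes).ravel())
    removed: list = []
    while len(kept) >= 2:
        order = np.argsort(kept)
        largest, second = kept[order[-1]], kept[order[-2]]
        if largest > factor * second:
            removed.append(kept.pop(order[-1]))
        else:
            break
    return np.asarray(kept), np.asarray(removed)


def exclude_images_without_arterioles(table: StudyTable) -> StudyTable:
    """Exclude images with zero detected arterioles from arteriole analyses.

    Such images cannot support the arteriole-coverage analysis and would
    misclassify intramural deposits as extramural; their vessel rows of kind
    ``arteriole`` (none exist) and their aggregate rows are dropped, and the
    exclusion is logged.  Capillary rows are retained.
    """
    vessels = table.vessels
    aggregates = table.aggregates
    all_images = set(vessels["image_id"]) | set(aggregates["image_id"])
    with_art = set(
        vessels.loc[vessels["kind"] == "arteriole", "image_id"]
    )
    excluded = sorted(all_images - with_art)
    log = pd.DataFrame(
        {"image_id": excluded, "reason": "no arterioles detected"},
        columns=["image_id", "reason"],
    )
    if not excluded:
        return StudyTable(vessels=vessels, aggregates=aggregates,
                          exclusions=pd.concat([table.exclusions, log], ignore_index=True))
    keep_agg = ~aggregates["image_id"].isin(excluded)
    return StudyTable(
        vessels=vessels.copy(),
        aggregates=aggregates.loc[keep_agg].reset_index(drop=True),
        exclusions=pd.concat([table.exclusions, log], ignore_index=True),
    )


def measure_image(
    group: str,
    mouse_id: str,
    image_id: str,
    arterioles: LabeledVessels,
    capillaries: LabeledVessels,
    aggregates: AggregateSet,
    compartment_rule: str = "majority",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image measurement rows from segmentation and detection output.

    Returns ``(vessel_rows, aggregate_rows)``: coverage for every arteriole
    and capillary against the detected amyloid mask, and size plus
    compartment for every aggregate.
    """
    abeta_mask = aggregates.mask()
    wall_mask = arterioles.mask()
    v_rows = []
    for vessels in (arterioles, capillaries):
        for rec in vessels.records.itertuples(index=False):
            vm = vessels.mask_of(rec.vessel_id)
            wall_px = int(rec.area_px)
            overlap = int(np.count_nonzero(vm & abeta_mask))
            v_rows.append({
                "group": group, "mouse_id": mouse_id, "image_id": image_id,
                "vessel_id": f"{image_id}_{rec.kind[:3]}{rec.vessel_id}",
                "kind": rec.kind, "wall_area_px": wall_px, "abeta_px": overlap,
                "coverage_pct": 100.0 * overlap / wall_px,
            })
    a_rows = []
    for rec in aggregates.records.itertuples(index=False):
        am = aggregates.mask_of(rec.agg_id)
        comp = assign_compartment(am, wall_mask, rule=compartment_rule)
        a_rows.append({
            "group": group, "mouse_id": mouse_id, "image_id": image_id,
            "agg_id": f"{image_id}_a{rec.agg_id}", "size_px": int(rec.size_px),
            "compartment": comp,
        })
    return (
        pd.DataFrame(v_rows, columns=VESSEL_TABLE_COLUMNS),
        pd.DataFrame(a_rows, columns=AGGREGATE_TABLE_COLUMNS),
    )


def preprocess_study_table(
    table: StudyTable, outlier_factor: float = 20.0
) -> tuple[StudyTable, pd.DataFrame]:
    """Apply the preprocessing rules before statistical modelling.

    Excludes arteriole-free images, then removes extreme size outliers
    independently per compartment dataset.  Returns the cleaned table and an
    audit frame of removed aggregate sizes.
    """
    table = exclude_images_without_arterioles(table)
    agg = table.aggregates
    removed_rows = []
    kept_parts = []
    for comp, sub in agg.groupby("compartment", sort=False):
        _, removed = remove_extreme_outliers(sub["size_px"].to_numpy(), outlier_factor)
        drop_ids = []
        sizes_left = sub.copy()
        for val in removed:
            idx = sizes_left[sizes_left["size_px"] == val].index[0]
            drop_ids.append(idx)
            removed_rows.append({"compartment": comp, "size_px": int(val)})
            sizes_left = sizes_left.drop(index=idx)
        kept_parts.append(sizes_left)
    cleaned = (
        pd.concat(kept_parts).sort_index().reset_index(drop=True)
        if kept_parts else agg
    )
    audit = pd.DataFrame(removed_rows, columns=["compartment", "size_px"])
    return (
        StudyTable(vessels=table.vessels, aggregates=cleaned,
                   exclusions=table.exclusions),
        audit,
    )
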