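"""Longest-diameter morphometry and Day-0/Day-4 organoid tracking.

The growth readout is the per-organoid relative change in the longest
diameter between the pre-treatment (Day 0) and post-treatment (Day 4)
images:

    rel_change_pct = 100 * (d_day4 - d_day0) / d_day0

"Longest diameter" is the maximum Feret diameter of the segmented mask
(the manual line-tool measurement it replaces is a Feret measurement in
spirit), plus one pixel of pixel extent so a single pixel has diameter one
pixel rather than zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .imgproc import FieldImage, SegmentationResult


def longest_diameter(mask: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Maximum Feret diameter of a binary mask, in µm.

    Greatest distance between two boundary pixel centers, plus 1 px for
    pixel extent, times the pixel size.  Computed on the convex hull of the
    boundary pixels, which carries the same maximum as the full boundary.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no diameter")
    boundary = mask & ~ndi.binary_erosion(mask, border_value=0)
    pts = np.argwhere(boundary).astype(np.float64)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear / degenerate sets: brute force below
            pass
    feret_px = 0.0 if len(pts) == 1 else float(pdist(pts).max())
    return (feret_px + 1.0) * pixel_size_um


def relative_change(d0_um: float, d4_um: float) -> float:
    """Percent change in diameter between Day 0 and Day 4."""
    if d0_um <= 0:
        raise ValueError("d0_um must be > 0")
    return 100.0 * (d4_um - d0_um) / d0_um


def measure_field(seg: SegmentationResult, field: FieldImage) -> pd.DataFrame:
    """Per-label detections for one segmented field.

    Columns: label, day, arm, replicate, field_index, centroid_row_um,
    centroid_col_um, area_um2, diameter_um.
    """
    rows = []
    px = seg.pixel_size_um
    slices = ndi.find_objects(seg.label_image)
    for label in seg.labels:
        sl = slices[label - 1]
        mask = seg.label_image[sl] == label
        cr, cc = ndi.center_of_mass(mask)
        rows.append(
            {
                "label": int(label),
                "day": field.day,
                "line_id": field.line_id,
                "arm": field.arm,
                "replicate": field.replicate,
                "field_index": field.field_index,
                "centroid_row_um": (cr + sl[0].start) * px,
                "centroid_col_um": (cc + sl[1].start) * px,
                "area_um2": float(mask.sum()) * px**2,
                "diameter_um": longest_diameter(mask, px),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "day",
            "line_id",
            "arm",
            "replicate",
            "field_index",
            "centroid_row_um",
            "centroid_col_um",
            "area_um2",
            "diameter_um",
        ],
    )


def pair_organoids(
    day0: pd.DataFrame, day4: pd.DataFrame, max_shift_um: float = 150.0
) -> pd.DataFrame:
    """Match Day-0 and Day-4 detections by nearest centroid within a field.

    Organoids are embedded in gel on a gridded dish, so an organoid's Day-4
    position is its Day-0 position plus a small drift.  Matching is greedy
    on centroid distance (deterministic: sorted by distance, then labels),
    each detection used at most once, and only shifts up to
    ``max_shift_um`` are accepted.  Unmatched Day-0 detections become
    unpaired records (no Day-4-derived fields); unmatched Day-4 detections
    are dropped as new/unidentified objects.

    Input frames must describe the same (arm, replicate, field) universe.
    """
    key_cols = ["line_id", "arm", "replicate", "field_index"]
    k0 = set(map(tuple, day0[key_cols].drop_duplicates().itertuples(index=False)))
    k4 = set(map(tuple, day4[key_cols].drop_duplicates().itertuples(index=False)))
    extra = k4 - k0
    if extra:
        raise ValueError(f"Day-4 detections reference unknown fields: {sorted(extra)}")

    records = []
    for key, g0 in day0.groupby(key_cols, sort=True):
        g4 = day4
        for col, val in zip(key_cols, key):
            g4 = g4[g4[col] == val]
        g0 = g0.reset_index(drop=True)
        g4 = g4.reset_index(drop=True)
        cand = []
        for i in range(len(g0)):
            for j in range(len(g4)):
                d = float(
                    np.hypot(
                        g0.centroid_row_um[i] - g4.centroid_row_um[j],
                        g0.centroid_col_um[i] - g4.centroid_col_um[j],
                    )
                )
                if d <= max_shift_um:
                    cand.append((d, int(g0.label[i]), int(g4.label[j]), i, j))
        cand.sort(key=lambda t: (t[0], t[1], t[2]))
        used0: set[int] = set()
        used4: set[int] = set()
        matches: dict[int, tuple[int, float]] = {}
        for d, _, _, i, j in cand:
            if i in used0 or j in used4:
                continue
            used0.add(i)
            used4.add(j)
            matches[i] = (j, d)

        for i in range(len(g0)):
            base = {
                "organoid_id": "{}-{}-r{}-f{}-L{}".format(
                    key[0], key[1], key[2], key[3], int(g0.label[i])
                ),
                "line_id": key[0],
                "arm": key[1],
                "replicate": key[2],
                "field_index": key[3],
                "label_day0": int(g0.label[i]),
                "d0_um": float(g0.diameter_um[i]),
                "centroid0_row_um": float(g0.centroid_row_um[i]),
                "centroid0_col_um": float(g0.centroid_col_um[i]),
            }
            if i in matches:
                j, d = matches[i]
                base.update(
                    paired=True,
                    label_day4=int(g4.label[j]),
                    d4_um=float(g4.diameter_um[j]),
                    shift_um=d,
                    rel_change_pct=relative_change(
                        float(g0.diameter_um[i]), float(g4.diameter_um[j])
                    ),
                )
            else:
                base.update(
                    paired=False,
                    label_day4=pd.NA,
                    d4_um=np.nan,
                    shift_um=np.nan,
                    rel_change_pct=np.nan,
                )
            records.append(base)
    return pd.DataFrame(records)
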