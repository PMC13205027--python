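"""Optical redox ratio (ORR) per organoid and its change across days.

The ORR reports the cellular oxidation–reduction state through the
autofluorescence of two metabolic cofactors:

    ORR = I_NADPH / (I_NADPH + I_FAD)

with I the background-normalized channel intensity averaged over the
organoid's leading-edge band.  The per-organoid change across treatment,
ΔORR = ORR(Day 4) − ORR(Day 0), decreases when chemotherapy shifts the
organoid toward a more oxidized state, so a response shows up as negative
ΔORR relative to control.

Two aggregation choices are deliberate and documented: channel intensities
are *means* over the leading-edge mask (the conventional intensity
statistic), and the ORR is the ratio of those mask means rather than a
mean of per-pixel ratios, which is robust to per-pixel zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imgproc import FieldImage, SegmentationResult, background_normalize


def organoid_orr(
    nadph_norm: np.ndarray, fad_norm: np.ndarray, edge_mask: np.ndarray
) -> float:
    """ORR of one organoid from background-normalized channels.

    Returns NaN (an *undefined-ORR* record, not an exception) when both
    channel means are zero over the mask; callers count and exclude those.
    """
    edge_mask = np.asarray(edge_mask, dtype=bool)
    if not edge_mask.any():
        raise ValueError("edge mask is empty")
    i_n = float(np.mean(np.asarray(nadph_norm, dtype=np.float64)[edge_mask]))
    i_f = float(np.mean(np.asarray(fad_norm, dtype=np.float64)[edge_mask]))
    if i_n < 0 or i_f < 0:
        raise ValueError("normalized intensities must be >= 0")
    if i_n + i_f == 0:
        return float("nan")
    return i_n / (i_n + i_f)


def delta_orr(orr_day0: float, orr_day4: float) -> float:
    """Per-organoid change in ORR: Day 4 minus Day 0 (range [-1, 1]).

    The simple difference is used so that a treatment-induced decrease in
    ORR yields a negative ΔORR.  Normalizing to a control-arm baseline
    instead is possible downstream (the effect size is shift-invariant and
    unaffected by a common offset).
    """
    for v in (orr_day0, orr_day4):
        if not 0.0 <= v <= 1.0:
            raise ValueError("ORR values must lie in [0, 1]")
    return float(orr_day4) - float(orr_day0)


def measure_field_redox(
    seg: SegmentationResult,
    field: FieldImage,
    edge_width_px: int = 20,
    background_mode: str = "subtract",
) -> pd.DataFrame:
    """Leading-edge channel means and ORR for every label in one field.

    Both autofluorescence channels are background-normalized against the
    field's background region (to absorb day-to-day excitation/detection
    drift), then averaged over each organoid's leading-edge band.

    Columns: label, day, i_nadph, i_fad, orr, plus the recorded background
    levels (identical for all rows of a field).
    """
    nadph = background_normalize(field.nadph, seg.background_mask, mode=background_mode)
    fad = background_normalize(field.fad, seg.background_mask, mode=background_mode)
    rows = []
    slices = ndi.find_objects(seg.label_image)
    for label in seg.labels:
        # leading edge computed inside the label's bounding box (equivalent
        # to leading_edge_mask on the full field, but O(object) not O(field))
        sl = slices[label - 1]
        pad = tuple(
            slice(max(0, s.start - 1), min(n, s.stop + 1))
            for s, n in zip(sl, seg.label_image.shape)
        )
        mask = seg.label_image[pad] == label
        dist = ndi.distance_transform_edt(mask)
        edge = mask & (dist <= edge_width_px)
        i_n = float(np.mean(nadph.data[pad][edge]))
        i_f = float(np.mean(fad.data[pad][edge]))
        rows.append(
            {
                "label": int(label),
                "day": field.day,
                "i_nadph": i_n,
                "i_fad": i_f,
                "orr": (i_n / (i_n + i_f)) if (i_n + i_f) > 0 else np.nan,
                "background_nadph": nadph.background_level,
                "background_fad": fad.background_level,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "day",
            "i_nadph",
            "i_fad",
            "orr",
            "background_nadph",
            "background_fad",
        ],
    )
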