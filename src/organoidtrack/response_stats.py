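"""Arm summaries, the median-based Glass's delta, and comparator readouts.

The effect size at the heart of the analysis is a modified Glass's delta:

    mGΔ = (x̃_control − x̃_treatment) / σ_control

where x̃ is the *median* of the per-organoid measurement (relative change
in diameter, or ΔORR) pooled across technical replicates, and σ_control is
the control arm's sample standard deviation of the same measurement.  The
median resists the heavy skew of per-organoid growth distributions while
the control SD expresses the treatment shift in units of the line's
untreated variability; positive mGΔ means the treatment suppressed growth
(or redox) relative to control.  mGΔ is invariant to shifting all values
by a constant and to rescaling all values by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ArmSummary:
    """Median / SD summary of one arm's per-organoid values (one modality)."""

    line_id: str
    treatment_label: str
    modality: str  # "diameter" | "orr"
    n: int
    median: float
    sd: float
    values: tuple[float, ...]


@dataclass(frozen=True)
class EffectSize:
    """A modified Glass's delta tagged by line, treatment and modality."""

    line_id: str
    treatment_label: str
    modality: str
    mglass_delta: float
    n_control: int
    n_treatment: int


def summarize_arm(values, line_id: str = "", treatment_label: str = "", modality: str = "diameter") -> ArmSummary:
    """Summarize one arm: sample median and SD (n−1 denominator).

    Values are pooled across all technical replicates before summarizing;
    finite values only, and at least two are required for an SD.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError(
            f"arm {treatment_label!r} ({modality}): need >= 2 finite values, "
            f"got {arr.size}"
        )
    return ArmSummary(
        line_id=line_id,
        treatment_label=treatment_label,
        modality=modality,
        n=int(arr.size),
        median=float(np.median(arr)),
        sd=float(np.std(arr, ddof=1)),
        values=tuple(arr.tolist()),
    )


def mglass_delta(control: ArmSummary, treatment: ArmSummary) -> EffectSize:
    """Modified Glass's delta of a treatment arm against its control.

    (control median − treatment median) / control SD.  Undefined when the
    control arm has zero spread.
    """
    if control.line_id != treatment.line_id or control.modality != treatment.modality:
        raise ValueError("control and treatment must share line and modality")
    if control.sd <= 0:
        raise ValueError(
            f"control arm SD is {control.sd}; effect size undefined"
        )
    return EffectSize(
        line_id=control.line_id,
        treatment_label=treatment.treatment_label,
        modality=control.modality,
        mglass_delta=(control.median - treatment.median) / control.sd,
        n_control=control.n,
        n_treatment=treatment.n,
    )


def compare_arms(control_values, treatment_values, method: str = "mannwhitney") -> float:
    """Two-sided p-value comparing per-organoid values between two arms.

    Default is the Mann–Whitney rank-sum test (per-organoid growth and
    redox distributions are skewed); ``method='ttest'`` swaps in Welch's
    t-test.  Returns NaN when either arm has fewer than 3 finite values.
    """
    a = np.asarray(list(control_values), dtype=np.float64)
    b = np.asarray(list(treatment_values), dtype=np.float64)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        return float("nan")
    if method == "mannwhitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if method == "ttest":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class WellReadouts:
    """Whole-well comparator readouts for one treated arm."""

    ctg_ratio: float
    endpoint_median_d4_um: float


def well_level_readouts(
    treated_d4_um,
    treated_well_luminescence,
    control_well_luminescence,
) -> WellReadouts:
    """Well-level comparators: luminescence ratio and endpoint diameter.

    ``ctg_ratio`` is the mean treated-well luminescence over the mean
    control-well luminescence (the classic viability readout);
    ``endpoint_median_d4_um`` is the median Day-4 diameter with no Day-0
    reference.  Both discard per-organoid pairing, which is exactly why
    they lose power when baseline sizes vary widely.
    """
    t = np.asarray(list(treated_well_luminescence), dtype=np.float64)
    c = np.asarray(list(control_well_luminescence), dtype=np.float64)
    if t.size == 0 or c.size == 0 or c.mean() == 0:
        raise ValueError("need non-empty well luminescence for both arms")
    d4 = np.asarray(list(treated_d4_um), dtype=np.float64)
    d4 = d4[np.isfinite(d4)]
    if d4.size == 0:
        raise ValueError("need at least one Day-4 diameter")
    return WellReadouts(
        ctg_ratio=float(t.mean() / c.mean()),
        endpoint_median_d4_um=float(np.median(d4)),
    )
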