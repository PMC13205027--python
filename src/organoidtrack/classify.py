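"""Response classification, RECIST mapping, and concordance tables.

Effect sizes are converted to a predicted response category (sensitive /
intermediate / resistant) with cutoffs that depend on the treatment class:
chemotherapy regimens (5FU, oxaliplatin, SN38, FOLFOX, FOLFIRI) carry
larger effect sizes than radiation-containing regimens (XRT, 5FU+XRT), so
the two classes use different thresholds.  Predicted categories are then
cross-tabulated against the patient's clinical RECIST v1.1 category to
measure concordance.

Boundary inclusivity is preserved per threshold (the diameter chemo
cutoff "1.25 or higher" is inclusive; the ΔORR chemo cutoff ">1.5" is
exclusive) and serialized with results so a table can always be re-read
unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .response_stats import EffectSize

CATEGORIES = ("resistant", "intermediate", "sensitive")
_RANK = {c: i for i, c in enumerate(CATEGORIES)}

RECIST_CATEGORIES = ("CR", "PR", "SD", "PD")
RESPONSE_CATEGORIES = ("CR", "PR")  # "clinical response" = partial or complete

#: treatment label -> treatment class; configurable copy via dict(...)
TREATMENT_CLASSES: Mapping[str, str] = {
    "5FU": "chemo",
    "oxaliplatin": "chemo",
    "SN38": "chemo",
    "FOLFOX": "chemo",
    "FOLFIRI": "chemo",
    "XRT": "chemoRT",
    "5FU+XRT": "chemoRT",
}


def treatment_class(
    treatment_label: str, classes: Mapping[str, str] = TREATMENT_CLASSES
) -> str:
    """Map a treatment label to its threshold class."""
    try:
        return classes[treatment_label]
    except KeyError:
        raise KeyError(
            f"unknown treatment class for {treatment_label!r}; "
            f"known labels: {sorted(classes)}"
        ) from None


@dataclass(frozen=True)
class Cutoffs:
    """Sensitive/resistant cutoffs on the mGΔ scale, with inclusivity."""

    sensitive_cutoff: float
    resistant_cutoff: float
    sensitive_inclusive: bool = True
    resistant_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.sensitive_cutoff < self.resistant_cutoff:
            raise ValueError("sensitive_cutoff must be >= resistant_cutoff")

    def classify(self, mgd: float) -> str:
        if not np.isfinite(mgd):
            raise ValueError("effect size must be finite")
        sens = mgd >= self.sensitive_cutoff if self.sensitive_inclusive else mgd > self.sensitive_cutoff
        res = mgd <= self.resistant_cutoff if self.resistant_inclusive else mgd < self.resistant_cutoff
        if sens:
            return "sensitive"
        if res:
            return "resistant"
        return "intermediate"

    def to_dict(self) -> dict:
        return {
            "sensitive_cutoff": self.sensitive_cutoff,
            "resistant_cutoff": self.resistant_cutoff,
            "sensitive_inclusive": self.sensitive_inclusive,
            "resistant_inclusive": self.resistant_inclusive,
        }


@dataclass(frozen=True)
class ThresholdSet:
    """Cutoffs keyed by (modality, treatment_class)."""

    name: str
    cutoffs: Mapping[tuple[str, str], Cutoffs]

    def get(self, modality: str, tclass: str) -> Cutoffs:
        try:
            return self.cutoffs[(modality, tclass)]
        except KeyError:
            raise KeyError(
                f"no cutoffs for modality={modality!r}, class={tclass!r}; "
                f"known: {sorted(self.cutoffs)}"
            ) from None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cutoffs": {
                f"{m}/{t}": c.to_dict() for (m, t), c in sorted(self.cutoffs.items())
            },
        }


#: validated clinical-correlation cutoffs.  Diameter, chemo: sensitive at
#: 1.25 or higher, resistant at 0.75 or lower.  Diameter, chemoRT: sensitive
#: at 1 or higher, resistant at 0 or lower.  ΔORR cutoffs are exclusive:
#: chemo sensitive > 1.5 / resistant < 0; chemoRT sensitive > 1 / resistant < 0.
DEFAULT_THRESHOLDS = ThresholdSet(
    name="validated",
    cutoffs={
        ("diameter", "chemo"): Cutoffs(1.25, 0.75, True, True),
        ("diameter", "chemoRT"): Cutoffs(1.0, 0.0, True, True),
        ("orr", "chemo"): Cutoffs(1.5, 0.0, False, False),
        ("orr", "chemoRT"): Cutoffs(1.0, 0.0, False, False),
    },
)

#: alternative chemoRT diameter cutoffs (sensitive > 1, resistant < 0.5)
#: proposed when radiation thresholds were first explored; shipped as a
#: named preset so either convention can be reproduced.
NOVEL_XRT_THRESHOLDS = ThresholdSet(
    name="novel-xrt",
    cutoffs={
        ("diameter", "chemo"): Cutoffs(1.25, 0.75, True, True),
        ("diameter", "chemoRT"): Cutoffs(1.0, 0.5, False, False),
        ("orr", "chemo"): Cutoffs(1.5, 0.0, False, False),
        ("orr", "chemoRT"): Cutoffs(1.0, 0.0, False, False),
    },
)

THRESHOLD_PRESETS: Mapping[str, ThresholdSet] = {
    "validated": DEFAULT_THRESHOLDS,
    "novel-xrt": NOVEL_XRT_THRESHOLDS,
}


def classify_response(
    effect: EffectSize,
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
    classes: Mapping[str, str] = TREATMENT_CLASSES,
) -> str:
    """Predicted response category for one effect size.

    Monotone non-decreasing in mGΔ for fixed thresholds: a larger effect
    never yields a less sensitive category.
    """
    tclass = treatment_class(effect.treatment_label, classes)
    return thresholds.get(effect.modality, tclass).classify(effect.mglass_delta)


def combine_modalities(diam_category: str | None, orr_category: str | None) -> str:
    """Combine diameter and ΔORR categories: the more sensitive one wins.

    The redox readout can upgrade an intermediate diameter call (metabolic
    response precedes a size response), hence most-sensitive-wins; a
    missing modality defers to the other.  Commutative and idempotent.
    """
    cats = [c for c in (diam_category, orr_category) if c is not None]
    if not cats:
        raise ValueError("at least one modality category is required")
    for c in cats:
        if c not in _RANK:
            raise ValueError(f"unknown category {c!r}; known: {CATEGORIES}")
    return max(cats, key=_RANK.__getitem__)


def recist_category(sld_pre_mm: float, sld_post_mm: float) -> str:
    """RECIST v1.1 target-lesion category from pre/post SLD (mm).

    CR: disappearance (post = 0).  PR: ≥30% decrease.  PD: ≥20% increase
    AND ≥5 mm absolute increase.  SD otherwise.  Only the SLD rules are
    implemented (no non-target or new-lesion logic).
    """
    if sld_pre_mm <= 0:
        raise ValueError("sld_pre_mm must be > 0")
    if sld_post_mm < 0:
        raise ValueError("sld_post_mm must be >= 0")
    if sld_post_mm == 0:
        return "CR"
    change = (sld_post_mm - sld_pre_mm) / sld_pre_mm
    if change <= -0.30:
        return "PR"
    if change >= 0.20 and (sld_post_mm - sld_pre_mm) >= 5.0:
        return "PD"
    return "SD"


@dataclass
class ConcordanceTable:
    """Cross-tabulation of predicted vs clinical response categories.

    ``counts`` is a 3x4 frame (rows: sensitive/intermediate/resistant;
    columns: CR/PR/SD/PD); ``response_rate`` holds each predicted row's
    clinical response rate = fraction of subjects with PR or CR (NaN for
    empty rows), reported to 0.1%.
    """

    counts: pd.DataFrame
    response_rate: pd.Series

    @property
    def n_subjects(self) -> int:
        return int(self.counts.to_numpy().sum())


def concordance_table(
    predicted: Mapping[str, str], clinical: Mapping[str, str]
) -> ConcordanceTable:
    """Build the concordance table from per-subject categories.

    ``predicted`` maps subject id -> sensitive/intermediate/resistant;
    ``clinical`` maps subject id -> CR/PR/SD/PD.  Subject ids must match
    one-to-one.
    """
    missing = sorted(set(predicted) ^ set(clinical))
    if missing:
        raise ValueError(f"subject ids do not match 1:1; unmatched: {missing}")
    rows = ("sensitive", "intermediate", "resistant")
    counts = pd.DataFrame(
        0, index=pd.Index(rows, name="predicted"), columns=list(RECIST_CATEGORIES)
    )
    for sid, pred in predicted.items():
        clin = clinical[sid]
        if pred not in _RANK:
            raise ValueError(f"unknown predicted category {pred!r} for {sid!r}")
        if clin not in RECIST_CATEGORIES:
            raise ValueError(f"unknown clinical category {clin!r} for {sid!r}")
        counts.loc[pred, clin] += 1
    totals = counts.sum(axis=1)
    responders = counts[list(RESPONSE_CATEGORIES)].sum(axis=1)
    with np.errstate(invalid="ignore"):
        rate = (responders / totals).astype(float)
    rate = (rate * 1000).round() / 1000  # report to 0.1%
    rate[totals == 0] = np.nan
    return ConcordanceTable(counts=counts, response_rate=rate.rename("response_rate"))


def concordance_from_effects(
    effects: Iterable[EffectSize],
    clinical_sld: Mapping[str, tuple[float, float]],
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
) -> ConcordanceTable:
    """Concordance between effect-size predictions and SLD-derived RECIST.

    Subjects are identified as ``line_id/treatment_label``; effect sizes of
    both modalities for one subject are combined (most sensitive wins).
    """
    by_subject: dict[str, dict[str, str]] = {}
    for e in effects:
        sid = f"{e.line_id}/{e.treatment_label}"
        by_subject.setdefault(sid, {})[e.modality] = classify_response(e, thresholds)
    predicted = {
        sid: combine_modalities(cats.get("diameter"), cats.get("orr"))
        for sid, cats in by_subject.items()
    }
    clinical = {
        sid: recist_category(pre, post) for sid, (pre, post) in clinical_sld.items()
    }
    return concordance_table(predicted, clinical)
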