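"""End-to-end orchestration: simulate → segment → track → score → concord.

Two entry points:

* :func:`run_experiment` — in-memory pipeline over one cohort spec; renders
  fields, segments them, tracks organoids across days and returns measured
  per-organoid records plus arm summaries and effect sizes.  This is the
  workhorse for simulation studies and recovery experiments.
* :func:`run_pipeline` — the same stages as a reproducible on-disk run
  directory (TIFF images, stage CSVs, JSON report) driven by a serialized
  :class:`PipelineConfig`; each stage reads only documented files from the
  run directory, so stages are independently re-runnable from the CLI.

Determinism contract: identical (config, seed) reproduces byte-identical
CSV outputs; every output directory carries the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .classify import (
    THRESHOLD_PRESETS,
    classify_response,
    combine_modalities,
    concordance_table,
    recist_category,
)
from .imgproc import (
    FieldImage,
    SegmentationParams,
    read_field,
    segment_organoids,
)
from .morphometry import measure_field, pair_organoids
from .redox import measure_field_redox
from .response_stats import EffectSize, compare_arms, mglass_delta, summarize_arm
from .synthcohort import (
    ChannelParams,
    CohortSpec,
    LinkParams,
    cohort_to_frame,
    field_rng,
    generate_cohort,
    iter_field_groups,
    render_field,
    simulate_clinical_outcome,
    simulate_well_luminescence,
    write_cohort,
)

log = logging.getLogger("organoidtrack")

#: physical leading-edge band width emulated when converting to pixels
EDGE_BAND_UM = 20 * (3340.0 / 2044.0)  # 20 px at the full-frame pixel size


def edge_width_for(pixel_size_um: float) -> int:
    """Edge band width in pixels preserving the ~33 µm physical band."""
    return max(1, int(round(EDGE_BAND_UM / pixel_size_um)))


# ---------------------------------------------------------------------------
# in-memory experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    """Everything one simulated experiment produced."""

    spec: CohortSpec
    truth: pd.DataFrame
    records: pd.DataFrame  # measured per-organoid records
    effects: pd.DataFrame  # one row per (treatment, modality)
    effect_objs: list[EffectSize]
    wells: pd.DataFrame  # per-(arm, replicate) luminescence proxy


_MODALITY_COLUMNS = {"diameter": "rel_change_pct", "orr": "delta_orr"}


def compute_effects(
    records: pd.DataFrame, control_label: str = "control"
) -> tuple[pd.DataFrame, list[EffectSize]]:
    """Arm medians/SDs, effect sizes and rank-sum p-values from records.

    For each treated arm and each modality (relative change in diameter;
    ΔORR) the arm's per-organoid values are pooled across replicates,
    summarized (median, SD with n−1), compared to the control arm with the
    modified Glass's delta, and tested with a two-sided Mann–Whitney test.
    """
    rows, objs = [], []
    for line_id, grp in records.groupby("line_id", sort=True):
        arms = [a for a in grp["arm"].unique() if a != control_label]
        if control_label not in set(grp["arm"]):
            raise ValueError(f"line {line_id!r}: no arm labelled {control_label!r}")
        for modality, col in _MODALITY_COLUMNS.items():
            if col not in grp.columns:
                continue
            ctrl_vals = grp.loc[grp["arm"] == control_label, col].dropna()
            ctrl = summarize_arm(ctrl_vals, line_id, control_label, modality)
            for arm in sorted(arms):
                vals = grp.loc[grp["arm"] == arm, col].dropna()
                summ = summarize_arm(vals, line_id, arm, modality)
                eff = mglass_delta(ctrl, summ)
                objs.append(eff)
                rows.append(
                    {
                        "line_id": line_id,
                        "treatment": arm,
                        "modality": modality,
                        "n_control": ctrl.n,
                        "n_treatment": summ.n,
                        "median_control": ctrl.median,
                        "median_treatment": summ.median,
                        "sd_control": ctrl.sd,
                        "mglass_delta": eff.mglass_delta,
                        "p_value": compare_arms(ctrl.values, summ.values),
                    }
                )
    return pd.DataFrame(rows), objs


def _measure_both_days(
    spec: CohortSpec,
    cohort,
    channel_params: ChannelParams,
    seg_params: SegmentationParams,
    edge_width_px: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render, segment and measure every field of a cohort for both days."""
    dets: dict[int, list[pd.DataFrame]] = {0: [], 4: []}
    for arm, rep, fld, group in iter_field_groups(spec, cohort):
        for day in (0, 4):
            fi = render_field(
                group,
                day,
                channel_params,
                spec.field_size_px,
                spec.pixel_size_um,
                field_rng(spec, arm, rep, fld, day),
                field_index=fld,
                replicate=rep,
                arm=arm,
                line_id=spec.line_id,
            )
            seg = segment_organoids(fi, seg_params)
            if seg.n_labels == 0:
                continue
            det = measure_field(seg, fi)
            red = measure_field_redox(seg, fi, edge_width_px)
            dets[day].append(
                det.merge(red[["label", "i_nadph", "i_fad", "orr"]], on="label")
            )
    empty = pd.DataFrame(
        columns=[
            "label", "day", "line_id", "arm", "replicate", "field_index",
            "centroid_row_um", "centroid_col_um", "area_um2", "diameter_um",
            "i_nadph", "i_fad", "orr",
        ]
    )
    day0 = pd.concat(dets[0], ignore_index=True) if dets[0] else empty.copy()
    day4 = pd.concat(dets[4], ignore_index=True) if dets[4] else empty.copy()
    return day0, day4


def _merge_redox(records: pd.DataFrame, day0: pd.DataFrame, day4: pd.DataFrame) -> pd.DataFrame:
    """Attach per-day ORR to paired records and derive ΔORR."""
    key = ["line_id", "arm", "replicate", "field_index"]
    r = records.merge(
        day0[key + ["label", "orr"]].rename(columns={"label": "label_day0", "orr": "orr0"}),
        on=key + ["label_day0"],
        how="left",
    )
    d4 = day4[key + ["label", "orr"]].rename(columns={"label": "label_day4", "orr": "orr4"})
    r["label_day4"] = r["label_day4"].astype("Int64")
    d4["label_day4"] = d4["label_day4"].astype("Int64")
    r = r.merge(d4, on=key + ["label_day4"], how="left")
    r["delta_orr"] = r["orr4"] - r["orr0"]
    n_undef = int(((r["orr0"].isna() | r["orr4"].isna()) & r["paired"]).sum())
    if n_undef:
        log.info("records with undefined ORR excluded from ΔORR: %d", n_undef)
    return r


def run_experiment(
    spec: CohortSpec,
    channel_params: ChannelParams | None = None,
    seg_params: SegmentationParams | None = None,
    edge_width_px: int | None = None,
    max_shift_um: float = 150.0,
    control_label: str = "control",
    ctg_noise_cv: float = 0.05,
) -> ExperimentResult:
    """Run the full imaging pipeline in memory for one cohort spec."""
    channel_params = channel_params or ChannelParams()
    seg_params = seg_params or SegmentationParams()
    if edge_width_px is None:
        edge_width_px = edge_width_for(spec.pixel_size_um)

    cohort = generate_cohort(spec)
    day0, day4 = _measure_both_days(spec, cohort, channel_params, seg_params, edge_width_px)
    records = pair_organoids(day0, day4, max_shift_um)
    records = _merge_redox(records, day0, day4)
    log.info(
        "line %s: detected d0=%d d4=%d, paired=%d",
        spec.line_id, len(day0), len(day4), int(records["paired"].sum()),
    )

    well_rows = []
    by_well: dict[tuple[str, int], list] = {}
    for o in cohort:
        by_well.setdefault((o.arm, o.replicate), []).append(o)
    for i, ((arm, rep), orgs) in enumerate(sorted(by_well.items())):
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 3, i]))
        well_rows.append(
            {
                "line_id": spec.line_id,
                "arm": arm,
                "replicate": rep,
                "luminescence": simulate_well_luminescence(orgs, ctg_noise_cv, rng),
            }
        )
    effects, objs = compute_effects(records, control_label)
    return ExperimentResult(
        spec=spec,
        truth=cohort_to_frame(cohort),
        records=records,
        effects=effects,
        effect_objs=objs,
        wells=pd.DataFrame(well_rows),
    )


def true_effects(truth: pd.DataFrame, control_label: str = "control") -> pd.DataFrame:
    """Ground-truth effect sizes straight from the generator's table."""
    renamed = truth.rename(
        columns={"true_rel_change_pct": "rel_change_pct", "true_delta_orr": "delta_orr"}
    )
    eff, _ = compute_effects(renamed, control_label)
    return eff


# ---------------------------------------------------------------------------
# on-disk pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Reproducible description of one pipeline run."""

    cohorts: list[CohortSpec]
    channel_params: ChannelParams = dc_field(default_factory=ChannelParams)
    seg_params: SegmentationParams = dc_field(default_factory=SegmentationParams)
    clinical_link: LinkParams = dc_field(default_factory=LinkParams)
    edge_width_px: int | None = None
    max_shift_um: float = 150.0
    threshold_preset: str = "validated"
    control_label: str = "control"
    ctg_noise_cv: float = 0.05
    out_dir: str = "runs/demo"
    seed: int | None = None  # overrides each cohort's own seed when set
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "cohorts": [c.to_dict() for c in self.cohorts],
            "channel_params": dataclasses.asdict(self.channel_params),
            "seg_params": dataclasses.asdict(self.seg_params),
            "clinical_link": dataclasses.asdict(self.clinical_link),
            "edge_width_px": self.edge_width_px,
            "max_shift_um": self.max_shift_um,
            "threshold_preset": self.threshold_preset,
            "control_label": self.control_label,
            "ctg_noise_cv": self.ctg_noise_cv,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            cohorts=[CohortSpec.from_dict(c) for c in d["cohorts"]],
            channel_params=ChannelParams(**d.get("channel_params", {})),
            seg_params=SegmentationParams(**d.get("seg_params", {})),
            clinical_link=LinkParams(**d.get("clinical_link", {})),
            edge_width_px=d.get("edge_width_px"),
            max_shift_um=float(d.get("max_shift_um", 150.0)),
            threshold_preset=d.get("threshold_preset", "validated"),
            control_label=d.get("control_label", "control"),
            ctg_noise_cv=float(d.get("ctg_noise_cv", 0.05)),
            out_dir=d.get("out_dir", "runs/demo"),
            seed=d.get("seed"),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def effective_cohorts(self) -> list[CohortSpec]:
        if self.seed is None:
            return list(self.cohorts)
        return [replace(c, seed=int(self.seed) + i) for i, c in enumerate(self.cohorts)]


def _write_meta(config: PipelineConfig, run_dir: Path) -> None:
    (run_dir / "run_meta.json").write_text(
        json.dumps(
            {"config_hash": config.config_hash(), "seed": config.seed}, indent=2
        )
    )
    config.to_json(run_dir / "config.json")


def simulate_stage(config: PipelineConfig, run_dir: Path) -> None:
    """Render and write all cohorts; derive wells and simulated clinic data."""
    truth_frames, well_rows, clin_rows = [], [], []
    for spec in config.effective_cohorts():
        log.info("simulate: line %s (%d arms)", spec.line_id, len(spec.arms))
        cohort = generate_cohort(spec)
        write_cohort(spec, cohort, run_dir, config.channel_params)
        truth_frames.append(cohort_to_frame(cohort))
        by_well: dict[tuple[str, int], list] = {}
        for o in cohort:
            by_well.setdefault((o.arm, o.replicate), []).append(o)
        for i, ((arm, rep), orgs) in enumerate(sorted(by_well.items())):
            rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 3, i]))
            well_rows.append(
                {
                    "line_id": spec.line_id,
                    "arm": arm,
                    "replicate": rep,
                    "luminescence": simulate_well_luminescence(
                        orgs, config.ctg_noise_cv, rng
                    ),
                }
            )
        # clinical outcomes driven by the true diameter effect of each arm
        eff = true_effects(truth_frames[-1], config.control_label)
        diam = eff[eff["modality"] == "diameter"]
        for j, row in enumerate(diam.itertuples()):
            rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 4, j]))
            pre, post = simulate_clinical_outcome(
                row.mglass_delta, config.clinical_link, rng
            )
            clin_rows.append(
                {
                    "subject_id": f"{spec.line_id}/{row.treatment}",
                    "sld_pre_mm": pre,
                    "sld_post_mm": post,
                }
            )
    pd.concat(truth_frames, ignore_index=True).to_csv(
        run_dir / "ground_truth.csv", index=False
    )
    pd.DataFrame(well_rows).to_csv(run_dir / "wells.csv", index=False)
    pd.DataFrame(clin_rows).to_csv(run_dir / "clinical.csv", index=False)


def segment_stage(config: PipelineConfig, run_dir: Path) -> None:
    """Segment every written field; write label TIFFs and detections.csv."""
    img_dir = run_dir / "images"
    lbl_dir = run_dir / "labels"
    lbl_dir.mkdir(exist_ok=True)
    dets = []
    for tif in sorted(img_dir.glob("*.tif")):
        fi = read_field(tif)
        seg = segment_organoids(fi, config.seg_params)
        tifffile.imwrite(
            lbl_dir / tif.name,
            seg.label_image.astype(np.uint16),
            photometric="minisblack",
        )
        if seg.n_labels == 0:
            continue
        ew = config.edge_width_px or edge_width_for(fi.pixel_size_um)
        det = measure_field(seg, fi)
        red = measure_field_redox(seg, fi, ew)
        dets.append(det.merge(red[["label", "i_nadph", "i_fad", "orr"]], on="label"))
    if not dets:
        raise RuntimeError("segment: no organoids detected in any field")
    pd.concat(dets, ignore_index=True).to_csv(run_dir / "detections.csv", index=False)
    log.info("segment: %d detections", sum(len(d) for d in dets))


def measure_stage(config: PipelineConfig, run_dir: Path) -> None:
    """Pair Day-0/Day-4 detections; write the per-organoid records CSV."""
    det = pd.read_csv(run_dir / "detections.csv")
    day0 = det[det["day"] == 0].reset_index(drop=True)
    day4 = det[det["day"] == 4].reset_index(drop=True)
    records = pair_organoids(day0, day4, config.max_shift_um)
    records.to_csv(run_dir / "organoids.csv", index=False)
    log.info(
        "measure: %d records, %d paired", len(records), int(records["paired"].sum())
    )


def redox_stage(config: PipelineConfig, run_dir: Path) -> None:
    """Attach per-day ORR and ΔORR to the per-organoid records CSV."""
    det = pd.read_csv(run_dir / "detections.csv")
    records = pd.read_csv(run_dir / "organoids.csv")
    records = records.drop(
        columns=[c for c in ("orr0", "orr4", "delta_orr") if c in records], errors="ignore"
    )
    day0 = det[det["day"] == 0].reset_index(drop=True)
    day4 = det[det["day"] == 4].reset_index(drop=True)
    records = _merge_redox(records, day0, day4)
    records.to_csv(run_dir / "organoids.csv", index=False)


def score_stage(config: PipelineConfig, run_dir: Path) -> None:
    """Effect sizes and p-values per (line, treatment, modality)."""
    records = pd.read_csv(run_dir / "organoids.csv")
    effects, _ = compute_effects(records, config.control_label)
    effects.to_csv(run_dir / "effects.csv", index=False)
    log.info("score: %d effect sizes", len(effects))


def classify_stage(config: PipelineConfig, run_dir: Path) -> None:
    """Predicted response category per subject (both modalities combined)."""
    thresholds = THRESHOLD_PRESETS[config.threshold_preset]
    effects = pd.read_csv(run_dir / "effects.csv")
    rows = []
    for (line_id, treatment), grp in effects.groupby(["line_id", "treatment"]):
        cats: dict[str, str] = {}
        for row in grp.itertuples():
            eff = EffectSize(
                line_id=line_id,
                treatment_label=treatment,
                modality=row.modality,
                mglass_delta=row.mglass_delta,
                n_control=row.n_control,
                n_treatment=row.n_treatment,
            )
            cats[row.modality] = classify_response(eff, thresholds)
        rows.append(
            {
                "subject_id": f"{line_id}/{treatment}",
                "line_id": line_id,
                "treatment": treatment,
                "diameter_category": cats.get("diameter"),
                "orr_category": cats.get("orr"),
                "combined_category": combine_modalities(
                    cats.get("diameter"), cats.get("orr")
                ),
                "threshold_preset": thresholds.name,
            }
        )
    pd.DataFrame(rows).to_csv(run_dir / "categories.csv", index=False)


def concord_stage(config: PipelineConfig, run_dir: Path) -> None:
    """Cross-tabulate predicted categories against simulated RECIST calls."""
    cats = pd.read_csv(run_dir / "categories.csv")
    clin = pd.read_csv(run_dir / "clinical.csv")
    clinical = {
        r.subject_id: recist_category(r.sld_pre_mm, r.sld_post_mm)
        for r in clin.itertuples()
    }
    predicted = {r.subject_id: r.combined_category for r in cats.itertuples()}
    table = concordance_table(predicted, clinical)
    out = table.counts.copy()
    out["response_rate"] = table.response_rate
    out.to_csv(run_dir / "concordance.csv")
    report = {
        "n_subjects": table.n_subjects,
        "counts": {r: table.counts.loc[r].to_dict() for r in table.counts.index},
        "response_rate": {
            k: (None if pd.isna(v) else float(v))
            for k, v in table.response_rate.items()
        },
        "threshold_preset": config.threshold_preset,
        "config_hash": config.config_hash(),
    }
    (run_dir / "report.json").write_text(json.dumps(report, indent=2))


_STAGES = (
    ("simulate", simulate_stage),
    ("segment", segment_stage),
    ("measure", measure_stage),
    ("redox", redox_stage),
    ("score", score_stage),
    ("classify", classify_stage),
    ("concord", concord_stage),
)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage into the configured run directory.

    Fails fast on an unknown threshold preset; a stage failure aborts with
    the stage name while earlier outputs are preserved on disk.
    """
    if config.threshold_preset not in THRESHOLD_PRESETS:
        raise ValueError(
            f"unknown threshold preset {config.threshold_preset!r}; "
            f"known: {sorted(THRESHOLD_PRESETS)}"
        )
    logging.basicConfig(level=config.log_level)
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _write_meta(config, run_dir)
    for name, stage in _STAGES:
        try:
            stage(config, run_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    write_report(run_dir)
    return run_dir


def write_report(run_dir: str | Path) -> Path:
    """Human-readable run summary (medians, effect sizes, concordance)."""
    run_dir = Path(run_dir)
    lines = ["organoidtrack run report", "=" * 40]
    meta_path = run_dir / "run_meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        lines.append(f"config hash: {meta['config_hash']}   seed: {meta['seed']}")
    eff_path = run_dir / "effects.csv"
    if eff_path.exists():
        effects = pd.read_csv(eff_path)
        lines.append("")
        lines.append("effect sizes (median-based Glass's delta vs control):")
        for r in effects.itertuples():
            lines.append(
                f"  {r.line_id:>8s} {r.treatment:>8s} {r.modality:>8s}: "
                f"median {r.median_treatment:8.3f} vs control {r.median_control:8.3f} "
                f"(SD {r.sd_control:7.3f})  mGΔ = {r.mglass_delta:5.2f}  p = {r.p_value:.3g}"
            )
    cat_path = run_dir / "categories.csv"
    if cat_path.exists():
        cats = pd.read_csv(cat_path)
        lines.append("")
        lines.append("predicted response categories:")
        for r in cats.itertuples():
            lines.append(
                f"  {r.subject_id:>20s}: diameter={r.diameter_category} "
                f"orr={r.orr_category} combined={r.combined_category}"
            )
    conc_path = run_dir / "concordance.csv"
    if conc_path.exists():
        lines.append("")
        lines.append("concordance with simulated RECIST categories:")
        lines.append(pd.read_csv(conc_path).to_string(index=False))
    text = "\n".join(lines) + "\n"
    out = run_dir / "report.txt"
    out.write_text(text)
    return out
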