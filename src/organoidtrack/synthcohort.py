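"""Synthetic organoid cohorts with rendered two-timepoint phantom fields.

The generator emulates the geometry of a gridded-dish widefield experiment:
organoids embedded in gel, imaged on Day 0, treated, and re-imaged on Day 4
in the same positions (plus small jitter).  Each arm's biology is described
by sampling laws for baseline diameter, percent growth, baseline optical
redox ratio (ORR) and its change (ΔORR), so the true per-arm medians and
effect sizes are known exactly and every downstream stage can be validated
against ground truth.

Placement uses one organoid per grid cell, which both mimics the gridded
dish and guarantees that no two organoid masks overlap in a rendered field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .imgproc import FieldImage, write_field
from .laws import Law

#: full-frame geometry of the widefield system being emulated:
#: 3.34 mm x 3.34 mm fields at 2044 x 2048 px (1.634 um/px)
FULL_FIELD = {
    "field_size_px": (2044, 2048),
    "pixel_size_um": 3340.0 / 2044.0,
    "grid_pitch_px": 384,
}

#: coarser, smaller fields with the same organoid biology; used for fast
#: tests and large simulated cohorts (geometry is a parameter, not a constant)
REDUCED_FIELD = {
    "field_size_px": (768, 768),
    "pixel_size_um": 4.0,
    "grid_pitch_px": 192,
}


class PlacementError(ValueError):
    """Raised when an arm's organoids cannot be placed without overlap."""


@dataclass(frozen=True)
class ArmSpec:
    """Generative description of one treatment arm.

    Laws are stated on the scales the statistics summarise: growth as the
    true percent change in diameter, redox as Day-0 ORR and per-organoid
    ΔORR.  ``viability_factor`` scales the arm's well-luminescence proxy.
    """

    treatment_label: str
    n_organoids: int
    d0_diameter_law: Law = dc_field(default_factory=lambda: Law.lognormal(200.0, 0.15))
    growth_pct_law: Law = dc_field(default_factory=lambda: Law.normal(64.0, 56.6))
    orr0_law: Law = dc_field(default_factory=lambda: Law.normal(0.60, 0.05))
    delta_orr_law: Law = dc_field(default_factory=lambda: Law.normal(0.046, 0.0426))
    viability_factor: float = 1.0
    attrition: float = 0.0  # probability an organoid is absent on Day 4
    #: lower truncation of sampled growth (%).  −95 guarantees a positive
    #: Day-4 diameter; a higher floor (e.g. −75) models the fact that an
    #: organoid shrunk far below baseline has disintegrated beyond
    #: measurability while leaving every arm median untouched (the floor
    #: sits far below all of them).
    growth_floor_pct: float = -95.0

    def __post_init__(self) -> None:
        if self.n_organoids < 1:
            raise ValueError("n_organoids must be >= 1")
        if not -95.0 <= self.growth_floor_pct < 0.0:
            raise ValueError("growth_floor_pct must lie in [-95, 0)")
        if not 0.0 <= self.viability_factor <= 1.0:
            raise ValueError("viability_factor must be in [0, 1]")
        if not 0.0 <= self.attrition < 1.0:
            raise ValueError("attrition must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "treatment_label": self.treatment_label,
            "n_organoids": self.n_organoids,
            "d0_diameter_law": self.d0_diameter_law.to_dict(),
            "growth_pct_law": self.growth_pct_law.to_dict(),
            "orr0_law": self.orr0_law.to_dict(),
            "delta_orr_law": self.delta_orr_law.to_dict(),
            "viability_factor": self.viability_factor,
            "attrition": self.attrition,
            "growth_floor_pct": self.growth_floor_pct,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArmSpec":
        return cls(
            treatment_label=d["treatment_label"],
            n_organoids=int(d["n_organoids"]),
            d0_diameter_law=Law.from_dict(d["d0_diameter_law"]),
            growth_pct_law=Law.from_dict(d["growth_pct_law"]),
            orr0_law=Law.from_dict(d["orr0_law"]),
            delta_orr_law=Law.from_dict(d["delta_orr_law"]),
            viability_factor=float(d.get("viability_factor", 1.0)),
            attrition=float(d.get("attrition", 0.0)),
            growth_floor_pct=float(d.get("growth_floor_pct", -95.0)),
        )


@dataclass(frozen=True)
class CohortSpec:
    """One organoid line's simulated experiment.

    Defaults mirror the emulated acquisition: five fields of view per
    technical replicate, three replicates per arm, full-frame geometry.
    The same (spec, seed) always reproduces bit-identical cohorts/images.
    """

    line_id: str
    arms: tuple[ArmSpec, ...]
    fields_per_replicate: int = 5
    replicates: int = 3
    field_size_px: tuple[int, int] = (2044, 2048)
    pixel_size_um: float = 3340.0 / 2044.0
    grid_pitch_px: int = 384
    day4_jitter_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("arms must be non-empty")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.fields_per_replicate < 1 or self.replicates < 1:
            raise ValueError("fields_per_replicate and replicates must be >= 1")
        object.__setattr__(self, "arms", tuple(self.arms))
        object.__setattr__(self, "field_size_px", tuple(self.field_size_px))

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (
            self.field_size_px[0] // self.grid_pitch_px,
            self.field_size_px[1] // self.grid_pitch_px,
        )

    @property
    def cells_per_field(self) -> int:
        r, c = self.grid_shape
        return r * c

    def to_dict(self) -> dict:
        return {
            "line_id": self.line_id,
            "arms": [a.to_dict() for a in self.arms],
            "fields_per_replicate": self.fields_per_replicate,
            "replicates": self.replicates,
            "field_size_px": list(self.field_size_px),
            "pixel_size_um": self.pixel_size_um,
            "grid_pitch_px": self.grid_pitch_px,
            "day4_jitter_um": self.day4_jitter_um,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(
            line_id=d["line_id"],
            arms=tuple(ArmSpec.from_dict(a) for a in d["arms"]),
            fields_per_replicate=int(d.get("fields_per_replicate", 5)),
            replicates=int(d.get("replicates", 3)),
            field_size_px=tuple(d.get("field_size_px", (2044, 2048))),
            pixel_size_um=float(d.get("pixel_size_um", 3340.0 / 2044.0)),
            grid_pitch_px=int(d.get("grid_pitch_px", 384)),
            day4_jitter_um=float(d.get("day4_jitter_um", 5.0)),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class GroundTruthOrganoid:
    """True state of one simulated organoid across both imaging days."""

    organoid_id: str
    line_id: str
    arm: str
    replicate: int
    field_index: int
    grid_cell: tuple[int, int]
    center0_rc: tuple[float, float]  # (row, col) px on Day 0
    center4_rc: tuple[float, float]
    d0_um: float
    d4_um: float
    orr0: float
    orr4: float
    present_day4: bool = True
    angle_rad: float = 0.0
    aspect: float = 1.0  # minor/major axis ratio
    viability_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.d0_um <= 0:
            raise ValueError("d0_um must be > 0")
        if self.present_day4 and self.d4_um <= 0:
            raise ValueError("d4_um must be > 0 when present on Day 4")
        for v in (self.orr0, self.orr4):
            if not 0.0 < v < 1.0:
                raise ValueError("ORR values must lie in (0, 1)")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_MARGIN_PX = 4  # clearance between an organoid mask and its grid cell border


def _arm_rng(spec: CohortSpec, arm_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 1000 + arm_index])
    )


def generate_cohort(spec: CohortSpec) -> list[GroundTruthOrganoid]:
    """Sample a full ground-truth cohort for one line.

    Each arm gets exactly ``n_organoids`` organoids, spread round-robin
    over replicates, fields and grid cells.  Growth is truncated below at
    the arm's ``growth_floor_pct`` (at most −95%, so a collapsed organoid
    still has positive size) and above so the Day-4 mask stays inside its
    grid cell; under the default laws the upper truncation touches only a
    negligible far tail.
    """
    n_rows, n_cols = spec.grid_shape
    if n_rows < 1 or n_cols < 1:
        raise PlacementError(
            f"field {spec.field_size_px} too small for grid pitch "
            f"{spec.grid_pitch_px}"
        )
    capacity = spec.replicates * spec.fields_per_replicate * spec.cells_per_field
    pitch_um = spec.grid_pitch_px * spec.pixel_size_um
    d_cap_um = pitch_um - 2 * _MARGIN_PX * spec.pixel_size_um

    out: list[GroundTruthOrganoid] = []
    for ai, arm in enumerate(spec.arms):
        if arm.n_organoids > capacity:
            raise PlacementError(
                f"arm {arm.treatment_label!r}: {arm.n_organoids} organoids exceed "
                f"capacity {capacity} ({spec.replicates} replicates x "
                f"{spec.fields_per_replicate} fields x {spec.cells_per_field} cells)"
            )
        rng = _arm_rng(spec, ai)
        n = arm.n_organoids
        d0 = arm.d0_diameter_law.sample(rng, n)
        if np.any(d0 <= 0):
            raise ValueError(f"arm {arm.treatment_label!r}: non-positive d0 sampled")
        if np.any(d0 > d_cap_um):
            raise PlacementError(
                f"arm {arm.treatment_label!r}: baseline diameter "
                f"{d0.max():.0f} um exceeds grid cell capacity {d_cap_um:.0f} um"
            )
        growth = arm.growth_pct_law.sample(rng, n)
        growth = np.maximum(growth, arm.growth_floor_pct)
        g_cap = (d_cap_um / d0 - 1.0) * 100.0
        growth = np.minimum(growth, g_cap)
        d4 = d0 * (1.0 + growth / 100.0)
        orr0 = np.clip(arm.orr0_law.sample(rng, n), 0.01, 0.99)
        orr4 = np.clip(orr0 + arm.delta_orr_law.sample(rng, n), 0.01, 0.99)
        present = rng.random(n) >= arm.attrition
        angle = rng.uniform(0.0, np.pi, n)
        aspect = rng.uniform(0.75, 1.0, n)

        for i in range(n):
            rep = i % spec.replicates
            fld = (i // spec.replicates) % spec.fields_per_replicate
            cell = i // (spec.replicates * spec.fields_per_replicate)
            cell_rc = (cell // n_cols, cell % n_cols)
            d_max_px = max(d0[i], d4[i]) / spec.pixel_size_um
            half = d_max_px / 2.0 + _MARGIN_PX
            lo_r = cell_rc[0] * spec.grid_pitch_px + half
            hi_r = (cell_rc[0] + 1) * spec.grid_pitch_px - half
            lo_c = cell_rc[1] * spec.grid_pitch_px + half
            hi_c = (cell_rc[1] + 1) * spec.grid_pitch_px - half
            r0 = rng.uniform(lo_r, max(lo_r, hi_r))
            c0 = rng.uniform(lo_c, max(lo_c, hi_c))
            jit = spec.day4_jitter_um / spec.pixel_size_um
            r4 = float(np.clip(r0 + rng.normal(0.0, jit), lo_r, max(lo_r, hi_r)))
            c4 = float(np.clip(c0 + rng.normal(0.0, jit), lo_c, max(lo_c, hi_c)))
            out.append(
                GroundTruthOrganoid(
                    organoid_id=f"{spec.line_id}-{arm.treatment_label}-{i:04d}",
                    line_id=spec.line_id,
                    arm=arm.treatment_label,
                    replicate=rep,
                    field_index=fld,
                    grid_cell=cell_rc,
                    center0_rc=(float(r0), float(c0)),
                    center4_rc=(r4, c4),
                    d0_um=float(d0[i]),
                    d4_um=float(d4[i]),
                    orr0=float(orr0[i]),
                    orr4=float(orr4[i]),
                    present_day4=bool(present[i]),
                    angle_rad=float(angle[i]),
                    aspect=float(aspect[i]),
                    viability_factor=arm.viability_factor,
                )
            )
    return out


def cohort_to_frame(organoids: Sequence[GroundTruthOrganoid]) -> pd.DataFrame:
    """Ground-truth table, one row per organoid (synthetic stand-in data)."""
    rows = []
    for o in organoids:
        rows.append(
            {
                "organoid_id": o.organoid_id,
                "line_id": o.line_id,
                "arm": o.arm,
                "replicate": o.replicate,
                "field_index": o.field_index,
                "grid_row": o.grid_cell[0],
                "grid_col": o.grid_cell[1],
                "center0_row_px": o.center0_rc[0],
                "center0_col_px": o.center0_rc[1],
                "center4_row_px": o.center4_rc[0],
                "center4_col_px": o.center4_rc[1],
                "d0_um": o.d0_um,
                "d4_um": o.d4_um,
                "true_rel_change_pct": 100.0 * (o.d4_um - o.d0_um) / o.d0_um,
                "orr0": o.orr0,
                "orr4": o.orr4,
                "true_delta_orr": o.orr4 - o.orr0,
                "present_day4": o.present_day4,
                "viability_factor": o.viability_factor,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelParams:
    """Rendering model for the three channels (intensities in a.u.).

    Brightfield organoids are dark-rimmed ellipses on a bright background;
    the rim band (``rim_width_px``) lies just inside the true boundary so
    the outer edge of the rendered object coincides with the true diameter.
    Fluorescence channels share a rim-concentrated radial profile whose
    NAD(P)H:FAD amplitude split encodes the organoid's true ORR, so the
    background-subtracted intensity ratio recovers it exactly.
    """

    bf_background: float = 3000.0
    bf_interior: float = 2400.0
    bf_rim: float = 1200.0
    rim_width_px: float = 4.0
    fluor_background: float = 400.0
    fluor_amplitude: float = 2000.0
    profile_base: float = 0.35  # interior floor of the radial profile
    profile_rim_frac: float = 0.15  # rim band width as fraction of radius
    noise_sd_bf: float = 20.0
    noise_sd_fluor: float = 20.0

    def noise_free(self) -> "ChannelParams":
        return replace(self, noise_sd_bf=0.0, noise_sd_fluor=0.0)


def _ellipse_rho(
    shape: tuple[int, int],
    center_rc: tuple[float, float],
    d_px: float,
    angle: float,
    aspect: float,
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Normalized elliptical radius (1.0 at the boundary) on a bounding box."""
    a = d_px / 2.0  # semi-major
    b = a * aspect
    half = int(math.ceil(a)) + 2
    r0 = max(0, int(math.floor(center_rc[0])) - half)
    r1 = min(shape[0], int(math.ceil(center_rc[0])) + half + 1)
    c0 = max(0, int(math.floor(center_rc[1])) - half)
    c1 = min(shape[1], int(math.ceil(center_rc[1])) + half + 1)
    rr, cc = np.meshgrid(
        np.arange(r0, r1, dtype=np.float64) - center_rc[0],
        np.arange(c0, c1, dtype=np.float64) - center_rc[1],
        indexing="ij",
    )
    ca, sa = math.cos(angle), math.sin(angle)
    u = rr * ca + cc * sa
    v = -rr * sa + cc * ca
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return (slice(r0, r1), slice(c0, c1)), rho


def _organoid_day_state(
    o: GroundTruthOrganoid, day: int
) -> tuple[tuple[float, float], float, float]:
    if day == 0:
        return o.center0_rc, o.d0_um, o.orr0
    if day == 4:
        return o.center4_rc, o.d4_um, o.orr4
    raise ValueError("day must be 0 or 4")


def render_field(
    organoids: Sequence[GroundTruthOrganoid],
    day: int,
    params: ChannelParams,
    field_size_px: tuple[int, int],
    pixel_size_um: float,
    rng: np.random.Generator,
    field_index: int = 0,
    replicate: int = 0,
    arm: str = "",
    line_id: str = "",
) -> FieldImage:
    """Render one multi-channel field for the given day.

    Organoids absent on Day 4 are simply not drawn.  Organoids whose mask
    would extend beyond the field are clipped and flagged in provenance.
    """
    shape = tuple(field_size_px)
    bf = np.full(shape, params.bf_background, dtype=np.float64)
    nadph = np.full(shape, params.fluor_background, dtype=np.float64)
    fad = np.full(shape, params.fluor_background, dtype=np.float64)
    clipped: list[str] = []

    for o in organoids:
        if day == 4 and not o.present_day4:
            continue
        center, d_um, orr = _organoid_day_state(o, day)
        d_px = d_um / pixel_size_um
        a = d_px / 2.0
        if (
            center[0] - a < 0
            or center[1] - a < 0
            or center[0] + a > shape[0]
            or center[1] + a > shape[1]
        ):
            clipped.append(o.organoid_id)
        box, rho = _ellipse_rho(shape, center, d_px, o.angle_rad, o.aspect)
        inside = rho <= 1.0
        if not inside.any():
            continue
        # brightfield: dark rim just inside the boundary, dimmed interior
        rim_frac = params.rim_width_px / a
        rim = inside & (rho >= 1.0 - rim_frac)
        sub = bf[box]
        sub[inside] = params.bf_interior
        sub[rim] = params.bf_rim
        # fluorescence: shared rim-concentrated profile, split by ORR
        prof = np.zeros_like(rho)
        prof[inside] = params.profile_base + (1.0 - params.profile_base) * np.exp(
            -(((1.0 - rho[inside]) / params.profile_rim_frac) ** 2)
        )
        nadph[box] += params.fluor_amplitude * orr * prof
        fad[box] += params.fluor_amplitude * (1.0 - orr) * prof

    if params.noise_sd_bf > 0:
        bf += rng.normal(0.0, params.noise_sd_bf, shape)
    if params.noise_sd_fluor > 0:
        nadph += rng.normal(0.0, params.noise_sd_fluor, shape)
        fad += rng.normal(0.0, params.noise_sd_fluor, shape)

    to_u16 = lambda x: np.clip(np.rint(x), 0, 65535).astype(np.uint16)
    return FieldImage(
        bf=to_u16(bf),
        nadph=to_u16(nadph),
        fad=to_u16(fad),
        pixel_size_um=pixel_size_um,
        day=day,
        field_index=field_index,
        replicate=replicate,
        arm=arm,
        line_id=line_id,
        provenance={"clipped_organoids": clipped, "synthetic": True},
    )


def truth_label_image(
    organoids: Sequence[GroundTruthOrganoid],
    day: int,
    field_size_px: tuple[int, int],
    pixel_size_um: float,
) -> np.ndarray:
    """Ground-truth label image (label i+1 = organoids[i]) for one day."""
    out = np.zeros(tuple(field_size_px), dtype=np.int32)
    for i, o in enumerate(organoids):
        if day == 4 and not o.present_day4:
            continue
        center, d_um, _ = _organoid_day_state(o, day)
        box, rho = _ellipse_rho(out.shape, center, d_um / pixel_size_um, o.angle_rad, o.aspect)
        out[box][rho <= 1.0] = i + 1
    return out


def iter_field_groups(
    spec: CohortSpec, organoids: Sequence[GroundTruthOrganoid]
) -> list[tuple[str, int, int, list[GroundTruthOrganoid]]]:
    """Group a cohort by (arm, replicate, field_index), deterministically."""
    groups: dict[tuple[str, int, int], list[GroundTruthOrganoid]] = {}
    for o in organoids:
        groups.setdefault((o.arm, o.replicate, o.field_index), []).append(o)
    arm_order = {a.treatment_label: i for i, a in enumerate(spec.arms)}
    keys = sorted(groups, key=lambda k: (arm_order[k[0]], k[1], k[2]))
    return [(k[0], k[1], k[2], groups[k]) for k in keys]


def field_rng(spec: CohortSpec, arm: str, replicate: int, field_index: int, day: int) -> np.random.Generator:
    """Deterministic per-(field, day) noise stream derived from the master seed."""
    arm_index = next(i for i, a in enumerate(spec.arms) if a.treatment_label == arm)
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 2, arm_index, replicate, field_index, day])
    )


# ---------------------------------------------------------------------------
# well-level and clinical simulators
# ---------------------------------------------------------------------------

def simulate_well_luminescence(
    organoids: Sequence[GroundTruthOrganoid],
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
    scale: float = 1.0,
    noise_floor: float = 0.0,
) -> float:
    """ATP-proportional luminescence proxy for one well.

    Luminescence is modelled as proportional to total viable cell mass:
    ``scale * sum(d4^3 * viability_factor)`` with multiplicative noise of
    coefficient of variation ``noise_cv``.  Monotone non-decreasing in every
    diameter.  An empty well returns the noise floor alone.
    """
    rng = rng or np.random.default_rng(0)
    total = sum(
        (o.d4_um**3) * o.viability_factor for o in organoids if o.present_day4
    )
    eps = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
    return float(scale * total * (1.0 + eps) + noise_floor)


@dataclass(frozen=True)
class LinkParams:
    """Linear link from a true effect size to a simulated clinical SLD change.

    ``pct_change = intercept_pct − slope_pct_per_unit * effect + noise``,
    clipped to [−100, +200].  The default slope maps an effect of 1.25 (the
    chemotherapy diameter sensitivity cutoff) to a −31% SLD change, just
    inside the RECIST partial-response boundary.
    """

    sld_pre_mm: float = 100.0
    intercept_pct: float = 0.0
    slope_pct_per_unit: float = 24.8
    noise_sd_pct: float = 10.0


def simulate_clinical_outcome(
    true_effect: float,
    link: LinkParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Simulate a patient's (pre, post) sum-of-longest-diameters in mm.

    The expected percent SLD change decreases monotonically with the true
    effect size, so stronger ex vivo responses map to deeper radiographic
    responses.  Output feeds :func:`organoidtrack.classify.recist_category`.
    """
    link = link or LinkParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.normal(0.0, link.noise_sd_pct) if link.noise_sd_pct > 0 else 0.0
    pct = link.intercept_pct - link.slope_pct_per_unit * float(true_effect) + noise
    pct = float(np.clip(pct, -100.0, 200.0))
    sld_post = max(0.0, link.sld_pre_mm * (1.0 + pct / 100.0))
    return float(link.sld_pre_mm), sld_post


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------

def write_cohort(
    spec: CohortSpec,
    organoids: Sequence[GroundTruthOrganoid],
    out_dir: str | Path,
    params: ChannelParams | None = None,
) -> Path:
    """Render and write every field (both days) plus the ground-truth CSV."""
    params = params or ChannelParams()
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for arm, rep, fld, group in iter_field_groups(spec, organoids):
        for day in (0, 4):
            fi = render_field(
                group,
                day,
                params,
                spec.field_size_px,
                spec.pixel_size_um,
                field_rng(spec, arm, rep, fld, day),
                field_index=fld,
                replicate=rep,
                arm=arm,
                line_id=spec.line_id,
            )
            write_field(fi, img_dir / f"{spec.line_id}_{arm}_r{rep}_f{fld}_d{day}.tif")
    cohort_to_frame(organoids).to_csv(out_dir / "ground_truth.csv", index=False)
    return out_dir
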