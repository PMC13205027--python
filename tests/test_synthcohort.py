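"""Generator invariants: determinism, median fidelity, rendering truth."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from organoidtrack.laws import Law
from organoidtrack.synthcohort import (
    ArmSpec,
    ChannelParams,
    CohortSpec,
    GroundTruthOrganoid,
    LinkParams,
    PlacementError,
    cohort_to_frame,
    field_rng,
    generate_cohort,
    render_field,
    simulate_clinical_outcome,
    simulate_well_luminescence,
    truth_label_image,
)

from conftest import small_cohort_spec


def _tabular_spec(arms, seed=0):
    """Large-capacity geometry for statistics-only cohorts (not rendered)."""
    return CohortSpec(
        line_id="TAB",
        arms=arms,
        fields_per_replicate=30,
        replicates=3,
        field_size_px=(2044, 2048),
        pixel_size_um=3340.0 / 2044.0,
        grid_pitch_px=384,
        seed=seed,
    )


class TestGenerateCohort:
    def test_same_seed_is_bit_identical(self, cohort_spec):
        t1 = cohort_to_frame(generate_cohort(cohort_spec))
        t2 = cohort_to_frame(generate_cohort(cohort_spec))
        pdt.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self, cohort_spec):
        other = CohortSpec.from_dict({**cohort_spec.to_dict(), "seed": 999})
        t1 = cohort_to_frame(generate_cohort(cohort_spec))
        t2 = cohort_to_frame(generate_cohort(other))
        assert not t1["d0_um"].equals(t2["d0_um"])

    def test_arm_counts_exact(self, cohort_spec):
        truth = cohort_to_frame(generate_cohort(cohort_spec))
        counts = truth.groupby("arm").size()
        for arm in cohort_spec.arms:
            assert counts[arm.treatment_label] == arm.n_organoids

    def test_identical_growth_laws_give_matching_medians(self):
        law = Law.normal(30.0, 40.0)
        arms = (
            ArmSpec("a", 500, growth_pct_law=law),
            ArmSpec("b", 500, growth_pct_law=law),
        )
        truth = cohort_to_frame(generate_cohort(_tabular_spec(arms, seed=3)))
        med = truth.groupby("arm")["true_rel_change_pct"].median()
        # order-statistic SE of the median: 1.253 * 40 / sqrt(500) = 2.24
        assert abs(med["a"] - med["b"]) < 3 * np.sqrt(2) * 1.253 * 40.0 / np.sqrt(500)

    def test_median_fidelity_of_growth_law(self):
        arms = (ArmSpec("control", 1000, growth_pct_law=Law.normal(64.0, 56.6)),)
        truth = cohort_to_frame(generate_cohort(_tabular_spec(arms, seed=11)))
        assert truth["true_rel_change_pct"].median() == pytest.approx(64.0, abs=5.0)

    def test_capacity_error_names_arm(self):
        arms = (ArmSpec("crowded", 10_000),)
        with pytest.raises(PlacementError, match="crowded"):
            generate_cohort(small_cohort_spec(arms=arms))

    def test_masks_never_overlap(self, cohort_spec):
        cohort = generate_cohort(cohort_spec)
        group = [
            o for o in cohort if (o.arm, o.replicate, o.field_index) == ("control", 0, 0)
        ]
        assert len(group) > 1
        for day in (0, 4):
            total = np.zeros(cohort_spec.field_size_px, dtype=int)
            for i, o in enumerate(group):
                single = truth_label_image(
                    [o], day, cohort_spec.field_size_px, cohort_spec.pixel_size_um
                )
                total += (single > 0).astype(int)
            assert total.max() == 1

    def test_orr_values_in_open_unit_interval(self, cohort_spec):
        truth = cohort_to_frame(generate_cohort(cohort_spec))
        for col in ("orr0", "orr4"):
            assert ((truth[col] > 0) & (truth[col] < 1)).all()


class TestRenderField:
    def test_orr_reconstruction_noise_free(self, noise_free_channels):
        org = GroundTruthOrganoid(
            organoid_id="x", line_id="L", arm="a", replicate=0, field_index=0,
            grid_cell=(0, 0), center0_rc=(128.0, 128.0), center4_rc=(128.0, 128.0),
            d0_um=300.0, d4_um=300.0, orr0=0.5, orr4=0.5, angle_rad=0.3, aspect=0.9,
        )
        fi = render_field(
            [org], 0, noise_free_channels, (256, 256), 4.0,
            np.random.default_rng(0),
        )
        inside = truth_label_image([org], 0, (256, 256), 4.0) > 0
        bg = noise_free_channels.fluor_background
        i_n = fi.nadph.astype(float)[inside].mean() - bg
        i_f = fi.fad.astype(float)[inside].mean() - bg
        assert i_n == pytest.approx(i_f, rel=0.01)

    def test_empty_field_is_background_only(self, noise_free_channels):
        fi = render_field(
            [], 0, noise_free_channels, (128, 128), 4.0, np.random.default_rng(0)
        )
        assert np.all(fi.bf == noise_free_channels.bf_background)
        assert np.all(fi.nadph == noise_free_channels.fluor_background)

    def test_rendered_disk_extent_matches_diameter(self):
        # 300 um disk at 1.634 um/px spans 183.6 px -> mask extent 183-184
        px = 3340.0 / 2044.0
        org = GroundTruthOrganoid(
            organoid_id="x", line_id="L", arm="a", replicate=0, field_index=0,
            grid_cell=(0, 0), center0_rc=(128.0, 128.0), center4_rc=(128.0, 128.0),
            d0_um=300.0, d4_um=300.0, orr0=0.5, orr4=0.5, angle_rad=0.0, aspect=1.0,
        )
        mask = truth_label_image([org], 0, (256, 256), px) > 0
        cols = np.where(mask.any(axis=0))[0]
        extent = cols.max() - cols.min() + 1
        assert extent in (183, 184)

    def test_render_deterministic_given_rng_seed(self, cohort_spec):
        cohort = generate_cohort(cohort_spec)
        group = [o for o in cohort if (o.arm, o.replicate, o.field_index) == ("control", 0, 0)]
        kw = dict(
            day=0, params=ChannelParams(),
            field_size_px=cohort_spec.field_size_px,
            pixel_size_um=cohort_spec.pixel_size_um,
        )
        f1 = render_field(group, rng=field_rng(cohort_spec, "control", 0, 0, 0), **kw)
        f2 = render_field(group, rng=field_rng(cohort_spec, "control", 0, 0, 0), **kw)
        assert np.array_equal(f1.bf, f2.bf)
        assert np.array_equal(f1.nadph, f2.nadph)


def _mk_org(d4, viability=1.0, present=True):
    return GroundTruthOrganoid(
        organoid_id=f"o{d4}", line_id="L", arm="a", replicate=0, field_index=0,
        grid_cell=(0, 0), center0_rc=(0, 0), center4_rc=(0, 0),
        d0_um=d4, d4_um=d4, orr0=0.5, orr4=0.5,
        present_day4=present, viability_factor=viability,
    )


class TestWellLuminescence:
    def test_cubic_scaling(self):
        small = [_mk_org(d) for d in (100, 200, 300)]
        big = [_mk_org(2 * d) for d in (100, 200, 300)]
        assert simulate_well_luminescence(big) == pytest.approx(
            8 * simulate_well_luminescence(small)
        )

    def test_viability_linearity(self):
        full = [_mk_org(150.0, viability=1.0) for _ in range(4)]
        half = [_mk_org(150.0, viability=0.5) for _ in range(4)]
        assert simulate_well_luminescence(full) == pytest.approx(
            2.0 * simulate_well_luminescence(half)
        )

    def test_hand_computed_value(self):
        orgs = [_mk_org(d) for d in (100, 200, 300)]
        assert simulate_well_luminescence(orgs) == pytest.approx(3.6e7)

    def test_empty_well_is_noise_floor(self):
        assert simulate_well_luminescence([], noise_floor=5.0) == pytest.approx(5.0)


class TestClinicalOutcome:
    def test_calibrated_effect_gives_31pct_reduction(self):
        link = LinkParams(sld_pre_mm=100.0, slope_pct_per_unit=31.0, noise_sd_pct=0.0)
        pre, post = simulate_clinical_outcome(1.0, link)
        assert post == pytest.approx(0.69 * pre)

    def test_zero_effect_zero_noise_is_unchanged(self):
        link = LinkParams(noise_sd_pct=0.0)
        pre, post = simulate_clinical_outcome(0.0, link)
        assert post == pytest.approx(pre)

    def test_deterministic_under_seed(self):
        link = LinkParams(noise_sd_pct=8.0)
        assert simulate_clinical_outcome(1.0, link, seed=42) == simulate_clinical_outcome(
            1.0, link, seed=42
        )

    def test_monotone_decreasing_in_effect(self):
        link = LinkParams(noise_sd_pct=0.0)
        posts = [simulate_clinical_outcome(e, link)[1] for e in (-1, 0, 1, 2)]
        assert posts == sorted(posts, reverse=True)
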