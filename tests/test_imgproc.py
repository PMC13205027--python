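"""Segmentation, leading-edge extraction and background normalization."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from organoidtrack.imgproc import (
    FieldImage,
    SegmentationParams,
    background_normalize,
    leading_edge_mask,
    segment_organoids,
)
from organoidtrack.synthcohort import generate_cohort, render_field, truth_label_image

from conftest import small_cohort_spec


def _field_from_bf(bf, pixel_size_um=4.0):
    z = np.zeros_like(bf)
    return FieldImage(bf=bf, nadph=z, fad=z, pixel_size_um=pixel_size_um, day=0)


def _rendered_noise_free(n=7, seed=5, channels=None):
    """Noise-free phantom at the native imaging resolution (1.634 µm/px)."""
    from organoidtrack.laws import Law
    from organoidtrack.synthcohort import ArmSpec, ChannelParams, CohortSpec

    spec = CohortSpec(
        line_id="FID",
        arms=(
            ArmSpec(
                "control", n,
                d0_diameter_law=Law.lognormal(350.0, 0.10),
                growth_pct_law=Law.normal(20.0, 15.0),
            ),
        ),
        fields_per_replicate=1,
        replicates=1,
        field_size_px=(1024, 1024),
        pixel_size_um=3340.0 / 2044.0,
        grid_pitch_px=341,
        seed=seed,
    )
    group = generate_cohort(spec)
    channels = channels or ChannelParams().noise_free()
    fi = render_field(
        group, 0, channels, spec.field_size_px, spec.pixel_size_um,
        np.random.default_rng(0),
    )
    truth = truth_label_image(group, 0, spec.field_size_px, spec.pixel_size_um)
    return fi, truth, group


def _jaccard(a, b):
    return np.logical_and(a, b).sum() / np.logical_or(a, b).sum()


class TestSegmentOrganoids:
    def test_recovers_all_objects_with_high_jaccard(self, seg_params):
        fi, truth, group = _rendered_noise_free()
        seg = segment_organoids(fi, seg_params)
        n_true = int(truth.max())
        assert seg.n_labels == n_true
        for t in range(1, n_true + 1):
            tmask = truth == t
            overlap = np.bincount(
                seg.label_image[tmask].ravel(), minlength=seg.n_labels + 1
            )
            best = int(np.argmax(overlap[1:])) + 1
            assert _jaccard(tmask, seg.label_image == best) >= 0.95

    def test_blank_field_yields_zero_labels(self, rng):
        bf = rng.normal(3000.0, 20.0, (512, 512)).astype(np.uint16)
        seg = segment_organoids(_field_from_bf(bf))
        assert seg.n_labels == 0
        assert seg.background_mask.all()

    def test_constant_field_yields_zero_labels(self):
        bf = np.full((256, 256), 3000, dtype=np.uint16)
        assert segment_organoids(_field_from_bf(bf)).n_labels == 0

    def test_tangent_disks_are_split(self):
        bf = np.full((300, 300), 3000.0)
        yy, xx = np.indices(bf.shape)
        r = 40
        for cy, cx in ((150, 110), (150, 190)):  # borders touch at (150, 150)
            bf[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 1500.0
        seg = segment_organoids(_field_from_bf(bf.astype(np.uint16)))
        assert seg.n_labels == 2

    def test_intensity_scale_invariance(self, seg_params):
        fi, _, _ = _rendered_noise_free()
        seg1 = segment_organoids(fi, seg_params)
        scaled = FieldImage(
            bf=(fi.bf.astype(np.float64) * 3.7), nadph=fi.nadph, fad=fi.fad,
            pixel_size_um=fi.pixel_size_um, day=fi.day,
        )
        seg2 = segment_organoids(scaled, seg_params)
        assert np.array_equal(seg1.label_image, seg2.label_image)

    def test_min_area_removes_small_objects(self):
        bf = np.full((256, 256), 3000.0)
        yy, xx = np.indices(bf.shape)
        bf[(yy - 60) ** 2 + (xx - 60) ** 2 <= 30**2] = 1500.0  # big: keeps
        bf[(yy - 180) ** 2 + (xx - 180) ** 2 <= 3**2] = 1500.0  # tiny: removed
        seg = segment_organoids(
            _field_from_bf(bf.astype(np.uint16)),
            SegmentationParams(min_area_um2=2000.0),
        )
        assert seg.n_labels == 1


class TestLeadingEdgeMask:
    @staticmethod
    def _disk_labels(radius, shape=(160, 160)):
        yy, xx = np.indices(shape)
        mask = (yy - 80) ** 2 + (xx - 80) ** 2 <= radius**2
        return mask.astype(np.int32)

    def test_thin_object_returns_full_label(self):
        labels = self._disk_labels(15)
        edge = leading_edge_mask(labels, 1, width_px=20)
        assert np.array_equal(edge, labels == 1)

    def test_annulus_area_fraction(self):
        labels = self._disk_labels(50)
        edge = leading_edge_mask(labels, 1, width_px=20)
        frac = edge.sum() / (labels == 1).sum()
        assert frac == pytest.approx(1 - (30 / 50) ** 2, abs=0.03)

    def test_unknown_label_raises_with_label_name(self):
        labels = self._disk_labels(10)
        with pytest.raises(KeyError, match="99"):
            leading_edge_mask(labels, 99)

    def test_edge_subset_and_depth_bound(self, seg_params):
        fi, _, _ = _rendered_noise_free()
        seg = segment_organoids(fi, seg_params)
        for label in seg.labels[:3]:
            edge = leading_edge_mask(seg.label_image, int(label), width_px=8)
            lab_mask = seg.label_image == label
            assert np.all(lab_mask[edge])
            dist = ndi.distance_transform_edt(lab_mask)
            assert dist[edge].max() <= 8.0


class TestBackgroundNormalize:
    def test_constant_channel_goes_to_zero(self):
        ch = np.full((64, 64), 400.0)
        out = background_normalize(ch, np.ones_like(ch, dtype=bool))
        assert np.all(out.data == 0)
        assert out.background_level == 400.0

    def test_plateau_recovered_after_shift(self):
        ch = np.full((64, 64), 400.0)
        ch[20:40, 20:40] += 900.0
        bg = np.ones_like(ch, dtype=bool)
        bg[15:45, 15:45] = False
        out = background_normalize(ch, bg)
        assert out.data[30, 30] == pytest.approx(900.0)

    def test_background_level_estimate_under_noise(self, rng):
        ch = rng.normal(400.0, 20.0, (200, 200))
        out = background_normalize(ch, np.ones_like(ch, dtype=bool))
        # median SE = 1.253 * 20 / sqrt(4e4) = 0.125; 2 a.u. is > 10 SE
        assert out.background_level == pytest.approx(400.0, abs=2.0)

    def test_small_background_region_raises(self):
        ch = np.full((16, 16), 400.0)
        bg = np.zeros_like(ch, dtype=bool)
        bg[0, :10] = True
        with pytest.raises(ValueError, match="background region too small"):
            background_normalize(ch, bg)

    def test_idempotent_on_noise_free_output(self):
        ch = np.full((64, 64), 400.0)
        ch[20:40, 20:40] += 900.0
        bg = np.ones_like(ch, dtype=bool)
        bg[15:45, 15:45] = False
        once = background_normalize(ch, bg)
        twice = background_normalize(once.data, bg)
        assert np.array_equal(once.data, twice.data)

    def test_divide_mode(self):
        ch = np.full((64, 64), 800.0)
        out = background_normalize(ch, np.ones_like(ch, dtype=bool), mode="divide")
        assert np.all(out.data == 1.0)
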