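"""Renderer, cohort, and analytic-backend contracts."""

import numpy as np
import pytest
from scipy import stats
from skimage.color import rgb2hed

from oracles import flood_fill_components

from deltamarch.synthetic_tissue import (
    GradeAnchors,
    LabeledPatch,
    ParameterClipWarning,
    SceneParams,
    SceneTooCrowdedError,
    analytic_backend,
    make_cohort,
    render_scene,
)


def _params(**kw):
    base = dict(
        grade=2.0, n_tumor_nuclei=5, n_other_nuclei=3, tumor_radius_mean=6.0,
        other_radius_mean=3.0, nucleoli_per_tumor_nucleus=1.5, vasc_density=0.06,
        patch_size=96, seed=0,
    )
    base.update(kw)
    return SceneParams(**base)


class TestRenderScene:
    def test_empty_scene_is_pure_background(self):
        p = _params(n_tumor_nuclei=0, n_other_nuclei=0, vasc_density=0.0)
        patch = render_scene(p)
        assert patch.nuclei_mask.sum() == 0
        assert patch.vasc_mask.sum() == 0
        # constant background color everywhere
        assert np.ptp(patch.image.reshape(-1, 3), axis=0).max() < 1e-12

    def test_determinism_bit_identical(self):
        a = render_scene(_params(seed=42))
        b = render_scene(_params(seed=42))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.nuclei_mask, b.nuclei_mask)
        assert np.array_equal(a.vasc_mask, b.vasc_mask)

    def test_component_count_and_areas_radius8(self):
        p = _params(n_tumor_nuclei=5, n_other_nuclei=0, tumor_radius_mean=8.0,
                    vasc_density=0.0, seed=3)
        patch = render_scene(p)
        comps = flood_fill_components(patch.nuclei_mask == 2)
        assert len(comps) == 5
        target = np.pi * 8**2
        for pix in comps:
            assert abs(len(pix) - target) / target < 0.15

    def test_masks_share_dimensions_and_vessel_fraction(self):
        patch = render_scene(_params(vasc_density=0.08, seed=9))
        assert patch.image.shape[:2] == patch.nuclei_mask.shape == patch.vasc_mask.shape
        frac = patch.vasc_mask.mean()
        assert abs(frac - 0.08) / 0.08 < 0.2

    def test_nuclei_hematoxylin_dominant(self):
        patch = render_scene(_params(seed=5))
        h = rgb2hed(patch.image)[..., 0]
        bg_median = np.median(h[patch.nuclei_mask == 0])
        assert (h[patch.nuclei_mask > 0] > bg_median).all()

    def test_nucleoli_inside_nuclei(self):
        p = _params(n_tumor_nuclei=3, tumor_radius_mean=8.0, exact_nucleoli=2, seed=7)
        patch = render_scene(p)
        assert sum(patch.meta["planted_nucleoli_tumor"]) > 0

    def test_too_crowded_raises_informative_error(self):
        p = _params(n_tumor_nuclei=60, tumor_radius_mean=10.0)
        with pytest.raises(SceneTooCrowdedError, match="place nucleus"):
            render_scene(p)

    def test_minimum_patch_size(self):
        with pytest.raises(ValueError, match="patch_size"):
            render_scene(_params(patch_size=16))


class TestGradeAnchors:
    def test_monotone_mappings(self):
        a = GradeAnchors()
        gs = np.linspace(1, 4, 13)
        tr = [a.tumor_radius_at(g) for g in gs]
        vd = [a.vasc_density_at(g) for g in gs]
        nr = [a.nucleoli_rate_at(g) for g in gs]
        assert all(x < y for x, y in zip(tr, tr[1:]))
        assert all(x >= y for x, y in zip(vd, vd[1:]))
        assert all(x <= y for x, y in zip(nr, nr[1:]))


@pytest.fixture(scope="module")
def grade_stats():
    patches, _ = make_cohort(50, seed=17)
    areas, oareas, planted, vasc = {}, {}, {}, {}
    for g in (1, 2, 3, 4):
        sel = [p for p in patches if p.grade_label == g]
        areas[g] = [np.mean([np.pi * r**2 for r in p.meta["tumor_radii"]]) for p in sel]
        oareas[g] = [np.mean([np.pi * r**2 for r in p.meta["other_radii"]]) for p in sel]
        planted[g] = [np.mean(p.meta["planted_nucleoli_tumor"]) for p in sel]
        vasc[g] = [p.vasc_mask.mean() for p in sel]
    return areas, oareas, planted, vasc


class TestMakeCohort:
    def test_counts_and_design(self):
        patches, meta = make_cohort(3, grade_levels=(1, 4), n_slides=2, seed=0)
        assert len(patches) == 6 and len(meta) == 6
        assert meta["grade"].value_counts().to_dict() == {1: 3, 4: 3}
        assert set(meta["slide_id"]) == {"slide_00", "slide_01"}

    def test_grade_monotone_morphology(self, grade_stats):
        """Tumor area / planted nucleoli rise, vessels fall, non-tumor flat."""
        areas, oareas, planted, vasc = grade_stats
        means = {g: np.mean(areas[g]) for g in (1, 2, 3, 4)}
        assert means[1] < means[2] < means[3] < means[4]
        assert np.mean(planted[1]) < np.mean(planted[2]) < np.mean(planted[3]) < np.mean(planted[4])
        v = {g: np.mean(vasc[g]) for g in (1, 2, 3, 4)}
        assert v[1] > v[2] > v[3] > v[4]
        # non-tumor areas: one-way ANOVA fails to reject equality at alpha=0.01
        f, p = stats.f_oneway(*[oareas[g] for g in (1, 2, 3, 4)])
        assert p > 0.01



class TestAnalyticBackend:
    def test_round_trip_bit_exact(self):
        bk = analytic_backend()
        p = SceneParams.from_grade(2.4, 8, 5, size_factor=1.1, seed=19)
        direct = render_scene(p)
        via = bk.decode(bk.encode(p), bk.encode_stochastic(p))
        assert np.array_equal(direct.image, via.image)
        assert np.array_equal(direct.nuclei_mask, via.nuclei_mask)

    def test_state_swap_preserves_grade_statistics(self):
        bk = analytic_backend()
        code = bk.encode(SceneParams.from_grade(3.0, 9, 6, seed=0))
        a = bk.decode(code, 101)
        b = bk.decode(code, 202)
        assert a.meta["tumor_centers"] != b.meta["tumor_centers"]
        ra, rb = np.mean(a.meta["tumor_radii"]), np.mean(b.meta["tumor_radii"])
        assert abs(ra - rb) / ra < 0.05  # same grade-conditional distribution

    def test_grade_direction_increases_tumor_radius(self):
        bk = analytic_backend()
        code = bk.encode(SceneParams.from_grade(1.0, 8, 5, seed=0))
        radii = []
        for t in np.linspace(0, 2.5, 6):
            params = bk.params_from_code(code + t * bk.grade_direction, 0)
            radii.append(params.tumor_radius_mean)
        assert all(x < y for x, y in zip(radii, radii[1:]))

    def test_out_of_bounds_code_clips_with_warning(self):
        bk = analytic_backend()
        code = np.array([7.0, 8.0, 5.0, 0.0])
        with pytest.warns(ParameterClipWarning):
            params = bk.params_from_code(code, 0)
        assert params.grade == 4.0
        assert bk.clip_warnings

    def test_same_seed_same_positions_across_grades(self):
        bk = analytic_backend()
        lo = bk.decode(np.array([1.0, 7.0, 4.0, 0.0]), 55)
        hi = bk.decode(np.array([4.0, 7.0, 4.0, 0.0]), 55)
        assert lo.meta["tumor_centers"] == hi.meta["tumor_centers"]
        assert np.mean(hi.meta["tumor_radii"]) > np.mean(lo.meta["tumor_radii"])


class TestPatchIO:
    def test_save_load_round_trip(self, tmp_path):
        patch = render_scene(_params(seed=33))
        patch.patch_id, patch.slide_id, patch.grade_label = "p1", "s1", 2
        from deltamarch.synthetic_tissue import save_patch, load_patch

        save_patch(patch, tmp_path)
        loaded = load_patch(tmp_path, "p1")
        assert np.array_equal(loaded.nuclei_mask, patch.nuclei_mask)
        assert np.array_equal(loaded.vasc_mask, patch.vasc_mask)
        assert np.max(np.abs(loaded.image - patch.image)) <= 1 / 255 + 1e-12
        assert loaded.grade_label == 2 and loaded.slide_id == "s1"
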