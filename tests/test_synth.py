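"""Synthetic phantom, target, dose engine and cohort generator."""

import numpy as np
import pytest

from arcdose import dvh, geometry as geo, synth
from arcdose.grids import MEDIA


@pytest.fixture(scope="module")
def phantom():
    return synth.make_phantom()


class TestPhantom:
    def test_all_four_media_present(self, phantom):
        present = set(np.unique(phantom.media.values))
        assert present == set(range(len(MEDIA)))

    def test_lung_fraction_of_body(self, phantom):
        body = np.count_nonzero(phantom.external.values)
        lung = np.count_nonzero(phantom.lung.values)
        assert 0.15 < lung / body < 0.5

    def test_media_partition_body(self, phantom):
        soft = phantom.media.region("soft tissue")
        lung = phantom.media.region("lung")
        bone = phantom.media.region("bone")
        assert not (soft & lung).any() and not (soft & bone).any()
        np.testing.assert_array_equal(soft | lung | bone, phantom.external.values)

    def test_deterministic(self):
        a = synth.make_phantom()
        b = synth.make_phantom()
        np.testing.assert_array_equal(a.media.values, b.media.values)

    def test_lung_bone_overlap_rejected(self):
        spec = synth.PhantomSpec(bone_centre_y=0.0, bone_radius=30.0)
        with pytest.raises(ValueError, match="overlap"):
            synth.make_phantom(spec)


class TestTarget:
    def test_ptv_contains_ctv(self, phantom):
        ctv, ptv = synth.make_target(synth.TargetSpec(lobes=3, seed=4), phantom)
        assert np.all(ptv.values | ~ctv.values)

    def test_sphere_target_high_sphericity(self):
        # fine-grid phantom so the digitized sphere is well resolved
        spec = synth.PhantomSpec(shape=(72, 72, 72), spacing=(1.5, 1.5, 1.5),
                                 body_half_axes=(52.0, 52.0),
                                 lung_half_axes=(30.0, 20.0, 15.0),
                                 lung_centres_x=(-25.0, 25.0),
                                 bone_centre_y=40.0, bone_radius=6.0,
                                 cord_radius=3.0, oesophagus_centre=(25.0, -4.0),
                                 oesophagus_radius=3.0)
        ph = synth.make_phantom(spec)
        ctv, _ = synth.make_target(
            synth.TargetSpec(centre=(0, 0, 0), radius_mm=20.0, lobes=1, margin_mm=5.0),
            ph)
        area, volume = geo.surface_and_volume(ctv)
        assert geo.sphericity(area, volume) >= 0.95

    def test_more_lobes_lower_sphericity(self, phantom):
        psis = []
        for lobes in (1, 4):
            ctv, _ = synth.make_target(
                synth.TargetSpec(radius_mm=35.0, lobes=lobes, seed=2), phantom)
            area, volume = geo.surface_and_volume(ctv)
            psis.append(geo.sphericity(area, volume))
        assert psis[1] < psis[0]

    def test_escaping_ptv_clipped_with_warning(self, phantom):
        spec = synth.TargetSpec(centre=(0, -10, 120), radius_mm=35.0, margin_mm=8.0)
        with pytest.warns(UserWarning, match="clipped"):
            _, ptv = synth.make_target(spec, phantom)
        assert not (ptv.values & ~phantom.external.values).any()


class TestDoseEngine:
    def test_single_field_depth_falloff(self, phantom):
        ctv, ptv = synth.make_target(synth.TargetSpec(), phantom)
        spec = synth.BeamSpec(technique="static", gantry_angles=(0.0,),
                              field_margin_mm=(8, 5))
        dose = synth.simulate_dose(phantom, ptv, spec)
        # along the beam axis inside the body the dose decreases with depth
        iz = dose.values.shape[0] // 2
        ix = np.argmin(np.abs(dose.axis_coords(2) - 60.0))
        profile = dose.values[iz, :, ix]
        inside = phantom.external.values[iz, :, ix] & (profile > 0)
        vals = profile[inside]
        assert vals[0] > vals[-1]
        assert np.sum(np.diff(vals) > 1e-9) < 0.1 * vals.size

    def test_arc_azimuthal_symmetry_on_centred_target(self):
        # symmetric configuration: circular body, target at the origin and
        # water-equivalent attenuation everywhere, so the summed arc beams
        # should wash out any azimuthal preference; sampled on an exact-radius
        # circle (a finite-width ring would mix in the steep radial gradient)
        from scipy import ndimage

        spec = synth.PhantomSpec(
            shape=(24, 116, 116), spacing=(4.0, 2.0, 2.0),
            body_half_axes=(110.0, 110.0),
            lung_half_axes=(30.0, 20.0, 15.0), lung_centres_x=(-60.0, 60.0),
            bone_centre_y=85.0, bone_radius=8.0, cord_radius=3.0,
            oesophagus_centre=(50.0, -8.0), oesophagus_radius=4.0)
        ph = synth.make_phantom(spec)
        ctv, ptv = synth.make_target(
            synth.TargetSpec(centre=(0, 0, 0), radius_mm=25.0), ph)
        uniform = {m: 1.0 for m in ("lung", "soft tissue", "bone")}
        uniform["outside"] = 0.0
        dose = synth.simulate_dose(ph, ptv, synth.BeamSpec(technique="arc",
                                                           attenuation=uniform))
        plane = dose.values[dose.values.shape[0] // 2]
        ys, xs = dose.axis_coords(1), dose.axis_coords(2)
        phis = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        radius = 40.0
        py = (radius * np.cos(phis) - ys[0]) / dose.spacing[1]
        px = (radius * np.sin(phis) - xs[0]) / dose.spacing[2]
        vals = ndimage.map_coordinates(plane, [py, px], order=1)
        assert (vals.max() - vals.min()) / vals.max() < 0.05

    def test_arc_trades_low_dose_bath_for_conformity(self, phantom):
        ctv, ptv = synth.make_target(synth.TargetSpec(), phantom)
        static = synth.simulate_dose(phantom, ptv, synth.BeamSpec(
            technique="static", gantry_angles=(0, 120, 240), field_margin_mm=(8, 5)))
        arc = synth.simulate_dose(phantom, ptv, synth.BeamSpec(technique="arc"))
        kwargs = dict(lung=phantom.lung, external=phantom.external, bin_width=0.05)
        m_static = dvh.compute_plan_metrics(static, ptv, **kwargs)
        m_arc = dvh.compute_plan_metrics(arc, ptv, **kwargs)
        assert m_arc.v5_pct >= m_static.v5_pct
        assert m_arc.cn >= m_static.cn

    def test_arc_control_points(self):
        spec = synth.BeamSpec(technique="arc")
        assert len(spec.angles()) == 89  # 356 degrees at 4-degree spacing

    def test_empty_ptv_rejected(self, phantom):
        from arcdose.grids import StructureMask
        empty = StructureMask(np.zeros_like(phantom.external.values),
                              spacing=phantom.spacing, origin=phantom.origin)
        with pytest.raises(ValueError):
            synth.simulate_dose(phantom, empty, synth.BeamSpec())


@pytest.fixture(scope="module")
def dose(phantom):
    ctv, ptv = synth.make_target(synth.TargetSpec(), phantom)
    return synth.simulate_dose(phantom, ptv, synth.BeamSpec(technique="arc"))


class TestMeasuredPlane:
    def test_clean_extraction_identity(self, phantom, dose):
        plane = synth.make_measured_plane(dose, 0.0, synth.BeamSpec(), phantom.media)
        iz = int(np.argmin(np.abs(dose.axis_coords(0))))
        np.testing.assert_array_equal(plane.values, dose.values[iz])

    def test_uniform_offset_gives_gamma_one_in_uniform_regions(self, phantom, dose):
        from arcdose.gamma import GammaParams, gamma_map
        spec = synth.BeamSpec(medium_offsets_pct={m: 3.0 for m in
                                                  ("lung", "soft tissue", "bone")})
        film = synth.make_measured_plane(dose, 0.0, spec, phantom.media)
        clean = synth.make_measured_plane(dose, 0.0, synth.BeamSpec(), phantom.media)
        res = gamma_map(film, clean, GammaParams(dd_pct=3.0, dta_mm=3.0))
        # in the flat PTV plateau the dose offset alone sets gamma ~ 1
        plateau = clean.values >= 0.95 * clean.values.max()
        vals = res.gamma[plateau & res.evaluated]
        assert np.nanmedian(vals) == pytest.approx(1.0, abs=0.15)

    def test_seed_determinism(self, phantom, dose):
        spec = synth.BeamSpec(noise_sd_pct=2.0, registration_shift_mm=(1.0, -0.5), seed=9)
        a = synth.make_measured_plane(dose, 0.0, spec, phantom.media)
        b = synth.make_measured_plane(dose, 0.0, spec, phantom.media)
        np.testing.assert_array_equal(a.values, b.values)

    def test_plane_outside_grid_rejected(self, dose):
        with pytest.raises(ValueError, match="outside"):
            synth.make_measured_plane(dose, 1e4, synth.BeamSpec())


class TestCohort:
    def test_small_cohort_end_to_end(self, tmp_path):
        cohort = synth.make_cohort(2, master_seed=5, out_dir=tmp_path / "c")
        assert len(cohort) == 2
        lo, hi = synth.PTV_VOLUME_RANGE_CM3
        assert ((cohort.v_ptv_cm3 >= 0.8 * lo) & (cohort.v_ptv_cm3 <= hi)).all()
        for metric in ("cn", "hi", "v5_pct", "mld_cgy", "mu"):
            for variant in ("3DCRT", "DCAT0", "DCAT45"):
                assert f"{metric}::{variant}" in cohort
        assert (tmp_path / "c" / "cohort.csv").exists()
        assert (tmp_path / "c" / "manifest.json").exists()

    def test_same_master_seed_identical(self):
        a = synth.make_cohort(2, master_seed=11)
        b = synth.make_cohort(2, master_seed=11)
        import pandas as pd
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            synth.make_cohort(1)
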