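"""Synthetic thorax phantoms, targets, plans and cohorts.

Everything downstream modules consume can be generated here with no external
data: a thorax-like medium map (lung / soft tissue / bone inside an
elliptical body), CTV/PTV pairs of controllable sphericity (a main lobe plus
optional protruding lobes, expanded by an isotropic margin), static
multi-field and ~356-degree arc dose distributions from a deliberately
simple beam engine, "measured" film planes carrying per-medium systematic
offsets plus noise and a small registration shift, and full plan cohorts.

The dose engine is intentionally crude — primary-photon exponential
attenuation through the media (relative attenuation defaults: lung 0.25,
soft tissue 1.0, bone 1.6 times water) with a Gaussian penumbra on the field
aperture — because the analysis, not the physics, is the product.  It still
reproduces the qualitative trade-offs the analysis must detect: an arc bathes
more lung in low dose (higher V5Gy) while conforming better to the target
(higher CN) than a few static fields with larger field margins.

Everything is deterministic under fixed seeds at every level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from . import dvh as dvh_mod
from . import geometry as geo
from .grids import DoseGrid, MediumLabelMap, PlanarDose, StructureMask, MEDIA
from .io_formats import write_portable

__all__ = [
    "PhantomSpec", "TargetSpec", "BeamSpec", "Phantom",
    "make_phantom", "make_target", "simulate_dose", "make_measured_plane",
    "make_cohort", "simulate_diff_cohort", "simulate_metric_cohort",
]

#: attenuation of water at ~6 MV, per mm
MU_WATER_MM = 0.005

#: relative attenuation (electron-density proxy) per medium
RELATIVE_ATTENUATION = {"outside": 0.0, "lung": 0.25, "soft tissue": 1.0, "bone": 1.6}

#: fractionation table: total dose (Gy) -> (case frequency, dose per fraction Gy)
PRESCRIPTIONS = {36.0: (21, 3.0), 50.0: (3, 2.0), 30.0: (3, 3.0), 55.0: (2, 2.2),
                 59.4: (1, 2.2), 48.0: (1, 3.0), 45.0: (1, 2.5), 39.0: (1, 3.0),
                 35.0: (1, 2.5), 20.0: (1, 4.0)}

#: PTV volume range sampled by the cohort generator, cm^3
PTV_VOLUME_RANGE_CM3 = (145.2, 2686.5)

#: collimator-angle variants: extra penumbra blur (mm) and MU perturbation;
#: the engine cannot model the collimator physically, so the variant axis is
#: a documented synthetic perturbation that exercises the ranking analysis
#: (blurs must stay resolvable on the default 4 mm cohort grid)
COLLIMATOR_VARIANTS = {"DCAT0": 0.0, "DCAT30": 1.2, "DCAT45": 1.8, "DCAT90": 3.0}


@dataclass
class PhantomSpec:
    """Thorax phantom layout: elliptical body, two lung ellipsoids, a spine
    bone insert with a spinal-cord channel, and an oesophageal tube."""

    shape: tuple[int, int, int] = (60, 60, 80)          # (nz, ny, nx)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)  # mm
    body_half_axes: tuple[float, float] = (100.0, 150.0)   # (y, x) mm
    lung_half_axes: tuple[float, float, float] = (100.0, 65.0, 55.0)
    lung_centres_x: tuple[float, float] = (-70.0, 70.0)
    lung_centre_y: float = -10.0
    bone_centre_y: float = 75.0
    bone_radius: float = 14.0
    cord_radius: float = 5.0
    oesophagus_centre: tuple[float, float] = (45.0, -8.0)  # (y, x)
    oesophagus_radius: float = 6.0
    seed: int = 0


@dataclass
class Phantom:
    """Generated phantom: media plus the organ masks the analysis needs."""

    media: MediumLabelMap
    external: StructureMask
    lung: StructureMask
    cord: StructureMask
    oesophagus: StructureMask
    spec: PhantomSpec
    _fluence_cache: dict = dc_field(default_factory=dict, repr=False)

    @property
    def spacing(self):
        return self.media.spacing

    @property
    def origin(self):
        return self.media.origin


def _centred_coords(shape, spacing):
    """Voxel-centre coordinates per axis, with the grid centred on 0."""
    return [
        spacing[i] * (np.arange(shape[i]) - (shape[i] - 1) / 2.0)
        for i in range(len(shape))
    ]


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build the thorax phantom; deterministic for a fixed spec."""
    spec = spec or PhantomSpec()
    nz, ny, nx = spec.shape
    zs, ys, xs = _centred_coords(spec.shape, spec.spacing)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")

    by, bx = spec.body_half_axes
    body = (Y / by) ** 2 + (X / bx) ** 2 <= 1.0

    lz, ly, lx = spec.lung_half_axes
    lungs = np.zeros_like(body)
    for cx in spec.lung_centres_x:
        lungs |= (
            (Z / lz) ** 2 + ((Y - spec.lung_centre_y) / ly) ** 2 + ((X - cx) / lx) ** 2
        ) <= 1.0
    lungs &= body

    bone = ((Y - spec.bone_centre_y) ** 2 + X ** 2) <= spec.bone_radius ** 2
    bone &= body
    if (lungs & bone).any():
        raise ValueError("phantom spec invalid: lungs overlap the bone insert")

    cord = ((Y - spec.bone_centre_y) ** 2 + X ** 2) <= spec.cord_radius ** 2
    cord &= body
    oy, ox = spec.oesophagus_centre
    oeso = ((Y - oy) ** 2 + (X - ox) ** 2) <= spec.oesophagus_radius ** 2
    oeso &= body

    labels = np.zeros(spec.shape, dtype=np.int16)  # outside
    labels[body] = MEDIA.index("soft tissue")
    labels[lungs] = MEDIA.index("lung")
    labels[bone] = MEDIA.index("bone")

    origin = tuple(float(c[0]) for c in _centred_coords(spec.shape, spec.spacing))
    geom = dict(spacing=spec.spacing, origin=origin)
    media = MediumLabelMap(labels, **geom)
    return Phantom(
        media=media,
        external=StructureMask(body, name="external", role="external", **geom),
        lung=StructureMask(lungs, name="lung", role="lung", **geom),
        cord=StructureMask(cord, name="cord", role="cord", **geom),
        oesophagus=StructureMask(oeso, name="oesophagus", role="oesophagus", **geom),
        spec=spec,
    )


@dataclass
class TargetSpec:
    """Target construction: a main lobe with optional protrusions.

    ``lobes = 1`` gives a near-spherical CTV; extra lobes are smaller spheres
    attached at ~0.9 radii from the centre and strictly decrease the
    mask-derived sphericity.  The PTV is the CTV expanded by the isotropic
    margin ``margin_mm``.
    """

    centre: tuple[float, float, float] = (0.0, -10.0, 60.0)  # (z, y, x) mm
    radius_mm: float = 30.0
    lobes: int = 1
    lobe_radius_frac: float = 0.55
    lobe_offset_frac: float = 0.9
    margin_mm: float = 7.0
    seed: int = 0


def make_target(spec: TargetSpec, phantom: Phantom) -> tuple[StructureMask, StructureMask]:
    """Build (CTV, PTV) masks on the phantom grid.

    The PTV is the Euclidean dilation of the CTV by the isotropic margin.
    Both masks are clipped to the body with a warning if the PTV escapes it.
    """
    if spec.lobes < 1:
        raise ValueError("need at least one lobe")
    if spec.margin_mm <= 0:
        raise ValueError("margin must be positive")
    shape = phantom.media.values.shape
    zs, ys, xs = (phantom.media.axis_coords(i) for i in range(3))
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")

    rng = np.random.default_rng(spec.seed)
    cz, cy, cx = spec.centre
    ctv = (Z - cz) ** 2 + (Y - cy) ** 2 + (X - cx) ** 2 <= spec.radius_mm ** 2
    for _ in range(spec.lobes - 1):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        off = spec.lobe_offset_frac * spec.radius_mm * direction
        r_lobe = spec.lobe_radius_frac * spec.radius_mm
        ctv |= (
            (Z - cz - off[0]) ** 2 + (Y - cy - off[1]) ** 2 + (X - cx - off[2]) ** 2
        ) <= r_lobe ** 2
    if not ctv.any():
        raise ValueError("target lies outside the grid")

    geom = dict(spacing=phantom.spacing, origin=phantom.origin)
    ctv_mask = StructureMask(ctv & phantom.external.values, name="CTV", role="CTV", **geom)
    ptv_mask = geo.expand_margin(ctv_mask, spec.margin_mm)
    if (ptv_mask.values & ~phantom.external.values).any():
        warnings.warn("PTV escapes the body; clipped to the external contour", stacklevel=2)
        ptv_mask = StructureMask(ptv_mask.values & phantom.external.values,
                                 name="PTV", role="PTV", **geom)
    else:
        ptv_mask.name, ptv_mask.role = "PTV", "PTV"
    return ctv_mask, ptv_mask


@dataclass
class BeamSpec:
    """Beam arrangement and measurement-emulation parameters."""

    technique: str = "arc"                  # "static" | "arc"
    gantry_angles: tuple[float, ...] = (0.0, 120.0, 240.0)  # static only, degrees
    arc_start_deg: float = 182.0
    arc_stop_deg: float = 178.0             # reached clockwise through 360
    control_point_spacing_deg: float = 4.0
    field_margin_mm: tuple[float, float] = (5.0, 5.0)   # (cranio-caudal, transversal)
    penumbra_sigma_mm: float = 4.0
    prescription_gy: float = 36.0
    attenuation: dict = dc_field(default_factory=lambda: dict(RELATIVE_ATTENUATION))
    medium_offsets_pct: dict = dc_field(default_factory=dict)  # film per-medium offsets
    noise_sd_pct: float = 0.0               # film noise, % of the plane maximum
    registration_shift_mm: tuple[float, float] = (0.0, 0.0)   # (y, x)
    mu: int | None = None                   # recorded plan attribute
    seed: int = 0

    def angles(self) -> np.ndarray:
        if self.technique == "static":
            return np.asarray(self.gantry_angles, dtype=float)
        if self.control_point_spacing_deg <= 0:
            raise ValueError("control-point spacing must be positive")
        span = (self.arc_stop_deg - self.arc_start_deg) % 360.0
        n = int(span / self.control_point_spacing_deg)
        return (self.arc_start_deg + self.control_point_spacing_deg * np.arange(n)) % 360.0


def _density_map(phantom: Phantom, attenuation: dict) -> np.ndarray:
    dens = np.zeros(phantom.media.values.shape)
    for name in phantom.media.labels:
        dens[phantom.media.region(name)] = attenuation.get(name, 0.0)
    return dens


def _fluence_for_angle(phantom: Phantom, angle: float, attenuation_key: tuple) -> np.ndarray:
    """Primary fluence in the frame rotated so the beam travels along +y;
    cached on the phantom (the phantom is shared across a cohort)."""
    key = (round(float(angle), 3), attenuation_key)
    if key not in phantom._fluence_cache:
        dens = _density_map(phantom, dict(attenuation_key))
        rot = ndimage.rotate(dens, angle, axes=(1, 2), reshape=False, order=1, cval=0.0)
        depth = np.cumsum(rot, axis=1) * phantom.spacing[1] * MU_WATER_MM
        phantom._fluence_cache[key] = np.exp(-depth)
    return phantom._fluence_cache[key]


def simulate_dose(phantom: Phantom, ptv: StructureMask, beams: BeamSpec) -> DoseGrid:
    """Simplified forward dose calculation.

    Each field / arc control point contributes exponentially attenuated
    primary fluence inside an aperture shaped to the PTV projection in the
    beam's eye view, expanded by the field margins and softened by a Gaussian
    penumbra.  The sum is restricted to the body and normalised so the PTV
    median equals the prescription dose.
    """
    if ptv.is_empty():
        raise ValueError("PTV is empty")
    angles = beams.angles()
    att_key = tuple(sorted(beams.attenuation.items()))
    dz, dy, dx = phantom.spacing
    mz, mx = beams.field_margin_mm

    total = np.zeros(phantom.media.values.shape)
    ptv_f = ptv.values.astype(np.float64)
    for angle in angles:
        fluence = _fluence_for_angle(phantom, angle, att_key)
        ptv_rot = ndimage.rotate(ptv_f, angle, axes=(1, 2), reshape=False, order=1, cval=0.0)
        proj = ptv_rot.max(axis=1) > 0.5  # beam's-eye-view footprint, (z, x)
        if not proj.any():
            continue
        # anisotropic field margin: normalised-distance dilation as in expand_margin
        margins = np.array([max(mz, 1e-9), max(mx, 1e-9)])
        dt = ndimage.distance_transform_edt(~proj, sampling=np.array([dz, dx]) / margins)
        field = dt <= 1.0 + 1e-9
        # analytic penumbra: Gaussian edge profile of the signed distance (mm)
        # to the field border, sub-voxel smooth and stable across gantry angles
        d_out = ndimage.distance_transform_edt(~field, sampling=(dz, dx))
        d_in = ndimage.distance_transform_edt(field, sampling=(dz, dx))
        signed = d_in - d_out
        aperture = ndtr(signed / beams.penumbra_sigma_mm)
        contrib = fluence * aperture[:, None, :]
        total += ndimage.rotate(contrib, -angle, axes=(1, 2), reshape=False, order=1, cval=0.0)

    total /= len(angles)
    total *= phantom.external.values  # dose scored inside the body only
    ptv_median = np.median(total[ptv.values])
    if ptv_median <= 0:
        raise ValueError("simulated dose is zero over the PTV")
    total *= beams.prescription_gy / ptv_median
    np.clip(total, 0.0, None, out=total)
    return DoseGrid(total, spacing=phantom.spacing, origin=phantom.origin)


def make_measured_plane(dose: DoseGrid, plane_z_mm: float, beams: BeamSpec,
                        media: MediumLabelMap | None = None) -> PlanarDose:
    """Emulate a film measurement of one axial dose plane.

    Extracts the plane nearest ``plane_z_mm``, applies the per-medium
    multiplicative offsets (%), adds Gaussian noise (sd as % of the plane
    maximum) and a rigid in-plane registration shift.  With zero offsets,
    noise and shift the extracted plane is returned unchanged.
    """
    zs = dose.axis_coords(0)
    dzhalf = dose.spacing[0] / 2
    if plane_z_mm < zs[0] - dzhalf or plane_z_mm > zs[-1] + dzhalf:
        raise ValueError(f"plane z={plane_z_mm} mm outside grid [{zs[0]}, {zs[-1]}] mm")
    iz = int(np.argmin(np.abs(zs - plane_z_mm)))
    plane = dose.values[iz].copy()

    if beams.medium_offsets_pct:
        if media is None:
            raise ValueError("per-medium offsets require a medium label map")
        media_plane = media.plane(iz) if media.values.ndim == 3 else media
        for name, off in beams.medium_offsets_pct.items():
            plane[media_plane.region(name)] *= 1.0 + off / 100.0

    rng = np.random.default_rng(beams.seed)
    if beams.noise_sd_pct > 0:
        plane += rng.normal(0.0, beams.noise_sd_pct / 100.0 * plane.max(), plane.shape)
    if any(s != 0 for s in beams.registration_shift_mm):
        shift_vox = np.asarray(beams.registration_shift_mm) / np.asarray(dose.spacing[1:])
        plane = ndimage.shift(plane, shift_vox, order=1, mode="nearest")
    np.clip(plane, 0.0, None, out=plane)
    return PlanarDose(plane, spacing=dose.spacing[1:], origin=dose.origin[1:],
                      label=f"axial plane z={zs[iz]:.1f} mm")


# ---------------------------------------------------------------------------
# Cohort generation


def _sample_prescription(rng: np.random.Generator) -> tuple[float, float]:
    """Total prescription dose (Gy) and its dose per fraction (Gy)."""
    doses = np.array(list(PRESCRIPTIONS))
    weights = np.array([c for c, _ in PRESCRIPTIONS.values()], dtype=float)
    total = float(rng.choice(doses, p=weights / weights.sum()))
    return total, PRESCRIPTIONS[total][1]


def _sample_field_count(rng: np.random.Generator) -> int:
    return int(rng.choice([3, 4, 5], p=np.array([25, 9, 1]) / 35.0))


def make_cohort(n_patients: int, master_seed: int = 0,
                phantom_spec: PhantomSpec | None = None,
                out_dir: str | Path | None = None) -> pd.DataFrame:
    """Generate a full paired-plan cohort and its metric table.

    Per patient: a target of sampled volume (log-uniform PTV volume within
    the modelled clinical range), shape (1–4 lobes) and location, a static
    multi-field plan and an arc plan with the four collimator-angle variants
    (the variant axis perturbs only the MU proxy and the penumbra), and all
    geometric and DVH metrics computed through the analysis modules.

    Returns one row per patient; optionally writes portable artifacts and a
    manifest under ``out_dir``.
    """
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    phantom = make_phantom(phantom_spec)
    master = np.random.default_rng(master_seed)
    patient_seeds = master.integers(0, 2**31 - 1, size=n_patients)

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        write_portable(phantom.media, out_path / "phantom_media",
                       provenance={"master_seed": int(master_seed)})
        for m in (phantom.external, phantom.lung, phantom.cord, phantom.oesophagus):
            write_portable(m, out_path / f"phantom_{m.name}")

    lo, hi = PTV_VOLUME_RANGE_CM3
    rows = []
    manifest = []
    for pid, seed in enumerate(patient_seeds):
        rng = np.random.default_rng(seed)
        v_ptv_target = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        margin = float(rng.uniform(5.0, 10.0))
        r_ptv = (3.0 * v_ptv_target * 1000.0 / (4 * np.pi)) ** (1 / 3)
        radius = max(r_ptv - margin, 8.0)
        lobes = int(rng.choice([1, 2, 3, 4], p=[0.4, 0.3, 0.2, 0.1]))

        # keep the target roughly inside the body: pull large targets central
        side = rng.choice([-1.0, 1.0])
        max_x = max(25.0, min(80.0, 140.0 - r_ptv))
        cx = side * rng.uniform(25.0, max_x)
        cy = rng.uniform(-40.0, 20.0) * min(1.0, (90.0 - r_ptv) / 60.0)
        zmax = max(5.0, 105.0 - r_ptv)
        cz = rng.uniform(-zmax, zmax)
        tspec = TargetSpec(centre=(cz, cy, cx), radius_mm=radius, lobes=lobes,
                           margin_mm=margin, seed=int(rng.integers(2**31 - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv, ptv = make_target(tspec, phantom)

        d_nom, fraction_gy = _sample_prescription(rng)
        area, v_ctv = geo.surface_and_volume(ctv)
        psi = geo.sphericity(area, v_ctv)
        v_ptv = ptv.volume_cm3
        psi_tilde = geo.sphericity_like(v_ctv, v_ptv, margin)
        d_cord = geo.min_distance(ctv, phantom.cord)
        skin = StructureMask(~phantom.external.values, spacing=phantom.spacing,
                             origin=phantom.origin, name="outside body")
        d_skin = geo.min_distance(ctv, skin)
        overlap_cm3, overlap_pct = geo.overlap(ptv, phantom.lung)
        r_iso = geo.isocentre_displacement(cx, cy)

        row = {
            "patient": pid, "seed": int(seed), "d_nom_gy": d_nom,
            "v_ctv_cm3": v_ctv, "v_ptv_cm3": v_ptv, "margin_mm": margin,
            "psi": psi, "psi_tilde": psi_tilde, "lobes": lobes,
            "v_lung_cm3": phantom.lung.volume_cm3,
            "d_ctv_cord_mm": d_cord, "d_ctv_skin_mm": d_skin,
            "ptv_lung_overlap_cm3": overlap_cm3, "ptv_lung_overlap_pct": overlap_pct,
            "r_mm": r_iso,
        }

        n_fields = _sample_field_count(rng)
        base = float(rng.uniform(0.0, 360.0 / n_fields))
        static_angles = tuple((base + 360.0 * k / n_fields + rng.normal(0, 8))
                              % 360.0 for k in range(n_fields))
        # MU proxy per fraction: ~105 MU/Gy of fraction dose for static fields
        mu_static = int(round(rng.normal(105.0 * fraction_gy, 25.0)))
        static_spec = BeamSpec(technique="static", gantry_angles=static_angles,
                               field_margin_mm=(8.0, 5.0), prescription_gy=d_nom,
                               mu=mu_static, seed=int(rng.integers(2**31 - 1)))
        static_dose = simulate_dose(phantom, ptv, static_spec)

        arc_spec = BeamSpec(technique="arc", field_margin_mm=(5.0, 5.0),
                            prescription_gy=d_nom, seed=int(rng.integers(2**31 - 1)))
        arc_dose = simulate_dose(phantom, ptv, arc_spec)
        mu_arc = int(round(mu_static - rng.normal(50.0, 30.0)))

        organ_kwargs = dict(lung=phantom.lung, cord=phantom.cord,
                            oesophagus=phantom.oesophagus, external=phantom.external,
                            d_nom_gy=d_nom, bin_width=0.05)
        m_static = dvh_mod.compute_plan_metrics(static_dose, ptv, mu=mu_static,
                                                **organ_kwargs)
        _metrics_into_row(row, m_static, "3DCRT")

        for variant, extra_blur in COLLIMATOR_VARIANTS.items():
            values = arc_dose.values
            if extra_blur > 0:
                values = ndimage.gaussian_filter(
                    values, sigma=np.asarray([extra_blur] * 3) / np.asarray(phantom.spacing))
            vdose = DoseGrid(np.clip(values, 0, None), spacing=phantom.spacing,
                             origin=phantom.origin)
            mu_v = mu_arc + {"DCAT0": 0, "DCAT30": 2, "DCAT45": 3, "DCAT90": 5}[variant]
            m_arc = dvh_mod.compute_plan_metrics(vdose, ptv, mu=mu_v, **organ_kwargs)
            _metrics_into_row(row, m_arc, variant)

        if out_path is not None:
            pdir = out_path / f"patient_{pid:03d}"
            pdir.mkdir(exist_ok=True)
            write_portable(static_dose, pdir / "dose_3DCRT",
                           provenance={"seed": int(seed), "technique": "static"})
            write_portable(arc_dose, pdir / "dose_DCAT",
                           provenance={"seed": int(seed), "technique": "arc"})
            write_portable(ctv, pdir / "ctv")
            write_portable(ptv, pdir / "ptv")
            manifest.append({"patient": pid, "dir": pdir.name, "d_nom_gy": d_nom})
        rows.append(row)

    cohort = pd.DataFrame(rows).set_index("patient")
    if out_path is not None:
        cohort.to_csv(out_path / "cohort.csv")
        (out_path / "manifest.json").write_text(json.dumps(
            {"n_patients": n_patients, "master_seed": int(master_seed),
             "patients": manifest}, indent=1))
    return cohort


def _metrics_into_row(row: dict, m: dvh_mod.PlanMetrics, variant: str) -> None:
    for attr in ("cn", "hi", "dhd", "mld_cgy", "v20_pct", "v5_pct",
                 "d1cc_cord_cgy", "mean_oesophagus_cgy", "mu"):
        row[f"{attr}::{variant}"] = getattr(m, attr)


# ---------------------------------------------------------------------------
# Lightweight statistical generators for recovery studies


def simulate_diff_cohort(
    n_plans: int,
    offsets_pct: dict[str, float],
    between_plan_sd_pct: float = 1.5,
    within_plan_sd_pct: float = 2.5,
    seed: int = 0,
    plane_shape: tuple[int, int] = (48, 64),
) -> tuple[list[tuple[PlanarDose, PlanarDose]], MediumLabelMap]:
    """Cohort of (evaluation, reference) plane pairs with known error structure.

    The evaluation (calculated) plane misestimates the reference per medium:
    a fixed systematic offset per medium, a per-plan random effect (sd
    ``between_plan_sd_pct``) and per-pixel noise (sd ``within_plan_sd_pct``),
    all in % of the local reference dose — so the decomposition should
    recover M ~= offset, Sigma ~= between-plan sd and sigma ~= within-plan sd.
    """
    rng = np.random.default_rng(seed)
    ny, nx = plane_shape
    ys, xs = _centred_coords(plane_shape, (4.0, 4.0))
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    labels = np.zeros(plane_shape, dtype=np.int16)
    labels[:] = MEDIA.index("soft tissue")
    labels[(X < -30)] = MEDIA.index("lung")
    labels[(X > 60)] = MEDIA.index("bone")
    media = MediumLabelMap(labels, spacing=(4.0, 4.0), origin=(float(ys[0]), float(xs[0])))

    base = 2.0 * np.exp(-((Y / 120.0) ** 2 + (X / 160.0) ** 2))  # smooth, well above floor
    pairs = []
    for _ in range(n_plans):
        plan_effects = {m: rng.normal(0.0, between_plan_sd_pct) for m in offsets_pct}
        err = np.zeros(plane_shape)
        for m, off in offsets_pct.items():
            sel = media.region(m)
            err[sel] = off + plan_effects[m]
        err += rng.normal(0.0, within_plan_sd_pct, plane_shape)
        ev = base * (1.0 + err / 100.0)
        pairs.append((
            PlanarDose(np.clip(ev, 0, None), spacing=(4.0, 4.0)),
            PlanarDose(base, spacing=(4.0, 4.0)),
        ))
    return pairs, media


def simulate_metric_cohort(n_patients: int, effect: float, sd: float,
                           seed: int = 0, skew: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Paired metric samples with a known shift for statistics-pipeline tests.

    Returns (a, b) with a = b + difference; the difference is Gaussian with
    the given mean and sd, optionally skewed by exponentiating (lognormal
    shape) when ``skew`` > 0.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(20.0, 5.0, n_patients)
    if skew > 0:
        diff = effect + sd * (rng.lognormal(0.0, skew, n_patients)
                              - np.exp(skew ** 2 / 2.0))
    else:
        diff = rng.normal(effect, sd, n_patients)
    return b + diff, b
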