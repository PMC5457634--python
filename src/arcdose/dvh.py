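"""Cumulative dose-volume histograms and scalar plan metrics.

Plan quality is summarised by the standard photon-plan indices:

* conformation number  CN = (TV_RI / TV) * (TV_RI / V_RI), where TV_RI is the
  target volume covered by the reference isodose (95% of the prescription by
  default), TV the target volume and V_RI the total volume covered;
* homogeneity index  HI = (D2 - D98) / D_nom;
* dose homogeneity dispersion  DHD = sd / mean of the target dose;
* lung burden V20Gy, V5Gy (% volume at or above 20 / 5 Gy) and mean lung dose;
* cord D1cc — the dose covering the hottest 1 cm^3.

Cumulative DVH convention: fraction(t) = volume receiving a dose >= t divided
by the structure volume, so fraction(0) = 1 and the curve is non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid, StructureMask

logger = logging.getLogger(__name__)

__all__ = [
    "DVHCurve",
    "PlanMetrics",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "dose_at_absolute_volume",
    "conformation_number",
    "homogeneity_index",
    "dhd",
    "mean_dose",
    "check_constraints",
    "compute_plan_metrics",
]

DEFAULT_BIN_WIDTH_GY = 0.01


@dataclass
class DVHCurve:
    """Cumulative DVH sampled at uniform dose bin edges.

    ``fraction[i]`` is the fraction of the structure volume receiving at
    least ``dose[i]`` Gy; the curve starts at 1 for dose 0 and never rises.
    """

    dose: np.ndarray          # bin edges, Gy, uniform width, starting at 0
    fraction: np.ndarray      # cumulative volume fraction at each edge
    name: str = ""
    total_volume_cm3: float = 0.0

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.dose.shape != self.fraction.shape:
            raise ValueError("dose and fraction must have equal length")
        if self.dose[0] != 0:
            raise ValueError("DVH must start at dose 0")
        if np.any(np.diff(self.fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")
        if not np.isclose(self.fraction[0], 1.0):
            raise ValueError("fraction at dose 0 must be 1")

    @property
    def bin_width(self) -> float:
        return float(self.dose[1] - self.dose[0]) if len(self.dose) > 1 else 0.0


def _mask_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if not dose.same_geometry(mask):
        raise ValueError("dose and mask must share geometry")
    if mask.is_empty():
        raise ValueError("empty structure mask")
    return dose.values[mask.values]


def compute_dvh(dose: DoseGrid, mask: StructureMask,
                bin_width: float = DEFAULT_BIN_WIDTH_GY) -> DVHCurve:
    """Cumulative DVH of ``mask`` under ``dose`` at uniform ``bin_width`` (Gy)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    doses = np.sort(_mask_doses(dose, mask))
    n = doses.size
    top = float(doses[-1])
    n_edges = int(np.ceil(top / bin_width)) + 2
    edges = bin_width * np.arange(n_edges)
    # fraction(t) = #(dose >= t) / n via one vectorised search on sorted doses
    fraction = (n - np.searchsorted(doses, edges, side="left")) / n
    return DVHCurve(edges, fraction, name=mask.name, total_volume_cm3=mask.volume_cm3)


def dose_at_volume(dvh: DVHCurve, volume_pct: float) -> float:
    """D_v: smallest dose (Gy) at which the cumulative fraction drops to
    ``volume_pct``/100, linearly interpolated between bin edges (D2, D98)."""
    if not 0 < volume_pct < 100:
        raise ValueError("volume percentage must be in (0, 100)")
    target = volume_pct / 100.0
    # fraction is non-increasing; reverse for np.interp's ascending requirement
    return float(np.interp(target, dvh.fraction[::-1], dvh.dose[::-1]))


def volume_at_dose(dvh: DVHCurve, dose_gy: float) -> float:
    """V_t: percentage of the structure volume receiving >= ``dose_gy``."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    return float(100.0 * np.interp(dose_gy, dvh.dose, dvh.fraction))


def dose_at_absolute_volume(dose: DoseGrid, mask: StructureMask,
                            volume_cm3: float) -> float:
    """Hottest-volume dose (Gy): the maximum dose t such that at least
    ``volume_cm3`` of the structure receives >= t (e.g. cord D1cc)."""
    doses = np.sort(_mask_doses(dose, mask))[::-1]
    voxvol = mask.voxel_volume_cm3
    if volume_cm3 > doses.size * voxvol + 1e-9:
        raise ValueError(
            f"requested volume {volume_cm3} cm^3 exceeds structure volume "
            f"{doses.size * voxvol:.3f} cm^3"
        )
    k = max(1, int(np.ceil(volume_cm3 / voxvol - 1e-9)))
    return float(doses[min(k, doses.size) - 1])


def conformation_number(dose: DoseGrid, target: StructureMask,
                        reference_isodose_gy: float,
                        external: StructureMask | None = None) -> float:
    """Conformation number CN = (TV_RI/TV) * (TV_RI/V_RI).

    V_RI is counted inside the external contour when one is supplied, else
    over the whole grid.  CN = 0 by convention when no voxel reaches the
    reference isodose.
    """
    if reference_isodose_gy <= 0:
        raise ValueError("reference isodose must be positive")
    if target.is_empty():
        raise ValueError("empty target mask")
    hot = dose.values >= reference_isodose_gy
    if external is not None:
        if not dose.same_geometry(external):
            raise ValueError("external mask must share the dose geometry")
        hot = hot & external.values
    tv = np.count_nonzero(target.values)
    tv_ri = np.count_nonzero(hot & target.values)
    v_ri = np.count_nonzero(hot)
    if v_ri == 0:
        logger.info("no voxel reaches the reference isodose; CN = 0 by convention")
        return 0.0
    return float((tv_ri / tv) * (tv_ri / v_ri))


def homogeneity_index(d2_gy: float, d98_gy: float, d_nom_gy: float) -> float:
    """HI = (D2 - D98) / D_nom; 0 for a perfectly homogeneous target dose."""
    if d_nom_gy <= 0:
        raise ValueError("nominal dose must be positive")
    return float((d2_gy - d98_gy) / d_nom_gy)


def dhd(dose: DoseGrid, mask: StructureMask) -> float:
    """Dose homogeneity dispersion: sample sd / mean of the dose over the mask."""
    doses = _mask_doses(dose, mask)
    mean = float(doses.mean())
    if mean <= 0:
        raise ValueError("mean dose must be positive for DHD")
    sd = float(doses.std(ddof=1)) if doses.size > 1 else 0.0
    return sd / mean


def mean_dose(dose: DoseGrid, mask: StructureMask) -> float:
    """Mean dose (Gy) over a structure (MLD when the structure is lung)."""
    return float(_mask_doses(dose, mask).mean())


@dataclass
class PlanMetrics:
    """Scalar metrics of one treatment plan (doses to organs in cGy)."""

    cn: float | None = None
    hi: float | None = None
    dhd: float | None = None
    mld_cgy: float | None = None
    v20_pct: float | None = None
    v5_pct: float | None = None
    d1cc_cord_cgy: float | None = None
    mean_oesophagus_cgy: float | None = None
    mu: int | None = None                  # recorded plan attribute, never computed
    d_nom_gy: float | None = None
    reference_isodose_pct: float = 95.0
    d2_gy: float | None = None
    d98_gy: float | None = None


#: planning restrictions (strict inequalities; the boundary fails)
CONSTRAINTS = {
    "lung_v20": ("v20_pct", 35.0),        # V20Gy < 35 %
    "lung_v5": ("v5_pct", 60.0),          # V5Gy < 60 %
    "lung_mld": ("mld_cgy", 1500.0),      # MLD < 15 Gy
    "cord_d1cc": ("d1cc_cord_cgy", 5000.0),   # Dmax surrogate < 50 Gy
    "oesophagus_mean": ("mean_oesophagus_cgy", 3400.0),  # mean < 34 Gy
}


def check_constraints(metrics: PlanMetrics) -> dict[str, str]:
    """Evaluate the planning restrictions; returns pass/fail/not-evaluated.

    The cord limit uses D1cc as the maximum-dose surrogate.  All limits are
    strict: a metric exactly on the boundary fails.
    """
    out: dict[str, str] = {}
    for name, (attr, limit) in CONSTRAINTS.items():
        value = getattr(metrics, attr)
        if value is None:
            out[name] = "not evaluated"
        else:
            out[name] = "pass" if value < limit else "fail"
    return out


def compute_plan_metrics(
    dose: DoseGrid,
    ptv: StructureMask,
    lung: StructureMask | None = None,
    cord: StructureMask | None = None,
    oesophagus: StructureMask | None = None,
    external: StructureMask | None = None,
    d_nom_gy: float = 36.0,
    mu: int | None = None,
    reference_isodose_pct: float = 95.0,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> PlanMetrics:
    """Compute every scalar plan metric from a dose grid and structure masks."""
    ptv_dvh = compute_dvh(dose, ptv, bin_width)
    d2 = dose_at_volume(ptv_dvh, 2.0)
    d98 = dose_at_volume(ptv_dvh, 98.0)
    m = PlanMetrics(
        cn=conformation_number(dose, ptv, reference_isodose_pct / 100.0 * d_nom_gy,
                               external=external),
        hi=homogeneity_index(d2, d98, d_nom_gy),
        dhd=dhd(dose, ptv),
        mu=mu,
        d_nom_gy=d_nom_gy,
        reference_isodose_pct=reference_isodose_pct,
        d2_gy=d2,
        d98_gy=d98,
    )
    if lung is not None and not lung.is_empty():
        lung_dvh = compute_dvh(dose, lung, bin_width)
        m.v20_pct = volume_at_dose(lung_dvh, 20.0)
        m.v5_pct = volume_at_dose(lung_dvh, 5.0)
        m.mld_cgy = 100.0 * mean_dose(dose, lung)
    if cord is not None and not cord.is_empty():
        m.d1cc_cord_cgy = 100.0 * dose_at_absolute_volume(dose, cord, 1.0)
    if oesophagus is not None and not oesophagus.is_empty():
        m.mean_oesophagus_cgy = 100.0 * mean_dose(dose, oesophagus)
    return m
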