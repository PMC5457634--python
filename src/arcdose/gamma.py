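"""Gamma-index comparison of a reference and an evaluation dose distribution.

For every reference point r above the low-dose threshold,

    gamma(r) = min over r' of sqrt( delta^2(r, r') / dD^2  +  |r' - r|^2 / dd^2 ),

where delta is the dose difference between the evaluation distribution at r'
and the reference at r, dD is the dose criterion (a percentage of the
normalisation dose) and dd the distance-to-agreement criterion in mm.  A
point agrees when gamma < 1 (gamma exactly 1 counts as failing).  Summaries
are the pass fraction (% of evaluated points with gamma < 1) and the mean
gamma over evaluated points.

The normalisation dose is the global maximum of the *reference* distribution
(the measured film is conventionally the reference); ``norm="local"`` scales
the dose criterion by each reference point's own dose instead.

Two search strategies share this contract:

* :func:`gamma_map` — vectorised search over a displacement lattice of step
  ``dta/10``, processed in order of increasing displacement with pruning
  (once the distance term alone exceeds the worst current minimum, no
  further shift can improve any point);
* :func:`gamma_brute_force` — an exhaustive search on a finer lattice
  (step at most ``dta/20``), used as an independent oracle on small grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .grids import DoseGrid, PlanarDose

__all__ = ["GammaParams", "GammaResult", "gamma_map", "gamma_brute_force", "gamma_sweep"]


@dataclass
class GammaParams:
    """Criteria and search settings for a gamma comparison."""

    dd_pct: float = 3.0          # dose criterion, % of the normalisation dose
    dta_mm: float = 3.0          # distance-to-agreement criterion, mm
    threshold_pct: float = 10.0  # low-dose threshold, % of the normalisation dose
    norm: str = "global"         # "global" (max of reference) or "local"
    cap_mm: float | None = None  # search radius cap; default 3 * dta
    step_mm: float | None = None # search lattice step; default dta / 10

    def __post_init__(self) -> None:
        if self.dd_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("dose and distance criteria must be positive")
        if not 0 <= self.threshold_pct < 100:
            raise ValueError("threshold must lie in [0, 100)")
        if self.norm not in ("global", "local"):
            raise ValueError("norm must be 'global' or 'local'")
        if self.cap_mm is None:
            self.cap_mm = 3.0 * self.dta_mm
        if self.cap_mm < self.dta_mm:
            raise ValueError("search cap must be at least the DTA criterion")
        if self.step_mm is None:
            self.step_mm = self.dta_mm / 10.0


@dataclass
class GammaResult:
    """Gamma map plus its summaries over the evaluated points."""

    gamma: np.ndarray          # NaN where not evaluated
    evaluated: np.ndarray      # bool mask of evaluated reference points
    pass_fraction_pct: float
    mean_gamma: float
    params: GammaParams = field(repr=False, default_factory=GammaParams)


def _as_field(dist: PlanarDose | DoseGrid) -> tuple[np.ndarray, list[np.ndarray]]:
    axes = [dist.axis_coords(i) for i in range(dist.values.ndim)]
    return dist.values, axes


def _shift_lattice(ndim: int, step: float, cap: float) -> tuple[np.ndarray, np.ndarray]:
    """All displacement vectors on a regular lattice within the cap radius,
    sorted by increasing magnitude (the zero shift first)."""
    n = int(np.floor(cap / step))
    ax = step * np.arange(-n, n + 1)
    grids = np.meshgrid(*([ax] * ndim), indexing="ij")
    shifts = np.stack([g.ravel() for g in grids], axis=-1)
    r = np.linalg.norm(shifts, axis=1)
    keep = r <= cap + 1e-9
    shifts, r = shifts[keep], r[keep]
    order = np.argsort(r, kind="stable")
    return shifts[order], r[order]


def _prepare(reference, evaluation, params):
    ref_values, ref_axes = _as_field(reference)
    ev_values, ev_axes = _as_field(evaluation)
    if ref_values.ndim != ev_values.ndim:
        raise ValueError("reference and evaluation must have the same dimensionality")
    norm_dose = float(ref_values.max())
    if norm_dose <= 0:
        raise ValueError("reference distribution is identically zero")
    thresh = params.threshold_pct / 100.0 * norm_dose
    evaluated = ref_values >= thresh if params.threshold_pct > 0 else np.ones_like(ref_values, bool)
    if not evaluated.any():
        raise ValueError("no reference point above the low-dose threshold")
    if params.norm == "global":
        dd_abs = np.full(ref_values.shape, params.dd_pct / 100.0 * norm_dose)
    else:
        dd_abs = params.dd_pct / 100.0 * ref_values
        dd_abs[dd_abs <= 0] = np.inf
    interp = RegularGridInterpolator(
        tuple(ev_axes), ev_values, method="linear", bounds_error=False, fill_value=np.nan
    )
    coords = np.meshgrid(*ref_axes, indexing="ij")
    points = np.stack([c.ravel() for c in coords], axis=-1)
    return ref_values, evaluated, dd_abs, interp, points


def _summarise(gamma: np.ndarray, evaluated: np.ndarray, params: GammaParams) -> GammaResult:
    vals = gamma[evaluated]
    finite = np.isfinite(vals)
    evaluated = evaluated.copy()
    if not finite.all():
        # points with no evaluation-side coverage drop out of the summaries
        sub = np.zeros_like(evaluated)
        sub[evaluated] = ~finite
        evaluated &= ~sub
        vals = vals[finite]
    if vals.size == 0:
        raise ValueError("no evaluable reference point within evaluation coverage")
    return GammaResult(
        gamma=gamma,
        evaluated=evaluated,
        pass_fraction_pct=float(100.0 * np.mean(vals < 1.0)),
        mean_gamma=float(vals.mean()),
        params=params,
    )


def gamma_map(reference: PlanarDose | DoseGrid, evaluation: PlanarDose | DoseGrid,
              params: GammaParams | None = None) -> GammaResult:
    """Gamma map via a pruned search over a displacement lattice.

    Shifts are visited in order of increasing magnitude; the search stops as
    soon as the distance term alone exceeds the largest current per-point
    minimum, which no later shift can improve.
    """
    params = params or GammaParams()
    ref_values, evaluated, dd_abs, interp, points = _prepare(reference, evaluation, params)
    shifts, radii = _shift_lattice(ref_values.ndim, params.step_mm, params.cap_mm)

    ref_flat = ref_values.ravel()
    dd_flat = dd_abs.ravel()
    idx = np.flatnonzero(evaluated.ravel())
    pts = points[idx]
    ref_sel = ref_flat[idx]
    dd_sel = dd_flat[idx]

    g2 = np.full(idx.size, np.inf)
    best = np.zeros(idx.size, dtype=np.intp)
    dta2 = params.dta_mm ** 2
    for i, (shift, r) in enumerate(zip(shifts, radii)):
        dist_term = r * r / dta2
        worst = g2.max()
        if np.isfinite(worst) and dist_term >= worst:
            break  # sorted by radius: no remaining shift can improve any point
        ev = interp(pts + shift)
        cand = ((ev - ref_sel) / dd_sel) ** 2 + dist_term
        better = cand < g2  # NaN candidates (outside coverage) never win
        g2[better] = cand[better]
        best[better] = i

    # coarse-to-fine: refine each point on a fine lattice around its best shift
    ndim = shifts.shape[1]
    fine_step = params.step_mm / 12.0
    ax = fine_step * np.arange(-12, 13)
    local = np.stack([g.ravel() for g in np.meshgrid(*([ax] * ndim), indexing="ij")], axis=-1)
    has_min = np.isfinite(g2)
    if has_min.any() and local.shape[0] > 1:
        sel = np.flatnonzero(has_min)
        chunk = max(1, int(2e6 // local.shape[0]))
        for start in range(0, sel.size, chunk):
            s = sel[start:start + chunk]
            cand_shifts = shifts[best[s]][:, None, :] + local[None, :, :]
            rad2 = np.einsum("ijk,ijk->ij", cand_shifts, cand_shifts)
            keep_cap = rad2 <= params.cap_mm ** 2 + 1e-9
            query = pts[s][:, None, :] + cand_shifts
            ev = interp(query.reshape(-1, ndim)).reshape(len(s), -1)
            cand = ((ev - ref_sel[s, None]) / dd_sel[s, None]) ** 2 + rad2 / dta2
            cand[~keep_cap] = np.inf
            with np.errstate(invalid="ignore"):
                g2[s] = np.fmin(g2[s], np.nanmin(cand, axis=1))

    gamma = np.full(ref_flat.shape, np.nan)
    gamma[idx] = np.sqrt(g2)
    return _summarise(gamma.reshape(ref_values.shape), evaluated, params)


def gamma_brute_force(reference: PlanarDose | DoseGrid, evaluation: PlanarDose | DoseGrid,
                      params: GammaParams | None = None,
                      max_points: int = 64 * 64,
                      step_mm: float | None = None) -> GammaResult:
    """Exhaustive gamma search on a dense lattice (step <= dta/20, default
    dta/60): no pruning, no refinement, a plain minimum over every lattice
    displacement inside the cap.

    Independent oracle for :func:`gamma_map`; guards against grids larger
    than ``max_points`` reference points.
    """
    params = params or GammaParams()
    step = step_mm if step_mm is not None else params.dta_mm / 60.0
    if step > params.dta_mm / 20.0:
        raise ValueError("oracle lattice step must be at most dta/20")
    fine = GammaParams(
        dd_pct=params.dd_pct, dta_mm=params.dta_mm, threshold_pct=params.threshold_pct,
        norm=params.norm, cap_mm=params.cap_mm, step_mm=step,
    )
    ref_values, evaluated, dd_abs, interp, points = _prepare(reference, evaluation, fine)
    if ref_values.size > max_points:
        raise ValueError(f"brute-force guard: {ref_values.size} points exceeds {max_points}")

    aligned = ref_values.ndim == 2 and all(
        abs(s / step - round(s / step)) < 1e-9 for s in reference.spacing
    )
    if aligned:
        gamma = _brute_exhaustive_2d(reference, fine, dd_abs, interp)
    else:
        gamma = _brute_exhaustive_generic(ref_values, evaluated, dd_abs, interp, points, fine)
    gamma = gamma.reshape(ref_values.shape).copy()
    gamma[~evaluated] = np.nan
    return _summarise(gamma, evaluated, fine)


def _brute_exhaustive_2d(reference, fine: GammaParams, dd_abs, interp) -> np.ndarray:
    """Exhaustive 2D lattice search via one dense pre-sampled evaluation grid.

    The fine lattice is anchored on the reference grid (the reference spacing
    is an integer multiple of the lattice step), so every reference point
    plus every lattice displacement lands on a pre-sampled node and the
    minimisation reduces to strided slicing.
    """
    step = fine.step_mm
    ny, nx = reference.values.shape
    my = round(reference.spacing[0] / step)
    mx = round(reference.spacing[1] / step)
    ky = int(np.ceil(fine.cap_mm / step))
    kx = ky
    ax0 = reference.origin[0] + step * (np.arange((ny - 1) * my + 2 * ky + 1) - ky)
    ax1 = reference.origin[1] + step * (np.arange((nx - 1) * mx + 2 * kx + 1) - kx)
    fine_eval = interp(
        np.stack(np.meshgrid(ax0, ax1, indexing="ij"), axis=-1).reshape(-1, 2)
    ).reshape(len(ax0), len(ax1))

    dta2 = fine.dta_mm ** 2
    cap2 = fine.cap_mm ** 2 + 1e-9
    g2 = np.full((ny, nx), np.inf)
    for di in range(-ky, ky + 1):
        r2_row = (di * step) ** 2
        if r2_row > cap2:
            continue
        for dj in range(-kx, kx + 1):
            r2 = r2_row + (dj * step) ** 2
            if r2 > cap2:
                continue
            sub = fine_eval[ky + di::my, kx + dj::mx][:ny, :nx]
            cand = ((sub - reference.values) / dd_abs) ** 2 + r2 / dta2
            np.fmin(g2, cand, out=g2)
    with np.errstate(invalid="ignore"):
        return np.sqrt(g2)


def _brute_exhaustive_generic(ref_values, evaluated, dd_abs, interp, points,
                              fine: GammaParams) -> np.ndarray:
    """Chunked exhaustive search for 3D grids or non-aligned spacings."""
    shifts, radii = _shift_lattice(ref_values.ndim, fine.step_mm, fine.cap_mm)
    dist_terms = radii ** 2 / fine.dta_mm ** 2
    gamma = np.full(ref_values.size, np.nan)
    idx = np.flatnonzero(evaluated.ravel())
    ref_flat = ref_values.ravel()
    dd_flat = dd_abs.ravel()
    chunk = max(1, int(2e6 // shifts.shape[0]))
    for start in range(0, idx.size, chunk):
        sel = idx[start:start + chunk]
        query = points[sel][:, None, :] + shifts[None, :, :]
        ev = interp(query.reshape(-1, shifts.shape[1])).reshape(len(sel), -1)
        cand = ((ev - ref_flat[sel, None]) / dd_flat[sel, None]) ** 2 + dist_terms[None, :]
        with np.errstate(invalid="ignore"):
            gamma[sel] = np.sqrt(np.nanmin(cand, axis=1))
    return gamma


def gamma_sweep(reference: PlanarDose | DoseGrid, evaluation: PlanarDose | DoseGrid,
                criteria: list[tuple[float, float, float]],
                norm: str = "global") -> pd.DataFrame:
    """Summaries for a list of (dose %, DTA mm, threshold %) criteria."""
    rows = []
    for dd, dta, threshold in criteria:
        params = GammaParams(dd_pct=dd, dta_mm=dta, threshold_pct=threshold, norm=norm)
        res = gamma_map(reference, evaluation, params)
        rows.append({
            "dd_pct": dd, "dta_mm": dta, "threshold_pct": threshold,
            "pass_fraction_pct": res.pass_fraction_pct, "mean_gamma": res.mean_gamma,
            "n_evaluated": int(res.evaluated.sum()),
        })
    return pd.DataFrame(rows)
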