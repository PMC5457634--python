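"""Per-medium dose-error decomposition across a cohort of plan pairs.

For each verification plan the relative dose difference between the
TPS-calculated (evaluation) and the measured (reference) distribution,

    100 * (D_eval - D_ref) / D_ref   [%],

is averaged over each medium region (lung, soft tissue, bone).  Across a
cohort of n plans the per-medium summary is then

* M      — systematic error: mean over plans of the per-plan mean differences;
* Sigma  — standard deviation (n-1) over plans of the per-plan means;
* sigma  — random error: root-mean-square over plans of the within-plan SDs.

Signed values are reported throughout; a negative M means the calculation
underestimates the measured dose in that medium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import DoseGrid, MediumLabelMap, PlanarDose

__all__ = [
    "ErrorDecomposition",
    "relative_difference",
    "per_plan_region_stats",
    "decompose",
    "paired_symmetry_test",
]

#: reference doses below this fraction of the reference maximum are masked out
DEFAULT_DOSE_FLOOR = 0.05


@dataclass
class ErrorDecomposition:
    """Cohort-level per-medium errors (all in %): M, Sigma, sigma and n."""

    table: pd.DataFrame  # index: medium; columns: M_pct, Sigma_pct, sigma_pct, n_plans

    def __post_init__(self) -> None:
        t = self.table
        if (t["Sigma_pct"] < 0).any() or (t["sigma_pct"] < 0).any():
            raise ValueError("Sigma and sigma must be non-negative")
        if not np.isfinite(t["M_pct"]).all():
            raise ValueError("M must be finite")


def relative_difference(
    evaluation: PlanarDose | DoseGrid,
    reference: PlanarDose | DoseGrid,
    floor: float = DEFAULT_DOSE_FLOOR,
) -> np.ndarray:
    """Relative dose difference field in %, NaN where the reference dose is
    below ``floor`` times its maximum (excludes near-zero film dose)."""
    ev, ref = evaluation.values, reference.values
    if ev.shape != ref.shape:
        raise ValueError("evaluation and reference must share geometry")
    cutoff = floor * float(ref.max())
    valid = ref > max(cutoff, 0.0)
    if not valid.any():
        raise ValueError("every point falls below the dose floor")
    out = np.full(ref.shape, np.nan)
    out[valid] = 100.0 * (ev[valid] - ref[valid]) / ref[valid]
    return out


def per_plan_region_stats(diff_pct: np.ndarray, media: MediumLabelMap,
                          media_of_interest: tuple[str, ...] = ("lung", "soft tissue", "bone"),
                          ) -> pd.DataFrame:
    """Mean and sample SD (%) of a relative-difference field per medium.

    Media with no valid (unmasked) point are omitted from the result rather
    than reported as zero.
    """
    if diff_pct.shape != media.values.shape:
        raise ValueError("difference field and label map must share geometry")
    rows = {}
    for name in media_of_interest:
        sel = media.region(name)
        vals = diff_pct[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows[name] = {"mean_pct": float(vals.mean()), "sd_pct": sd, "n_points": vals.size}
    return pd.DataFrame.from_dict(rows, orient="index")


def decompose(plan_stats: list[pd.DataFrame]) -> ErrorDecomposition:
    """Cohort decomposition from per-plan region stats (one DataFrame per plan).

    Per medium: M = mean of per-plan means, Sigma = sample SD of per-plan
    means, sigma = RMS of per-plan SDs.  Requires at least two plans carrying
    the medium.
    """
    if len(plan_stats) < 2:
        raise ValueError("decomposition needs at least 2 plans (Sigma undefined)")
    media = sorted({m for df in plan_stats for m in df.index})
    rows = {}
    for medium in media:
        means = np.array([df.loc[medium, "mean_pct"] for df in plan_stats if medium in df.index])
        sds = np.array([df.loc[medium, "sd_pct"] for df in plan_stats if medium in df.index])
        if means.size < 2:
            raise ValueError(f"medium {medium!r} present in fewer than 2 plans")
        rows[medium] = {
            "M_pct": float(means.mean()),
            "Sigma_pct": float(means.std(ddof=1)),
            "sigma_pct": float(np.sqrt(np.mean(sds ** 2))),
            "n_plans": int(means.size),
        }
    return ErrorDecomposition(pd.DataFrame.from_dict(rows, orient="index"))


def paired_symmetry_test(per_plan_means: np.ndarray) -> float:
    """One-sample Wilcoxon signed-rank p-value for symmetry about zero of the
    per-plan mean differences; p = 1 by convention when every mean is zero."""
    x = np.asarray(per_plan_means, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 plans for the symmetry test")
    if np.all(x == 0):
        return 1.0
    return float(stats.wilcoxon(x).pvalue)
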