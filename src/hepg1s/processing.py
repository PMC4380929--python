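"""Replicate processing: calibrator correction, scaling, merging and the
linear/constant error models.

Immunoblot replicates live in arbitrary per-gel units.  Processing (i)
divides by the spiked recombinant-calibrator signal, (ii) estimates one
multiplicative scale factor per replicate against a smoothing-spline
consensus (alternating spline fit and per-replicate least-squares scales
until convergence), (iii) merges by per-time-point means, recording the SD
where three or more replicates are available, and (iv) derives per-point
standard errors from an error model: blot-like data carry a constant
relative error (through-origin regression of SD on mean), DNA-content data
a constant absolute error.  Finally each protein observable is normalized
to overall mean 1 and DNA content to 1 at the stimulation time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "TimeCourseDataset",
    "ErrorModel",
    "normalize_by_calibrator",
    "scale_and_merge",
    "estimate_linear_error",
    "compute_sem",
    "normalize_dataset",
]


@dataclass
class TimeCourseDataset:
    """A merged observation series with per-point uncertainty."""

    observable: str
    condition: str
    times: np.ndarray
    means: np.ndarray
    sems: np.ndarray | None
    n_replicates: np.ndarray
    sds: np.ndarray | None = None  # per-point SD where n >= 3, else NaN
    normalization: str = "none"  # none | unit-mean | anchored-at-stimulation
    scales: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.sems is not None and np.any(self.sems < 0):
            raise ValueError("SEM must be >= 0")


@dataclass(frozen=True)
class ErrorModel:
    """Measurement error: SD proportional to the mean (``linear``, slope =
    relative error) or constant (``constant``, for DNA-content assays)."""

    kind: str
    relative_error: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "constant"):
            raise ValueError("kind must be 'linear' or 'constant'")
        if self.relative_error < 0 or self.sd < 0:
            raise ValueError("error parameters must be >= 0")


def normalize_by_calibrator(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each intensity by its replicate's calibrator signal."""
    if "calibrator" not in table.columns:
        raise ValueError("table has no calibrator column")
    if np.any(table["calibrator"] <= 0):
        raise ValueError("calibrator signals must be > 0")
    out = table.copy()
    out["intensity"] = out["intensity"] / out["calibrator"]
    out["calibrator"] = 1.0
    return out


def _consensus_spline(times, values, weights, smoothness: float):
    # penalty parameter on a normalized [0, 1] scale: lam = (1 - p) / p
    lam = (1.0 - smoothness) / smoothness
    order = np.argsort(times)
    t, y, w = times[order], values[order], weights[order]
    ut, inv = np.unique(t, return_inverse=True)
    if ut.size < 4:  # too few support points for a cubic spline: fall back to means
        my = np.bincount(inv, weights=w * y) / np.bincount(inv, weights=w)
        return lambda x: np.interp(x, ut, my)
    wy = np.bincount(inv, weights=w * y)
    ws = np.bincount(inv, weights=w)
    return make_smoothing_spline(ut, wy / ws, w=ws, lam=lam)


def scale_and_merge(
    table: pd.DataFrame,
    smoothness: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> TimeCourseDataset:
    """Estimate per-replicate scales against a smoothing-spline consensus
    and merge to per-time-point means.

    ``smoothness`` is the spline roughness trade-off on a normalized [0, 1]
    scale (0.5 default).  Iterates spline fitting and per-replicate
    least-squares scale estimation to convergence (scales normalized to
    geometric mean 1), then averages per time point; the SD is recorded
    only where three or more replicates contribute.
    """
    if not 0 < smoothness < 1:
        raise ValueError("smoothness must be in (0, 1)")
    required = {"time_h", "replicate", "intensity"}
    if missing := required - set(table.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    obs = table["observable"].iloc[0] if "observable" in table.columns else ""
    cond = table["condition"].iloc[0] if "condition" in table.columns else ""

    reps = sorted(table["replicate"].unique())
    rep_data = {
        r: (g["time_h"].to_numpy(float), g["intensity"].to_numpy(float))
        for r, g in table.groupby("replicate")
    }
    for r, (_, y) in rep_data.items():
        if np.allclose(y, 0):
            raise ValueError(f"replicate {r} is all zero; scaling is degenerate")

    scales = {r: 1.0 for r in reps}
    if len(reps) > 1:
        for _ in range(max_iter):
            t_all = np.concatenate([rep_data[r][0] for r in reps])
            y_all = np.concatenate([scales[r] * rep_data[r][1] for r in reps])
            spline = _consensus_spline(t_all, y_all, np.ones_like(y_all), smoothness)
            new = {}
            for r in reps:
                t, y = rep_data[r]
                s = spline(t)
                denom = float(np.dot(y, y))
                new[r] = float(np.dot(y, s)) / denom if denom > 0 else 1.0
            gmean = np.exp(np.mean(np.log(np.abs(list(new.values())))))
            new = {r: v / gmean for r, v in new.items()}
            delta = max(abs(new[r] - scales[r]) for r in reps)
            scales = new
            if delta < tol:
                break

    scaled = table.copy()
    scaled["intensity"] = [
        scales[r] * v for r, v in zip(table["replicate"], table["intensity"])
    ]
    g = scaled.groupby("time_h")["intensity"]
    times = np.array(sorted(scaled["time_h"].unique()))
    means = g.mean().reindex(times).to_numpy()
    counts = g.count().reindex(times).to_numpy()
    sds = g.std(ddof=1).reindex(times).to_numpy()
    sds = np.where(counts >= 3, sds, np.nan)

    return TimeCourseDataset(
        observable=obs, condition=cond, times=times, means=means,
        sems=None, n_replicates=counts, sds=sds,
        scales=tuple(scales[r] for r in reps),
    )


def estimate_linear_error(
    means: np.ndarray, sds: np.ndarray
) -> ErrorModel:
    """Fit the linear error model: through-origin regression of the
    per-point SD on the mean; the slope is the relative error."""
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ok = np.isfinite(means) & np.isfinite(sds)
    if ok.sum() < 2:
        raise ValueError("need >= 2 points with replicate SD to fit the error model")
    m, s = means[ok], sds[ok]
    slope = float(np.dot(m, s) / np.dot(m, m))
    return ErrorModel(kind="linear", relative_error=max(slope, 0.0))


def estimate_constant_error(sds: np.ndarray) -> ErrorModel:
    """Constant error model: average SD over the complete data set."""
    sds = np.asarray(sds, float)
    ok = np.isfinite(sds)
    if not ok.any():
        raise ValueError("no replicate SDs available")
    return ErrorModel(kind="constant", sd=float(np.mean(sds[ok])))


def compute_sem(
    dataset: TimeCourseDataset, error_model: ErrorModel
) -> TimeCourseDataset:
    """Attach per-point standard errors from the error model:
    ``mean * relative_error / sqrt(n)`` (linear) or ``sd / sqrt(n)``
    (constant)."""
    n = np.maximum(dataset.n_replicates, 1)
    if error_model.kind == "linear":
        sems = np.abs(dataset.means) * error_model.relative_error / np.sqrt(n)
    else:
        sems = np.full_like(dataset.means, error_model.sd) / np.sqrt(n)
    return replace(dataset, sems=sems)


def normalize_dataset(
    dataset: TimeCourseDataset, t_stim: float | None = None
) -> TimeCourseDataset:
    """Normalize for estimation: protein observables to overall mean 1,
    DNA content to 1 at the stimulation time; SEMs rescale identically."""
    if t_stim is not None or dataset.observable == "dna":
        anchor_t = t_stim if t_stim is not None else 24.0
        i = int(np.argmin(np.abs(dataset.times - anchor_t)))
        norm = dataset.means[i]
        tag = "anchored-at-stimulation"
    else:
        norm = float(np.mean(dataset.means))
        tag = "unit-mean"
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("zero or undefined normalizer")
    return replace(
        dataset,
        means=dataset.means / norm,
        sems=None if dataset.sems is None else dataset.sems / norm,
        sds=None if dataset.sds is None else dataset.sds / norm,
        normalization=tag,
    )
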