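"""Post-calibration analyses.

* Control coefficients: local finite-difference sensitivity of a readout
  (DNA content at 72 h by default) to 10% parameter changes,
  ``[x(f*p) - x(p)] / [(f - 1) * x(p)]`` for f in {0.9, 1.1}, mapped over
  a best-fit ensemble and ranked by |median| with a sign filter per
  context (parameters whose increase raises basal DNA synthesis;
  parameters whose decrease lowers stimulated DNA synthesis).
* Dose-response curves and the half-maximum (EC50) dose per observable,
  the response being either the maximal value over a 72-h window or the
  72-h value, with the EC50 found by monotone interpolation of the
  half-maximum crossing.
* Two-input response surfaces (e.g. ERK x Akt activity) read out at 72 h,
  with the HGF dose path across the surface.
* Four-parameter Hill fits (baseline, amplitude, inflection, slope) with a
  curvature-based standard error of the inflection point -- used for
  restriction-point timing and experimental EC50s.
* Per-component linear regression of proliferation (S/G2/M fraction)
  against component intensity across doses, with Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .inputs import evaluate_inputs
from .network import ReactionNetwork
from .parameters import ParameterSet
from .simulate import ExperimentProtocol, compute_observables, simulate

__all__ = [
    "CDK2_CONC_NM",
    "CDK4_CONC_NM",
    "cdk2_cdk4_fold_excess",
    "finite_difference_control",
    "control_coefficient",
    "control_coefficient_table",
    "rank_sensitivities",
    "DoseResponseCurve",
    "dose_response",
    "half_maximum_dose",
    "response_surface",
    "HillFit",
    "fit_hill4",
    "regress_components_vs_proliferation",
]

#: Measured absolute concentrations at the restriction point (nM).
CDK2_CONC_NM = 23.6
CDK4_CONC_NM = 3.5


def cdk2_cdk4_fold_excess(
    cdk2_nm: float = CDK2_CONC_NM, cdk4_nm: float = CDK4_CONC_NM
) -> float:
    """Fold excess of CDK2 over CDK4 (~7 at the measured concentrations)."""
    if cdk4_nm <= 0:
        raise ValueError("CDK4 concentration must be > 0")
    return cdk2_nm / cdk4_nm


# --------------------------------------------------------------------------
# Control coefficients
# --------------------------------------------------------------------------


def finite_difference_control(response_fn, params: ParameterSet, param_id: str, f: float) -> float:
    """Normalized finite-difference control coefficient
    ``[x(f*p) - x(p)] / [(f - 1) * x(p)]`` for a generic response
    function of a parameter set."""
    if f == 1.0:
        raise ValueError("perturbation factor f must differ from 1")
    x0 = response_fn(params)
    if x0 == 0:
        raise ZeroDivisionError(f"response is 0 at the reference point for {param_id}")
    x1 = response_fn(params.with_updates(**{param_id: f * params.values[param_id]}))
    return (x1 - x0) / ((f - 1.0) * x0)


def _dna_at(network, params, protocol, t_read):
    traj = simulate(network, params, protocol, np.array([t_read]))
    return float(compute_observables(traj, network, params)["dna"][0])


def control_coefficient(
    network: ReactionNetwork,
    params: ParameterSet,
    param_id: str,
    f: float,
    protocol: ExperimentProtocol | None = None,
    t_read: float = 72.0,
) -> float:
    """Control of ``param_id`` over DNA content at ``t_read`` under the
    given protocol (default: 40 ng/ml continuous stimulation)."""
    protocol = protocol or ExperimentProtocol(hgf_dose=40.0)
    return finite_difference_control(
        lambda p: _dna_at(network, p, protocol, t_read), params, param_id, f
    )


def control_coefficient_table(
    network: ReactionNetwork,
    ensemble: list[ParameterSet],
    protocol: ExperimentProtocol,
    param_ids: list[str] | None = None,
    factors: tuple[float, float] = (0.9, 1.1),
    t_read: float = 72.0,
) -> pd.DataFrame:
    """Control coefficients for every parameter and ensemble member, for
    both a 10% decrease and a 10% increase (tidy rows: parameter, member,
    factor, coefficient)."""
    rows = []
    for member, params in enumerate(ensemble):
        ids = param_ids if param_ids is not None else list(params.free)
        x0 = _dna_at(network, params, protocol, t_read)
        if x0 == 0:
            raise ZeroDivisionError("reference DNA response is 0")
        for pid in ids:
            for f in factors:
                x1 = _dna_at(
                    network, params.with_updates(**{pid: f * params.values[pid]}),
                    protocol, t_read,
                )
                rows.append(
                    {
                        "parameter": pid,
                        "member": member,
                        "factor": f,
                        "coefficient": (x1 - x0) / ((f - 1.0) * x0),
                    }
                )
    return pd.DataFrame(rows)


def rank_sensitivities(
    table: pd.DataFrame, context: str, top: int = 16
) -> pd.DataFrame:
    """Rank parameters by |median coefficient| with the sign filter of the
    analysis context: ``basal-increase`` keeps parameters whose increase
    raises the readout (positive median), ``stimulated-decrease`` keeps
    those whose increase lowers it (negative median)."""
    if context not in ("basal-increase", "stimulated-decrease"):
        raise ValueError("context must be 'basal-increase' or 'stimulated-decrease'")
    if table.empty:
        raise ValueError("empty coefficient table")
    med = table.groupby("parameter")["coefficient"].median()
    keep = med > 0 if context == "basal-increase" else med < 0
    ranked = med[keep].abs().sort_values(ascending=False).head(top)
    return pd.DataFrame(
        {
            "parameter": ranked.index,
            "median_coefficient": med[ranked.index].to_numpy(),
            "abs_median": ranked.to_numpy(),
        }
    ).reset_index(drop=True)


# --------------------------------------------------------------------------
# Dose-response and EC50
# --------------------------------------------------------------------------


@dataclass
class DoseResponseCurve:
    """Per-observable dose-response over an ensemble."""

    observable: str
    doses: np.ndarray
    responses: np.ndarray  # (n_members, n_doses)
    response_def: str
    ec50s: np.ndarray  # per member; NaN where flat

    @property
    def median_ec50(self) -> float:
        vals = self.ec50s[np.isfinite(self.ec50s)]
        return float(np.median(vals)) if vals.size else float("nan")


def half_maximum_dose(doses: np.ndarray, response: np.ndarray, flat_tol: float = 0.01) -> float:
    """Dose of half-maximum response by monotone piecewise-linear
    interpolation (log-dose scale) of the first crossing between the
    curve's minimum and maximum.  Returns NaN for flat curves (range
    below ``flat_tol`` of the baseline magnitude)."""
    doses = np.asarray(doses, float)
    response = np.asarray(response, float)
    lo, hi = response.min(), response.max()
    scale = max(abs(response[0]), abs(hi), 1e-300)
    if hi - lo < flat_tol * scale:
        return float("nan")
    half = lo + 0.5 * (hi - lo)
    for i in range(doses.size - 1):
        a, b = response[i], response[i + 1]
        if (a - half) * (b - half) <= 0 and a != b:
            w = (half - a) / (b - a)
            if doses[i] <= 0:
                return float(doses[i] + w * (doses[i + 1] - doses[i]))
            ld = np.log10(doses[i]) + w * (np.log10(doses[i + 1]) - np.log10(doses[i]))
            return float(10**ld)
    return float("nan")


def dose_response(
    network: ReactionNetwork,
    ensemble: list[ParameterSet],
    doses: np.ndarray,
    observables: list[str] | None = None,
    response_def: str = "max-over-72h",
    t_stim: float = 24.0,
    window: float = 72.0,
) -> dict[str, DoseResponseCurve]:
    """Simulate dose-response curves for each observable and ensemble
    member and extract the half-maximum dose.

    ``response_def`` is ``"max-over-72h"`` (maximal observable value over a
    72-h window from stimulation; default, used for the EC50 ranking) or
    ``"at-72h"`` (value 48 h after stimulation at total time 72 h).
    """
    doses = np.asarray(doses, float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    if response_def not in ("max-over-72h", "at-72h"):
        raise ValueError("response_def must be 'max-over-72h' or 'at-72h'")
    if observables is None:
        observables = list(network.observables)
    if doses.max() < 100:
        warnings.warn("dose span may not reach saturation (max < 100 ng/ml)")

    t_end = t_stim + window if response_def == "max-over-72h" else 72.0
    times = (
        np.linspace(t_stim, t_end, 97)
        if response_def == "max-over-72h"
        else np.array([72.0])
    )
    responses = {
        o: np.zeros((len(ensemble), doses.size)) for o in observables
    }
    for m, params in enumerate(ensemble):
        for j, dose in enumerate(doses):
            proto = ExperimentProtocol(hgf_dose=float(dose), t_stim=t_stim, t_end=t_end)
            traj = simulate(network, params, proto, times)
            obs = compute_observables(traj, network, params)
            for o in observables:
                y = obs[o]
                responses[o][m, j] = y.max() if response_def == "max-over-72h" else y[-1]

    out = {}
    for o in observables:
        ec50s = np.array(
            [half_maximum_dose(doses, responses[o][m]) for m in range(len(ensemble))]
        )
        out[o] = DoseResponseCurve(o, doses, responses[o], response_def, ec50s)
    return out


def response_surface(
    network: ReactionNetwork,
    params: ParameterSet,
    axis1: str,
    axis2: str,
    grid: np.ndarray,
    observables: list[str] | None = None,
    t_read: float = 72.0,
    t_stim: float = 24.0,
    dose_path: np.ndarray | None = None,
) -> dict:
    """Readout intensities at ``t_read`` as a function of two clamped
    input-node activities (e.g. ERK x Akt).

    Returns ``{"grid", "surfaces" (obs -> matrix[i, j] for axis1=grid[i],
    axis2=grid[j]), "basal_point", "dose_path"}``; the dose path gives the
    (axis1, axis2) activities attained at each HGF dose, so the surface can
    be compared with the one-dimensional dose response.
    """
    from .inputs import INPUT_NODES

    for ax in (axis1, axis2):
        if ax not in INPUT_NODES:
            raise ValueError(f"{ax!r} is not an input node")
    grid = np.asarray(grid, float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("activity grid values must lie in [0, 1]")
    if observables is None:
        observables = list(network.observables)

    surfaces = {o: np.zeros((grid.size, grid.size)) for o in observables}
    for i, a1 in enumerate(grid):
        for j, a2 in enumerate(grid):
            proto = ExperimentProtocol(hgf_dose=0.0, t_stim=t_stim, t_end=t_read)
            clamped = params  # inputs enter via the clamp mechanism below
            traj = _simulate_clamped(network, clamped, proto, {axis1: a1, axis2: a2},
                                     np.array([t_read]))
            obs = compute_observables(traj, network, params)
            for o in observables:
                surfaces[o][i, j] = obs[o][0]

    ip = params.input_params()
    basal = evaluate_inputs(0.0, ip)
    path = None
    if dose_path is not None:
        states = [evaluate_inputs(float(d), ip) for d in dose_path]
        path = {
            "doses": np.asarray(dose_path, float),
            axis1: np.array([getattr(s, axis1) for s in states]),
            axis2: np.array([getattr(s, axis2) for s in states]),
        }
    return {
        "grid": grid,
        "surfaces": surfaces,
        "basal_point": (getattr(basal, axis1), getattr(basal, axis2)),
        "dose_path": path,
    }


def _simulate_clamped(network, params, protocol, clamps, times):
    """Simulate with input nodes clamped from the stimulation event on."""
    from .simulate import Trajectories, _compiled
    from .inputs import evaluate_inputs as _ev

    # represent the clamp as a washout-free protocol whose 'inhibitor'
    # clamps are injected directly
    comp = _compiled(network)
    import numpy as _np

    x = _np.zeros(comp.n)
    if comp.dna_idx is not None:
        x[comp.dna_idx] = 1.0
    ip = params.input_params()
    out = _np.empty((times.size, comp.n))
    filled = _np.zeros(times.size, dtype=bool)
    from .simulate import _integrate_segment

    events = [0.0, protocol.t_stim, protocol.t_end]
    for t0, t1 in zip(events[:-1], events[1:]):
        if t1 <= t0:
            continue
        inp = _ev(0.0, ip, clamps if t0 >= protocol.t_stim else None)
        f = comp.rhs(comp.keff(params, inp))
        mask = (~filled) & (times > t0) & (times <= t1 + 1e-12)
        t_eval = _np.unique(times[mask])
        x = _integrate_segment(f, x, t0, t1, t_eval, out, times, mask, 1e-6, 1e-9, "LSODA")
        filled |= mask
    if times.size and times[0] == 0.0:
        out[0] = 0.0
        if comp.dna_idx is not None:
            out[0, comp.dna_idx] = 1.0
    _np.clip(out, 0.0, None, out=out)
    return Trajectories(times=times, states=out, state_names=comp.state_names)


# --------------------------------------------------------------------------
# Four-parameter Hill fits
# --------------------------------------------------------------------------


@dataclass
class HillFit:
    """Four-parameter Hill regression ``base + amp * x^n / (k^n + x^n)``.

    ``k`` is the inflection point on the log-x axis (EC50 / restriction
    time); ``k_stderr`` is its curvature-based standard error.  ``flat``
    marks fits whose amplitude is negligible (inflection undefined);
    ``extrapolated`` marks inflections outside the data span.
    """

    base: float
    amp: float
    k: float
    n: float
    k_stderr: float
    residual_norm: float
    flat: bool = False
    extrapolated: bool = False

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        return self.base + self.amp * x**self.n / (self.k**self.n + x**self.n)


def fit_hill4(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> HillFit:
    """Nonlinear four-parameter Hill regression with multi-start
    initialization (the 4PL objective has well-known local minima).

    ``x`` must be positive (dose or time on a log-ready axis); ``weights``
    multiply the residuals.  Raises on non-convergence; constant data
    yield a flat-flagged fit with undefined inflection.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need at least 4 points for a four-parameter fit")
    if np.any(x <= 0):
        raise ValueError("x must be positive for log-domain initialization")
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)

    span = y.max() - y.min()
    scale = max(abs(y).max(), 1e-300)
    if span < 1e-8 * scale:
        return HillFit(float(y.mean()), 0.0, float("nan"), 1.0, float("nan"),
                       0.0, flat=True)

    increasing = y[np.argmax(x)] >= y[np.argmin(x)]
    amp0 = span if increasing else -span
    base0 = y.min() if increasing else y.max()
    lx = np.log10(x)

    def resid(theta):
        base, amp, lk, n = theta
        k = 10.0**lk
        return w * (base + amp * x**n / (k**n + x**n) - y)

    rng = np.random.default_rng(seed)
    best = None
    k_grid = np.quantile(lx, np.linspace(0.2, 0.8, n_starts))
    for i in range(n_starts):
        n0 = 10.0 ** rng.uniform(-0.3, 0.6) if i else 2.0
        theta0 = [base0, amp0, k_grid[i], n0]
        try:
            sol = least_squares(
                resid, theta0,
                bounds=([-np.inf, -np.inf, lx.min() - 3, 0.1],
                        [np.inf, np.inf, lx.max() + 3, 25.0]),
                method="trf",
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("four-parameter Hill fit did not converge")

    base, amp, lk, n = best.x
    k = float(10.0**lk)
    # standard error of k via the local curvature (J^T J)^-1, delta method
    dof = max(x.size - 4, 1)
    s2 = 2 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        k_se = float(np.sqrt(max(cov[2, 2], 0.0)) * abs(k * np.log(10.0)))
    except np.linalg.LinAlgError:
        k_se = float("nan")
    return HillFit(
        base=float(base), amp=float(amp), k=k, n=float(n),
        k_stderr=k_se, residual_norm=float(np.sqrt(2 * best.cost)),
        flat=abs(amp) < 1e-6 * scale,
        extrapolated=not (x.min() <= k <= x.max()),
    )


# --------------------------------------------------------------------------
# Component-vs-proliferation regression
# --------------------------------------------------------------------------


def regress_components_vs_proliferation(
    component_series: dict[str, np.ndarray],
    proliferation: np.ndarray,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """OLS of proliferation (S/G2/M percentage per dose) on each
    component's intensity over the matched dose grid.

    Returns one row per component with R^2, the two-sided slope p-value,
    the Bonferroni-adjusted p-value (``min(1, m * p)``), sorted by
    adjusted p.  ``m_tests`` defaults to the number of components.
    """
    prolif = np.asarray(proliferation, float)
    if not component_series:
        raise ValueError("no component series given")
    m = m_tests if m_tests is not None else len(component_series)
    if m < 1:
        raise ValueError("m_tests must be >= 1")
    rows = []
    for name, series in component_series.items():
        xs = np.asarray(series, float)
        if xs.size != prolif.size:
            raise ValueError(f"dose grids do not match for {name}")
        if xs.size < 3:
            raise ValueError("need at least 3 matched points per component")
        model = sm.OLS(prolif, sm.add_constant(xs)).fit()
        p = float(model.pvalues[1])
        rows.append(
            {
                "component": name,
                "slope": float(model.params[1]),
                "intercept": float(model.params[0]),
                "r_squared": float(model.rsquared),
                "p_value": p,
                "p_adjusted": min(1.0, m * p),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["p_adjusted", "p_value"], kind="stable")
        .reset_index(drop=True)
    )
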